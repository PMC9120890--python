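# Methods

## The measurement model

Cell-free DNA in plasma is a mixture: a fraction *tf* (the tumor
fraction) comes from tumor cells, the rest from normal diploid cells.
Read counts in fixed 50-kb genomic bins, expressed as log2 ratios to a
diploid baseline, then have expectation

    E[logR] = log2( tf · C/2 + (1 − tf) )

for a region of integer tumor copy number *C*. All copy-number and
tumor-fraction machinery in this package inverts that mixture. Per-bin
noise is modeled as i.i.d. Gaussian on the log2 ratio (default SD 0.3 at
50-kb bins); read-level sampling, GC and mappability bias are not
modeled — the package deliberately starts from binned log-ratios, the
granularity at which the downstream analysis operates.

The default genome is the 22 human autosomes (hg19 lengths truncated to
whole 50-kb bins). Sex chromosomes are excluded to avoid ploidy
ambiguity in the mixture formula.

## Segmentation

Per chromosome, recursive binary segmentation minimizes the within-
segment sum of squares; a split is kept while it reduces the SSE by more
than `penalty · σ² · log(n)` (default penalty 1.0), with σ estimated
robustly from successive bin differences. Two additions matter in
practice:

- a CBS-style *middle-interval* step: when no single split clears the
  threshold, the best in-vs-out interval extraction is tried at twice
  the penalty. A short event in the middle of a long segment dilutes
  both single-split contrasts and is otherwise missed;
- a *merge-back prune*: adjacent segments whose means differ by fewer
  than `t_merge` (default 2.5) noise standard errors are re-merged,
  counteracting the winner's-curse fragments a liberal split threshold
  produces;
- a minimum segment size (default 5 bins) so single-bin noise outliers
  cannot be isolated into spurious high-amplitude segments. The minimum
  is waived for noise-free input, where exact changepoints are
  recoverable anywhere.

## Tumor-fraction estimation

A grid search over tf ∈ {0, 0.01, …, 0.9}: for each candidate tf every
segment is assigned the copy number in 0..6 minimizing the squared
deviation of its mean log-ratio from the mixture prediction, weighted by
its bin count. Two regularizations make this identifiable:

- **Diploid prior.** Each segment called non-diploid pays a BIC-style
  penalty `2 · σ² · ln(N)` plus a quarter of that per extra copy-number
  step. Without it, at low tf the copy-number ladder is finer than the
  segment-mean noise and the fit "explains" noise with spurious calls.
  The factor 2 is the extreme-value scale of the maximal spurious
  segment mean, so noise segments are priced out while genuine events
  (hundreds of bins) remain cheap to call. With noiseless input the
  penalty vanishes and the fit inverts the mixture exactly.
- **Degeneracy handling.** The mixture is exactly invariant under
  (tf, C) → (tf/k, k·(C−2)+2): tf = 0.4 with CN {3, 1} predicts the same
  log-ratios as tf = 0.2 with CN {4, 0}. The single-copy-change prior
  above systematically disprefers the inflated-deviation branch, and a
  final check climbs from tf to k·tf (k = 2, 3) when the two solutions
  are statistically tied and the higher-tf model is strictly closer to
  diploid. Ties that survive all of this resolve toward smaller tf,
  which avoids spurious positivity. A profile whose events are *all*
  even-numbered copies (only CN 4/0, no CN 3/1) remains genuinely
  unidentifiable; the simulator's default event levels (gains {3, 4},
  losses {1}) make that configuration vanishingly rare.

The all-diploid model is returned whenever its score is within 2%
(relative) of the best score — a guard against calling noise. The
detection threshold for ctDNA positivity is 0 (any tf > 0 is positive),
matching the study's status definition. Sensitivity is genuinely limited
at low tf: a single altered segment covering <1% of bins at tf ≈ 0.03
falls below both the segmentation threshold and the diploid guard, and
the sample is reported negative — the test suite asserts this
limitation rather than hiding it.

## Recurrent regions

Per-bin G score = cohort mean of `max(±logR − 0.1, 0)` (gains and losses
separately). Significance from a permutation null that applies an
independent random cyclic shift to each sample's genome-wide bin vector
— chosen over bin-label shuffling because it preserves within-sample
spatial autocorrelation — with `p = (1 + #{G* ≥ G})/(n_perm + 1)`,
Benjamini–Hochberg correction across bins, and significance at q < 0.25.
Contiguous significant bins (gaps of ≤ 1 bin allowed) merge into
regions. Peak deconvolution and gene-level annotation are out of scope;
there is no analogue of a peak "confidence level" here.

## Longitudinal concordance and the discrepancy bootstrap

A region's state in a profile is the length-weighted majority copy
number over its overlapping segments (ties resolve toward diploid, then
toward the smaller copy number): gained iff CN ≥ 3, lost iff CN ≤ 1.
Conservation semantics: the denominator of a region's concordance is the
set of pairs altered (in the region's direction) at baseline, the
numerator those still altered at progression. An all-pairs agreement
denominator is available behind a flag. Loss-vs-gain conservation is
compared by an unpaired two-sided Wilcoxon rank-sum over regions
(regions, not patients, as sampling units).

The progression-emergent test uses the statistic
`T = n_emergent − n_reverted`. The null swaps each discordant pair's
baseline/progression labels independently with probability ½ — the
minimal exchangeable null for paired discrepancies — so T* is a sum of
random signs, and `p = (1 + #{T* ≥ T})/(n_boot + 1)`, one-sided toward
emergence. For small numbers of discordant pairs this null is exactly
enumerable (2^d sign patterns), which the tests use as an oracle. The
null is *discrete*: with ~9 discordant pairs the attainable p-values
jump from ≈0.02 to ≈0.09, so the realized type-I error at the 0.05 level
is ≈0.02 — conservative by construction, never anti-conservative. No
multiplicity correction is applied across regions by default (BH is
available), since the analysis is exploratory.

## ddPCR

Standard Poisson partitioning: a target at concentration c copies/µL
loads a droplet of volume v µL with probability `1 − exp(−c·v)`, so
`c = −ln(1 − k/n)/v` from k positive droplets of n. Droplet volume
defaults to 0.00085 µL (vendor standard) and is configurable and
reported in every output. Wells merge by summing counts *before* the
Poisson correction — never by averaging per-well fractions. A timepoint
requires at least duplicate wells and is mutation-positive only with ≥ 2
merged mutant-positive droplets. Saturated wells (k = n) are an error:
the concentration is unbounded.

## Clinical statistics

Kaplan–Meier, log-rank and Cox proportional hazards are provided by
lifelines (Efron tie handling; Wald CIs and p-values). Fisher's exact
test is two-sided by the probability-mass rule; the Wilcoxon rank-sum is
exact by enumeration when min(n) ≤ 10 with no ties and a tie-corrected
normal approximation otherwise (both via scipy, oracle-checked against
brute-force enumeration in the tests). 6-month ORR is any CR/PR within 6
months; CBR additionally admits stable disease maintained through month
6 (no progression in the window and SD-or-better at ≥ 6 months).
Patients with no assessment in the window are not evaluable and are
excluded from denominators, which are always reported explicitly.
Week-7 kinetics: `cleared_or_stable_zero` iff the week-7 TF is at or
below the detection threshold, else `persistent_or_new`.

## The synthetic cohort generator

The generator's defaults are the study conditions the analysis assumes;
each is a fixed design choice, not a fitted quantity:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 44 | cohort size |
| `baseline_positive_prob` | 0.675 | baseline ctDNA positivity |
| `tf_distribution` | Beta(1.2, 4)·0.6 | TF of positive patients (mass at low TF, where sensitivity is limited) |
| `n_cna_events`, `event_length` | 5–12, 2–50 Mb | segmental events per tumor |
| `gain_cn_levels` / `loss_cn_levels` | {3, 4} / {1} | event copy numbers |
| `conserve_loss_prob` / `conserve_gain_prob` | 0.833 / 0.714 | per-event conservation at progression |
| `noise_sd` | 0.3 | per-bin log-ratio SD at 50 kb |
| `true_log_hr` | ln 3.45 | PFS log hazard ratio, ctDNA-positive vs negative |
| `baseline_hazard` | 0.014 /month | ctDNA-negative hazard (6-month PFS ≈ 92%) |
| `censor_time` | 18 months | administrative censoring |
| `response_prob`, `clearance_given_response` | 0.65, 0.64 | responder fraction; week-7 TF clearance among responders (joint clearance ≈ 41.6% of positives) |
| `true_rise_prob`, `false_rise_prob` | 0.95, 0.134 | TF rises at end of treatment given progression / no progression (PPV of a rising TF ≈ 86% under the hazard defaults) |
| `pathway_alt_prob` | 0.775 | tumors carrying a CNA at a PI3K/AKT/mTOR-pathway locus |
| `droplet_count`, `droplet_volume_ul` | 20 000, 0.00085 | ddPCR well geometry |

An exponential proportional-hazards model cannot simultaneously match a
92% / 68% six-month PFS split *and* a hazard ratio of 3.45 (the first
pair implies HR ≈ 4.6); the generator pins the hazard ratio and the
negative stratum, putting the positive stratum's 6-month PFS at ≈ 75%.

Week-7 and end-of-treatment TF trajectories are multiplicative draws
(responders ×U(0.25, 0.6) or cleared to 0; non-responders ×U(0.8, 2.0);
rising patients ×U(1.5, 3.0) floored to a strict increase), truncated at
the detection floor (0.02) and 0.9. The ddPCR mutant allele fraction
tracks TF/2 with 10% relative noise, reflecting one heterozygous driver
mutation per trackable patient. Patient-level randomness flows through
`SeedSequence` spawning, so cohorts are bit-reproducible from the seed
and per-stage pipeline streams are independent (counter-keyed spawn
keys).

What the generator does **not** emulate: read-level noise, GC bias,
subclonal mixtures, tumor-tissue sequencing, lesion-level response
assessment, or informative censoring. Tests passing on these cohorts
show the *analysis* is correct under the stated model, not that the
model captures every property of real plasma data.

## Problem sizes

Tests and the acceptance script run on scaled-down inputs chosen to keep
the statistical content intact: a 500-Mb four-chromosome genome (10 000
bins at 50 kb) with events of 5–40 Mb for profile-level checks, cohorts
of 100–1500 synthetic patients for rate and survival measurements
(survival-only cohorts skip genomic simulation via
`simulate_genomics=False`), 200 profiles for the TF-RMSE measurement,
1000 simulated cohorts for bootstrap calibration, and 100/500 replicates
for Cox recovery/coverage. The Cox recovery benchmark uses balanced
strata and a higher event rate (baseline hazard 0.08/month) than the
cohort defaults: the ±20% recovery window is a statement about the
estimator at ≈ 200+ events, and at the cohort default event rate the
sampling SE of log HR alone exceeds the window.

## Known limitations

- The TF estimator is a deliberate simplification of HMM-based tools
  (no subclones, no GC correction, no allele-specific states); it makes
  no attempt to match any specific tool's numerical output.
- Bin-level recurrence scoring cannot separate arm-level from focal
  events and reports no gene annotations.
- The sign-flip bootstrap's sidedness (toward emergence) and the
  absence of per-region multiplicity correction are analysis choices,
  flagged in the output, not statistical necessities.
- Concordance percentages on estimated (rather than true) copy numbers
  are attenuated by TF-estimation error at low TF; the pipeline reports
  whichever profiles it is given.
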