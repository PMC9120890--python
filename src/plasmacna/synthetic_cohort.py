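"""Synthetic plasma-ctDNA cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes — and full ground truth — so every stage is testable without any
sequencing data: per-patient tumor copy-number profiles (segmental gains
and losses on a binned genome), partial conservation of alterations at
progression (losses conserved more often than gains), tumor-fraction
trajectories over three timepoints (baseline, week 7, end of treatment),
droplet-PCR wells for patients with a trackable driver mutation (mutant
allele fraction tied to tumor fraction), and progression-free survival
whose hazard depends on baseline ctDNA status.

Default rates are the study conditions being emulated: 67.5% baseline
positivity, loss/gain conservation probabilities 0.833/0.714, a 6-month
progression-free survival of ~92% in ctDNA-negative patients with a
hazard ratio of 3.45 for ctDNA-positive patients, ~41.5% week-7 ctDNA
clearance among baseline-positive patients, a 77.5% rate of tumor
copy-number alterations touching PI3K/AKT/mTOR-pathway loci, and a
rising-TF-at-progression coupling giving a positive predictive value of
~86%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical_stats as cs
from .cn_profile import SEGMENT_COLUMNS, BinnedProfile, SegmentProfile, write_seg
from .ddpcr import DEFAULT_DROPLET_VOLUME_UL, DropletWell, simulate_droplets
from .genome import default_genome, make_bins

TIMEPOINTS = ("baseline", "week7", "eot")

#: PI3K/AKT/mTOR-pathway loci (hg19, 1-Mb windows rounded to 50-kb bins)
#: around MTOR (1p36), PIK3C2B (1q32), AKT3 (1q44), PIK3CA (3q26),
#: TSC1 (9q34), AKT1 (14q32), RPS6KB1 (17q23) and STK11/PIK3R2 (19p13).
DEFAULT_PATHWAY_LOCI: tuple[tuple[str, int, int], ...] = (
    ("chr1", 10_750_000, 11_750_000),
    ("chr1", 204_400_000, 205_400_000),
    ("chr1", 243_350_000, 244_350_000),
    ("chr3", 178_400_000, 179_400_000),
    ("chr9", 135_300_000, 136_300_000),
    ("chr14", 104_750_000, 105_750_000),
    ("chr17", 57_500_000, 58_500_000),
    ("chr19", 1_000_000, 18_500_000),
)


@dataclass
class SimConfig:
    """Knobs of the cohort generator; defaults are the emulated study
    conditions (see module docstring)."""

    n_patients: int = 44
    bin_size_bp: int = 50_000
    genome: list[tuple[str, int]] | None = None
    baseline_positive_prob: float = 0.675
    tf_distribution: tuple[str, tuple[float, ...]] = ("beta", (1.2, 4.0, 0.6))
    n_cna_events: tuple[int, int] = (5, 12)
    event_length: tuple[int, int] = (2_000_000, 50_000_000)
    gain_cn_levels: tuple[int, ...] = (3, 4)
    loss_cn_levels: tuple[int, ...] = (1,)
    conserve_loss_prob: float = 0.833
    conserve_gain_prob: float = 0.714
    n_emergent_events: tuple[int, int] = (1, 4)
    noise_sd: float = 0.3
    true_log_hr: float = math.log(3.45)
    baseline_hazard: float = 0.014  # events/month in ctDNA-negative patients
    censor_time: float = 18.0  # months of administrative censoring
    droplet_count: int = 20_000
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    seed: int = 0
    # trajectory / clinical structure
    response_prob: float = 0.65
    clearance_given_response: float = 0.64
    true_rise_prob: float = 0.95
    false_rise_prob: float = 0.134
    new_positive_week7_prob: float = 0.08
    pathway_alt_prob: float = 0.775
    pathway_loci: tuple[tuple[str, int, int], ...] = DEFAULT_PATHWAY_LOCI
    mutation_assay_prob: float = 0.5
    cfdna_copies_per_ul: float = 3000.0
    detection_floor: float = 0.02
    min_logr: float = -8.0
    render_profiles: bool = True
    #: skip tumor-profile/evolution truth entirely (clinical-only cohorts)
    simulate_genomics: bool = True

    def __post_init__(self) -> None:
        if self.genome is None:
            self.genome = default_genome(self.bin_size_bp)
        # keep only pathway loci that exist on this genome
        sizes = dict(self.genome)
        self.pathway_loci = tuple(
            (c, lo, hi) for c, lo, hi in self.pathway_loci
            if c in sizes and hi <= sizes[c]
        )
        self.validate()

    def validate(self) -> None:
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")
        if not self.genome:
            raise ValueError("genome must be non-empty")
        if self.droplet_volume_ul <= 0:
            raise ValueError("droplet_volume_ul must be positive")
        for name in (
            "baseline_positive_prob", "conserve_loss_prob", "conserve_gain_prob",
            "response_prob", "clearance_given_response", "true_rise_prob",
            "false_rise_prob", "new_positive_week7_prob", "pathway_alt_prob",
            "mutation_assay_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(cn < 3 for cn in self.gain_cn_levels):
            raise ValueError("gain CN levels must be >= 3")
        if any(cn > 1 or cn < 0 for cn in self.loss_cn_levels):
            raise ValueError("loss CN levels must be in {0, 1}")
        lo, hi = self.n_cna_events
        if lo < 0 or hi < lo:
            raise ValueError("invalid n_cna_events range")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["genome"] = [list(g) for g in self.genome]
        d["pathway_loci"] = [list(x) for x in self.pathway_loci]
        return d


# ---------------------------------------------------------------------------
# Tumor profile simulation
# ---------------------------------------------------------------------------

def _round_bin(x: int, bin_size: int) -> int:
    return int(round(x / bin_size)) * bin_size


def _overlaps(a_chrom, a_start, a_end, events) -> bool:
    return any(
        c == a_chrom and a_start < e and s < a_end for c, s, e, *_ in events
    )


def _events_to_profile(
    sample_id: str, genome, bin_size: int, events
) -> SegmentProfile:
    """Tile the genome into diploid background plus the given events."""
    rows = []
    by_chrom: dict[str, list] = {}
    for ev in events:
        by_chrom.setdefault(ev[0], []).append(ev)
    for chrom, length in genome:
        evs = sorted(by_chrom.get(chrom, []), key=lambda e: e[1])
        pos = 0
        for _, s, e, cn in evs:
            if s > pos:
                rows.append((chrom, pos, s, 2))
            rows.append((chrom, s, e, cn))
            pos = e
        if pos < length:
            rows.append((chrom, pos, length, 2))
    seg = pd.DataFrame(
        [
            (
                c, s, e, max(1, math.ceil((e - s) / bin_size)),
                # canonical pure-tumor log-ratio, floored for CN=0
                max(math.log2(cn / 2.0) if cn > 0 else -8.0, -8.0),
                float(cn),
            )
            for c, s, e, cn in rows
        ],
        columns=SEGMENT_COLUMNS,
    )
    return SegmentProfile(sample_id, seg)


def _place_events(
    config: SimConfig,
    rng: np.random.Generator,
    n_events: int,
    existing: list,
    forbidden_loci=None,
) -> list:
    """Sample non-overlapping bin-aligned events; raises after bounded
    retries when the configuration is too dense to place."""
    genome = config.genome
    lengths = np.array([l for _, l in genome], dtype=float)
    probs = lengths / lengths.sum()
    events = list(existing)
    placed = []
    tries = 0
    max_tries = 200 * (n_events + 1)
    while len(placed) < n_events:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place copy-number events: configuration too dense"
            )
        ci = int(rng.choice(len(genome), p=probs))
        chrom, chrom_len = genome[ci]
        length = _round_bin(
            int(rng.integers(config.event_length[0], config.event_length[1] + 1)),
            config.bin_size_bp,
        )
        length = max(length, config.bin_size_bp)
        if length > chrom_len:
            continue  # event longer than the chromosome: resample
        start = _round_bin(int(rng.integers(0, chrom_len - length + 1)), config.bin_size_bp)
        end = min(start + length, chrom_len)
        if _overlaps(chrom, start, end, events):
            continue
        if forbidden_loci and _overlaps(chrom, start, end, [(c, s, e, None) for c, s, e in forbidden_loci]):
            continue
        if rng.random() < 0.5:
            cn = int(rng.choice(config.gain_cn_levels))
        else:
            cn = int(rng.choice(config.loss_cn_levels))
        ev = (chrom, start, end, cn)
        events.append(ev)
        placed.append(ev)
    return placed


def simulate_tumor_profile(
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "tumor",
    required_loci=None,
    forbidden_loci=None,
) -> SegmentProfile:
    """Simulate a tumor copy-number profile: a diploid background with a
    random number of non-overlapping bin-aligned gains and losses.

    ``required_loci`` forces the first event to overlap one (randomly
    chosen) locus; ``forbidden_loci`` excludes events from the listed
    intervals.
    """
    n_events = int(rng.integers(config.n_cna_events[0], config.n_cna_events[1] + 1))
    events: list = []
    if required_loci and n_events > 0:
        chrom, lo, hi = required_loci[int(rng.integers(0, len(required_loci)))]
        chrom_len = dict(config.genome)[chrom]
        length = _round_bin(
            int(rng.integers(config.event_length[0], config.event_length[1] + 1)),
            config.bin_size_bp,
        )
        length = min(max(length, config.bin_size_bp), chrom_len)
        mid = (lo + hi) // 2
        start = _round_bin(max(0, min(mid - length // 2, chrom_len - length)), config.bin_size_bp)
        end = min(start + length, chrom_len)
        if rng.random() < 0.5:
            cn = int(rng.choice(config.gain_cn_levels))
        else:
            cn = int(rng.choice(config.loss_cn_levels))
        events.append((chrom, start, end, cn))
        n_events -= 1
    events += _place_events(config, rng, n_events, events, forbidden_loci)
    return _events_to_profile(sample_id, config.genome, config.bin_size_bp, events)


def evolve_profile(
    baseline: SegmentProfile, config: SimConfig, rng: np.random.Generator
) -> tuple[SegmentProfile, list[dict]]:
    """Evolve a baseline profile to progression.

    Each baseline gain is retained with probability
    ``conserve_gain_prob`` and each loss with ``conserve_loss_prob``
    (reverted events return to CN = 2); new emergent events are placed in
    regions that were background at baseline.  Returns the progression
    profile and an event ledger (conserved / reverted / emergent).
    """
    seg = baseline.segments
    baseline_events = [
        (str(r.chrom), int(r.start), int(r.end), int(r.cn))
        for r in seg.itertuples(index=False)
        if not np.isnan(r.cn) and int(r.cn) != 2
    ]
    ledger: list[dict] = []
    kept: list = []
    for chrom, start, end, cn in baseline_events:
        direction = "gain" if cn >= 3 else "loss"
        p_keep = config.conserve_gain_prob if direction == "gain" else config.conserve_loss_prob
        fate = "conserved" if rng.random() < p_keep else "reverted"
        if fate == "conserved":
            kept.append((chrom, start, end, cn))
        ledger.append(
            {"chrom": chrom, "start": start, "end": end, "cn": cn,
             "direction": direction, "fate": fate}
        )
    n_new = int(rng.integers(config.n_emergent_events[0], config.n_emergent_events[1] + 1))
    # emergent events must avoid every baseline event (even reverted ones)
    occupied = list(baseline_events) + kept
    emergent = _place_events(config, rng, n_new, occupied)
    for chrom, start, end, cn in emergent:
        ledger.append(
            {"chrom": chrom, "start": start, "end": end, "cn": cn,
             "direction": "gain" if cn >= 3 else "loss", "fate": "emergent"}
        )
    profile = _events_to_profile(
        baseline.sample_id + "_prog", config.genome, config.bin_size_bp, kept + emergent
    )
    return profile, ledger


def render_logR(
    profile: SegmentProfile,
    tf: float,
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str | None = None,
) -> BinnedProfile:
    """Render a tumor profile into a binned plasma log-ratio profile at
    tumor fraction ``tf``: logR = log2(tf*CN/2 + (1-tf)) + N(0, noise_sd),
    floored at ``min_logr``."""
    if not 0 <= tf < 1:
        raise ValueError("tf must be in [0, 1)")
    bins = make_bins(config.genome, config.bin_size_bp)
    seg = profile.segments
    cn = np.empty(len(bins))
    bin_chroms = bins["chrom"].to_numpy()
    bin_starts = bins["start"].to_numpy()
    for chrom, sub in seg.groupby("chrom", sort=False):
        mask = bin_chroms == chrom
        idx = np.searchsorted(sub["start"].to_numpy(), bin_starts[mask], side="right") - 1
        cn[mask] = sub["cn"].to_numpy(dtype=float)[idx]
    mix = tf * cn / 2.0 + (1.0 - tf)
    logr = np.maximum(np.log2(np.maximum(mix, 2.0 ** config.min_logr)), config.min_logr)
    if config.noise_sd > 0:
        logr = logr + rng.normal(0.0, config.noise_sd, size=len(bins))
    out = bins.copy()
    out["logr"] = logr
    return BinnedProfile(sample_id or profile.sample_id, out)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class PlasmaSample:
    patient_id: str
    timepoint: str
    tf: float
    profile: BinnedProfile | None = None
    truth_segments: SegmentProfile | None = None
    wells: list[DropletWell] | None = None
    maf_true: float | None = None


@dataclass
class Patient:
    patient_id: str
    arm: str
    hr_positive: bool
    n_met_sites_ge3: bool
    visceral: bool
    pfs_months: float
    pfs_event: int
    assessments: list[tuple[float, str]]
    response_6m: bool | None
    cbr_6m: bool | None
    samples: dict[str, PlasmaSample] = field(default_factory=dict)


@dataclass
class Cohort:
    patients: list[Patient]
    config: SimConfig

    def to_clinical_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            tf = {tp: (p.samples[tp].tf if tp in p.samples else None) for tp in TIMEPOINTS}
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "arm": p.arm,
                    "hr_status": int(p.hr_positive),
                    "n_met_sites": int(p.n_met_sites_ge3),
                    "visceral": int(p.visceral),
                    "pfs_months": p.pfs_months,
                    "pfs_event": p.pfs_event,
                    "response_6m": p.response_6m,
                    "cbr_6m": p.cbr_6m,
                    "tf_baseline": tf["baseline"],
                    "tf_week7": tf["week7"],
                    "tf_eot": tf["eot"],
                    "ctdna_baseline": int(tf["baseline"] is not None and tf["baseline"] > 0),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PatientTruth:
    tf: dict[str, float]
    status: dict[str, str]
    baseline_segments: SegmentProfile
    progression_segments: SegmentProfile
    event_ledger: list[dict]
    maf: dict[str, float]
    pfs_months: float
    pfs_event: int
    responder: bool
    rising_at_eot: bool
    pathway_alt: bool


@dataclass
class GroundTruth:
    records: dict[str, PatientTruth]

    def __post_init__(self) -> None:
        for pid, rec in self.records.items():
            for tp, tf in rec.tf.items():
                if not 0 <= tf < 1:
                    raise ValueError(f"truth TF out of [0,1) for {pid}/{tp}")
            if rec.pfs_event and rec.pfs_months < 0:
                raise ValueError(f"negative event time for {pid}")


def _draw_tf(config: SimConfig, rng: np.random.Generator) -> float:
    family, params = config.tf_distribution
    if family == "beta":
        a, b, scale = params
        tf = float(rng.beta(a, b)) * scale
    elif family == "uniform":
        lo, hi = params
        tf = float(rng.uniform(lo, hi))
    else:
        raise ValueError(f"unknown tf distribution family {family!r}")
    return min(max(tf, config.detection_floor), 0.89)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Simulate a full cohort with ground truth; fully reproducible from
    ``config.seed``.

    Per patient: baseline ctDNA positivity, a tumor copy-number profile
    (pathway-locus involvement with probability ``pathway_alt_prob``),
    tumor-fraction trajectories over three timepoints (responders decline
    or clear, non-responders persist or rise; TF rises at the end of
    treatment for most progressing patients), exponential PFS with
    log-hazard ``log(baseline_hazard) + true_log_hr * 1[ctDNA-positive]``
    administratively censored at ``censor_time``, and duplicate ddPCR
    wells when a trackable mutation is assigned (true MAF = TF/2 up to
    noise).
    """
    if config.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(config.n_patients)
    patients: list[Patient] = []
    records: dict[str, PatientTruth] = {}

    for i in range(config.n_patients):
        rng = np.random.default_rng(patient_seeds[i])
        pid = f"PT{i + 1:04d}"

        positive = rng.random() < config.baseline_positive_prob
        tf_base = _draw_tf(config, rng) if positive else 0.0
        responder = rng.random() < config.response_prob

        # week-7 trajectory
        if positive:
            if responder and rng.random() < config.clearance_given_response:
                tf_w7 = 0.0
            elif responder:
                tf_w7 = max(tf_base * rng.uniform(0.25, 0.6), config.detection_floor)
            else:
                tf_w7 = min(max(tf_base * rng.uniform(0.8, 2.0), config.detection_floor), 0.85)
        else:
            tf_w7 = (
                rng.uniform(config.detection_floor, 0.1)
                if rng.random() < config.new_positive_week7_prob
                else 0.0
            )

        # PFS: exponential, hazard multiplied by exp(log HR) when positive
        hazard = config.baseline_hazard * math.exp(config.true_log_hr * positive)
        t = rng.exponential(1.0 / hazard)
        pfs_event = int(t <= config.censor_time)
        pfs_months = min(t, config.censor_time)

        # end-of-treatment trajectory, coupled to progression
        rising = (
            rng.random() < config.true_rise_prob
            if pfs_event
            else rng.random() < config.false_rise_prob
        )
        if rising:
            base = tf_w7 if tf_w7 > 0 else config.detection_floor
            tf_eot = min(max(base * rng.uniform(1.5, 3.0), tf_w7 + 0.03), 0.89)
        else:
            tf_eot = tf_w7 * rng.uniform(0.3, 0.9) if tf_w7 > 0 else 0.0
            if 0 < tf_eot < config.detection_floor:
                tf_eot = 0.0

        # response assessments -> endpoints
        assessments: list[tuple[float, str]] = []
        if responder:
            if pfs_months > 1.6 or not pfs_event:
                assessments.append((1.6, "PR"))
            if pfs_months > 6.0:
                assessments.append((6.0, "SD"))
        else:
            for m in (1.6, 3.5, 6.0):
                if m < pfs_months:
                    assessments.append((m, "SD"))
        if pfs_event and pfs_months <= 6.0:
            assessments.append((round(pfs_months, 2), "PD"))
        response = cs.orr_6m(assessments) if assessments else None
        cbr = cs.cbr_6m(assessments) if assessments else None

        # tumor genomic truth
        pathway_alt = rng.random() < config.pathway_alt_prob
        if config.simulate_genomics:
            baseline_truth = simulate_tumor_profile(
                config,
                rng,
                sample_id=f"{pid}_baseline",
                required_loci=config.pathway_loci if pathway_alt else None,
                forbidden_loci=None if pathway_alt else config.pathway_loci,
            )
            progression_truth, ledger = evolve_profile(baseline_truth, config, rng)
        else:
            baseline_truth = _events_to_profile(
                f"{pid}_baseline", config.genome, config.bin_size_bp, []
            )
            progression_truth, ledger = baseline_truth, []

        # ddPCR
        has_assay = rng.random() < config.mutation_assay_prob
        tf_by_tp = {"baseline": tf_base, "week7": tf_w7, "eot": tf_eot}
        maf_by_tp: dict[str, float] = {}
        wells_by_tp: dict[str, list[DropletWell] | None] = {}
        for tp, tf in tf_by_tp.items():
            if has_assay:
                maf = max(0.0, tf / 2.0 * (1.0 + 0.1 * rng.normal()))
                maf_by_tp[tp] = maf
                wells_by_tp[tp] = [
                    simulate_droplets(
                        maf, config.cfdna_copies_per_ul, config.droplet_count,
                        config.droplet_volume_ul, rng,
                    )
                    for _ in range(2)
                ]
            else:
                wells_by_tp[tp] = None

        # rendered plasma profiles
        samples: dict[str, PlasmaSample] = {}
        for tp, tf in tf_by_tp.items():
            truth_seg = progression_truth if (tp == "eot" and pfs_event) else baseline_truth
            profile = (
                render_logR(truth_seg, tf, config, rng, sample_id=f"{pid}_{tp}")
                if config.render_profiles
                else None
            )
            samples[tp] = PlasmaSample(
                patient_id=pid,
                timepoint=tp,
                tf=tf,
                profile=profile,
                truth_segments=truth_seg,
                wells=wells_by_tp[tp],
                maf_true=maf_by_tp.get(tp),
            )

        patients.append(
            Patient(
                patient_id=pid,
                arm="phase2",
                hr_positive=bool(rng.random() < 0.7),
                n_met_sites_ge3=bool(rng.random() < 0.35),
                visceral=bool(rng.random() < 0.6),
                pfs_months=float(pfs_months),
                pfs_event=pfs_event,
                assessments=assessments,
                response_6m=response,
                cbr_6m=cbr,
                samples=samples,
            )
        )
        records[pid] = PatientTruth(
            tf=tf_by_tp,
            status={tp: ("positive" if tf > 0 else "negative") for tp, tf in tf_by_tp.items()},
            baseline_segments=baseline_truth,
            progression_segments=progression_truth,
            event_ledger=ledger,
            maf=maf_by_tp,
            pfs_months=float(pfs_months),
            pfs_event=pfs_event,
            responder=responder,
            rising_at_eot=rising,
            pathway_alt=pathway_alt,
        )

    return Cohort(patients, config), GroundTruth(records)


def overlaps_loci(profile: SegmentProfile, loci) -> bool:
    """True when any non-diploid segment of ``profile`` overlaps any of
    the given ``(chrom, start, end)`` loci."""
    seg = profile.segments
    altered = seg[(~seg["cn"].isna()) & (seg["cn"] != 2)]
    for r in altered.itertuples(index=False):
        for chrom, lo, hi in loci:
            if r.chrom == chrom and r.start < hi and lo < r.end:
                return True
    return False


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir) -> None:
    """Persist a simulated cohort: clinical TSV, per-sample truth SEG
    files, and a JSON truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_clinical_frame().to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    segdir = outdir / "seg"
    segdir.mkdir(exist_ok=True)
    for p in cohort.patients:
        for tp, s in p.samples.items():
            if s.truth_segments is not None:
                write_seg(s.truth_segments, segdir / f"{p.patient_id}_{tp}.seg")
    summary = {
        pid: {
            "tf": rec.tf,
            "status": rec.status,
            "pfs_months": rec.pfs_months,
            "pfs_event": rec.pfs_event,
            "responder": rec.responder,
            "rising_at_eot": rec.rising_at_eot,
            "pathway_alt": rec.pathway_alt,
            "maf": rec.maf,
            "event_ledger": rec.event_ledger,
        }
        for pid, rec in truth.records.items()
    }
    (outdir / "truth.json").write_text(json.dumps(summary, indent=1))
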