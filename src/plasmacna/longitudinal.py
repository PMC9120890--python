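"""Baseline-vs-progression analysis of paired plasma copy-number profiles.

For each recurrent region, a paired sample is *conserved* when the
alteration present at baseline (gain: copy number >= 3; loss: copy
number <= 1) is still present at progression.  The module computes
per-region concordance percentages, compares conservation of losses vs
gains (Wilcoxon rank-sum over regions), and tests for an excess of
progression-emergent alterations with a sign-flip bootstrap: under the
null, each discordant pair's baseline/progression labels are swapped
independently with probability 1/2, so the emergent-minus-reverted
statistic is a sum of random signs.  Also provides tumor-fraction
dynamics categories and the positive predictive value of a rising TF for
radiological progression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clinical_stats import wilcoxon_ranksum
from .cn_profile import SegmentProfile
from .recurrence import Region

GAIN_CN_MIN = 3
LOSS_CN_MAX = 1


@dataclass
class PairedSample:
    """Baseline and progression segment profiles (with copy numbers) of
    one patient, on the same genome."""

    patient_id: str
    baseline: SegmentProfile
    progression: SegmentProfile

    def __post_init__(self) -> None:
        for name, prof in (("baseline", self.baseline), ("progression", self.progression)):
            if not prof.has_cn:
                raise ValueError(f"{name} profile of {self.patient_id} lacks copy numbers")


@dataclass
class ConcordanceResult:
    region: Region
    direction: str
    n_baseline_altered: int
    n_conserved: int
    concordance_pct: float | None  # None when no pair is altered at baseline

    @property
    def defined(self) -> bool:
        return self.concordance_pct is not None


@dataclass
class DiscrepancyTest:
    region: Region
    n_emergent: int
    n_reverted: int
    statistic: int
    p_boot: float
    n_boot: int


def region_state(profile: SegmentProfile, region: Region) -> str:
    """Copy-number state of a region: length-weighted majority CN over
    the overlapping segments; ``gained`` iff CN >= 3, ``lost`` iff
    CN <= 1, else ``neutral``."""
    seg = profile.segments
    sub = seg[seg["chrom"] == region.chrom]
    ov = np.minimum(sub["end"].to_numpy(), region.end) - np.maximum(
        sub["start"].to_numpy(), region.start
    )
    mask = ov > 0
    if not mask.any():
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} does not overlap "
            f"profile {profile.sample_id}"
        )
    cns = sub["cn"].to_numpy(dtype=float)[mask]
    weights = ov[mask].astype(float)
    if np.isnan(cns).any():
        raise ValueError("region_state requires assigned copy numbers")
    totals: dict[int, float] = {}
    for cn, w in zip(cns.astype(int), weights):
        totals[cn] = totals.get(cn, 0.0) + w
    # majority CN; ties resolved toward the value closest to diploid,
    # then toward the smaller CN, for determinism
    cn = min(totals, key=lambda c: (-totals[c], abs(c - 2), c))
    if cn >= GAIN_CN_MIN:
        return "gained"
    if cn <= LOSS_CN_MAX:
        return "lost"
    return "neutral"


def _altered(state: str, direction: str) -> bool:
    return state == ("gained" if direction == "gain" else "lost")


def region_concordance(
    pairs: list[PairedSample], region: Region, denominator: str = "baseline"
) -> ConcordanceResult:
    """Per-region conservation between baseline and progression.

    With the default ``denominator="baseline"`` (conservation
    semantics), the denominator is the number of pairs altered at
    baseline in the region's direction and the numerator those still
    altered at progression.  ``denominator="all"`` instead scores
    agreement of the two states over every pair.
    """
    if not pairs:
        raise ValueError("need at least one paired sample")
    if denominator not in ("baseline", "all"):
        raise ValueError("denominator must be 'baseline' or 'all'")
    n_denom = 0
    n_num = 0
    for pair in pairs:
        b = _altered(region_state(pair.baseline, region), region.direction)
        p = _altered(region_state(pair.progression, region), region.direction)
        if denominator == "baseline":
            if b:
                n_denom += 1
                n_num += b and p
        else:
            n_denom += 1
            n_num += b == p
    pct = 100.0 * n_num / n_denom if n_denom > 0 else None
    return ConcordanceResult(
        region=region,
        direction=region.direction,
        n_baseline_altered=n_denom,
        n_conserved=n_num,
        concordance_pct=pct,
    )


def conservation_by_direction(
    results: list[ConcordanceResult],
) -> tuple[float, float, float]:
    """Median conservation of losses vs gains across regions, with a
    two-sided Wilcoxon rank-sum p-value (regions as sampling units).

    Returns ``(median_loss_pct, median_gain_pct, p)``.
    """
    loss = [r.concordance_pct for r in results if r.direction == "loss" and r.defined]
    gain = [r.concordance_pct for r in results if r.direction == "gain" and r.defined]
    if not loss or not gain:
        raise ValueError("need at least one defined region per direction")
    p = wilcoxon_ranksum(loss, gain)
    return float(np.median(loss)), float(np.median(gain)), p


def discrepancy_bootstrap(
    pairs: list[PairedSample],
    region: Region,
    n_boot: int = 9999,
    rng: np.random.Generator | None = None,
) -> DiscrepancyTest:
    """Sign-flip bootstrap for progression-emergent alterations.

    The observed statistic is ``n_emergent - n_reverted`` (pairs altered
    at progression only minus pairs altered at baseline only).  The null
    swaps each discordant pair's two labels independently with
    probability 1/2 (concordant pairs contribute 0 either way), and
    ``p = (1 + #{T* >= T_obs}) / (n_boot + 1)``, one-sided toward
    emergence.  With no discordant pairs the statistic is 0 and p = 1.
    """
    if n_boot < 999:
        raise ValueError("n_boot must be >= 999")
    rng = np.random.default_rng() if rng is None else rng
    signs = []
    for pair in pairs:
        b = _altered(region_state(pair.baseline, region), region.direction)
        p = _altered(region_state(pair.progression, region), region.direction)
        if p and not b:
            signs.append(1)
        elif b and not p:
            signs.append(-1)
    n_emergent = signs.count(1)
    n_reverted = signs.count(-1)
    t_obs = n_emergent - n_reverted
    if not signs:
        return DiscrepancyTest(region, 0, 0, 0, 1.0, n_boot)
    d = len(signs)
    flips = rng.integers(0, 2, size=(n_boot, d)) * 2 - 1
    t_null = flips.sum(axis=1)
    p_boot = (1.0 + int((t_null >= t_obs).sum())) / (n_boot + 1.0)
    return DiscrepancyTest(region, n_emergent, n_reverted, t_obs, p_boot, n_boot)


def exact_signflip_p(n_emergent: int, n_reverted: int) -> float:
    """Exact enumeration of the sign-flip null: probability that a sum of
    ``d`` independent random signs is at least ``n_emergent - n_reverted``.
    Small-sample oracle for :func:`discrepancy_bootstrap`."""
    d = n_emergent + n_reverted
    t_obs = n_emergent - n_reverted
    if d == 0:
        return 1.0
    from math import comb

    # sum of d signs = 2k - d where k = number of +1 flips
    count = sum(comb(d, k) for k in range(d + 1) if 2 * k - d >= t_obs)
    return count / 2 ** d


# ---------------------------------------------------------------------------
# Tumor-fraction dynamics
# ---------------------------------------------------------------------------

def tf_dynamics(tf_by_timepoint, delta: float = 0.0) -> str:
    """Direction of the last tumor-fraction change: ``rising`` when the
    last TF exceeds the previous by more than ``delta``, ``falling`` when
    below by more than ``delta``, else ``stable``."""
    tfs = [t for t in tf_by_timepoint if t is not None]
    if len(tfs) < 2:
        raise ValueError("tf_dynamics requires at least two timepoints")
    prev, last = tfs[-2], tfs[-1]
    if last > prev + delta:
        return "rising"
    if last < prev - delta:
        return "falling"
    return "stable"


@dataclass
class PPVResult:
    """PPV of a rising tumor fraction for radiological progression, with
    an explicit denominator ledger."""

    ppv: float | None
    n_rising: int
    n_rising_progressed: int
    n_evaluable: int
    n_excluded: int


def ppv_at_progression(records, delta: float = 0.0) -> PPVResult:
    """Positive predictive value of rising TF at the last timepoint.

    ``records`` is an iterable of ``(patient_id, tf_sequence,
    progressed)``; patients with fewer than two TF measurements or a
    missing progression flag are excluded and counted.
    """
    n_rising = n_rising_prog = n_eval = n_excl = 0
    for _pid, tfs, progressed in records:
        tfs = [t for t in tfs if t is not None]
        if len(tfs) < 2 or progressed is None:
            n_excl += 1
            continue
        n_eval += 1
        if tf_dynamics(tfs, delta) == "rising":
            n_rising += 1
            n_rising_prog += bool(progressed)
    ppv = n_rising_prog / n_rising if n_rising > 0 else None
    return PPVResult(ppv, n_rising, n_rising_prog, n_eval, n_excl)
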