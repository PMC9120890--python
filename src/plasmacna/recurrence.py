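"""Recurrently altered regions across a cohort of copy-number profiles.

A simplified GISTIC-style scan: each bin receives a G score equal to the
cohort mean of the log-ratio exceedance over an amplitude threshold
(default 0.1), separately for gains and losses.  Significance comes from
a permutation null that cyclically shifts each sample's genome-wide bin
vector by an independent random offset (preserving within-sample spatial
correlation), with Benjamini-Hochberg correction across bins; bins with
q < 0.25 are merged into regions.

GISTIC's peak deconvolution and its "confidence level" parameter have no
analogue here and are intentionally not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cn_profile import BinnedProfile

DEFAULT_AMP_THRESHOLD = 0.1
DEFAULT_Q_THRESHOLD = 0.25


@dataclass(frozen=True)
class Region:
    """A recurrently gained or lost genomic region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    direction: str  # "gain" | "loss"
    g_score: float
    q_value: float
    n_bins: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must be < end")
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if not 0 <= self.q_value <= 1:
            raise ValueError("q_value must be in [0, 1]")


def _exceedance_matrix(
    profiles: list[BinnedProfile], direction: str, amp_threshold: float
) -> np.ndarray:
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    ref = profiles[0]
    for p in profiles[1:]:
        if not ref.same_grid(p):
            raise ValueError(f"profile {p.sample_id} is not on the shared bin grid")
    sign = 1.0 if direction == "gain" else -1.0
    M = np.stack([p.bins["logr"].to_numpy(dtype=float) for p in profiles])
    return np.maximum(sign * M - amp_threshold, 0.0)


def gscore_bins(
    profiles: list[BinnedProfile],
    direction: str,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> np.ndarray:
    """Per-bin G score: cohort mean of max(+/-logR - threshold, 0)."""
    return _exceedance_matrix(profiles, direction, amp_threshold).mean(axis=0)


def permutation_null(
    profiles: list[BinnedProfile],
    direction: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation p- and BH q-values for the per-bin G scores.

    Each permutation applies an independent random cyclic shift to every
    sample's bin vector; ``p = (1 + #{G* >= G}) / (n_perm + 1)``.
    Returns ``(g_obs, p, q)``; deterministic given ``rng``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng() if rng is None else rng
    E = _exceedance_matrix(profiles, direction, amp_threshold)
    n_samples, n_bins = E.shape
    g_obs = E.mean(axis=0)
    exceed_counts = np.zeros(n_bins, dtype=np.int64)
    for _ in range(n_perm):
        shifts = rng.integers(0, n_bins, size=n_samples)
        g_perm = np.zeros(n_bins)
        for s in range(n_samples):
            g_perm += np.roll(E[s], shifts[s])
        g_perm /= n_samples
        exceed_counts += g_perm >= g_obs - 1e-15
    p = (1.0 + exceed_counts) / (n_perm + 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return g_obs, p, q


def extract_regions(
    bins: pd.DataFrame,
    q_values: np.ndarray,
    g_scores: np.ndarray,
    direction: str,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    gap_bins: int = 1,
) -> list[Region]:
    """Merge runs of significant bins (q < threshold) into regions.

    Adjacent runs on the same chromosome separated by at most
    ``gap_bins`` non-significant bins are merged.  A region carries the
    maximum G score and minimum q of its bins.
    """
    q_values = np.asarray(q_values, dtype=float)
    g_scores = np.asarray(g_scores, dtype=float)
    if len(bins) != len(q_values) or len(bins) != len(g_scores):
        raise ValueError("bins, q_values and g_scores must align")
    sig = q_values < q_threshold
    regions: list[Region] = []
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        sig_idx = idx[sig[idx]]
        if len(sig_idx) == 0:
            continue
        # group significant bins, merging gaps of <= gap_bins
        run_start = sig_idx[0]
        prev = sig_idx[0]
        runs = []
        for i in sig_idx[1:]:
            if i - prev - 1 > gap_bins:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for lo, hi in runs:
            members = np.arange(lo, hi + 1)
            members = members[sig[members]]
            regions.append(
                Region(
                    chrom=str(chrom),
                    start=int(starts[lo]),
                    end=int(ends[hi]),
                    direction=direction,
                    g_score=float(g_scores[members].max()),
                    q_value=float(q_values[members].min()),
                    n_bins=int(hi - lo + 1),
                )
            )
    return regions


def find_recurrent_regions(
    profiles: list[BinnedProfile],
    directions: tuple[str, ...] = ("gain", "loss"),
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    gap_bins: int = 1,
) -> list[Region]:
    """Run the full scan (G score, permutation null, region extraction)
    for each direction and return the combined region list."""
    rng = np.random.default_rng() if rng is None else rng
    bins = profiles[0].bins[["chrom", "start", "end"]]
    out: list[Region] = []
    for direction in directions:
        g, _, q = permutation_null(
            profiles, direction, n_perm=n_perm, rng=rng, amp_threshold=amp_threshold
        )
        out.extend(extract_regions(bins, q, g, direction, q_threshold, gap_bins))
    return out


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    """Region list as a BED-style DataFrame (0-based half-open)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "direction": r.direction,
                "g_score": r.g_score,
                "q_value": r.q_value,
                "n_bins": r.n_bins,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "direction", "g_score", "q_value", "n_bins"],
    )
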