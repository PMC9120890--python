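"""Binned and segmented copy-number profiles, tumor-fraction estimation.

A plasma sample sequenced at low coverage yields one log2 read-depth
ratio per fixed-size genomic bin.  A tumor shedding a fraction ``tf`` of
the circulating DNA shifts the expected log-ratio of a region with
integer tumor copy number ``CN`` to

    logR = log2(tf * CN / 2 + (1 - tf))

This module provides the profile containers, SEG-format I/O, a
change-point segmentation of the binned log-ratios, and a grid-search
tumor-fraction estimator that inverts the mixture formula jointly over
``tf`` and the per-segment copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_COLUMNS = ["chrom", "start", "end", "logr"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "n_bins", "logr", "cn"]

#: log2-ratio floor applied to homozygous deletions at high tumor fraction
MIN_LOGR = -8.0


def _check_sorted_disjoint(df: pd.DataFrame, what: str) -> None:
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValueError(f"{what}: end <= start at row {bad}")
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if not (starts[1:] >= ends[:-1]).all():
            raise ValueError(f"{what}: overlapping or unsorted intervals on {chrom}")


@dataclass
class BinnedProfile:
    """Per-bin log2-ratio profile of one sample.

    Parameters
    ----------
    sample_id :
        Sample identifier.
    bins :
        DataFrame with columns ``chrom``, ``start``, ``end`` (0-based
        half-open) and ``logr``; non-overlapping and sorted within each
        chromosome.
    """

    sample_id: str
    bins: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BIN_COLUMNS if c not in self.bins.columns]
        if missing:
            raise ValueError(f"bins missing columns {missing}")
        self.bins = self.bins.reset_index(drop=True)
        if len(self.bins) == 0:
            raise ValueError("profile has no bins")
        if not np.isfinite(self.bins["logr"].to_numpy(dtype=float)).all():
            raise ValueError("logr must be finite (floor extreme values)")
        _check_sorted_disjoint(self.bins, "bins")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def same_grid(self, other: "BinnedProfile") -> bool:
        a, b = self.bins, other.bins
        if len(a) != len(b):
            return False
        return (
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )


@dataclass
class SegmentProfile:
    """Segmented profile: contiguous runs of bins with a shared mean log-ratio.

    ``segments`` has columns ``chrom``, ``start``, ``end`` (0-based
    half-open), ``n_bins``, ``logr`` (mean of member bins) and ``cn``
    (integer copy number; ``NaN`` until assigned).
    """

    sample_id: str
    segments: pd.DataFrame
    #: per-bin noise SD estimated during segmentation (None if unknown)
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SEGMENT_COLUMNS if c not in self.segments.columns]
        if missing:
            raise ValueError(f"segments missing columns {missing}")
        self.segments = self.segments.reset_index(drop=True)
        if len(self.segments) == 0:
            raise ValueError("profile has no segments")
        if (self.segments["n_bins"].to_numpy() < 1).any():
            raise ValueError("n_bins must be >= 1")
        cn = self.segments["cn"].to_numpy(dtype=float)
        if np.nanmin(cn, initial=0.0) < 0:
            raise ValueError("copy number must be non-negative")
        _check_sorted_disjoint(self.segments, "segments")

    @property
    def has_cn(self) -> bool:
        return not self.segments["cn"].isna().any()

    def with_cn(self, cn: np.ndarray) -> "SegmentProfile":
        """Return a copy with the per-segment copy numbers assigned."""
        if len(cn) != len(self.segments):
            raise ValueError("cn length must match number of segments")
        seg = self.segments.copy()
        seg["cn"] = np.asarray(cn, dtype=float)
        return SegmentProfile(self.sample_id, seg, noise_sd=self.noise_sd)


# ---------------------------------------------------------------------------
# SEG I/O (1-based inclusive coordinates, ichorCNA-style columns)
# ---------------------------------------------------------------------------

_SEG_HEADER = ["sample", "chrom", "start", "end", "num_bins", "logR"]


def write_seg(profile: SegmentProfile, path) -> None:
    """Write a segment profile as a tab-delimited SEG file.

    Coordinates are converted to the SEG dialect (1-based inclusive).
    A ``CN`` column is appended when copy numbers are assigned.
    """
    seg = profile.segments
    out = pd.DataFrame(
        {
            "sample": profile.sample_id,
            "chrom": seg["chrom"],
            "start": seg["start"] + 1,
            "end": seg["end"],
            "num_bins": seg["n_bins"],
            "logR": seg["logr"],
        }
    )
    if profile.has_cn:
        out["CN"] = seg["cn"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_seg(path) -> SegmentProfile:
    """Read a tab-delimited SEG file written in 1-based inclusive coordinates.

    Expected columns: ``sample, chrom, start, end, num_bins, logR`` and
    optionally ``CN``.  Malformed rows raise a ``ValueError`` naming the
    offending line number (1-based, header = line 1); overlapping
    segments are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in _SEG_HEADER if c.lower() not in cols]
    if missing:
        raise ValueError(f"SEG file {path} missing columns {missing}")
    df = df.rename(columns={cols[c.lower()]: c for c in _SEG_HEADER + ["cn"] if c.lower() in cols})
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            s, e, nb = int(row.start), int(row.end), int(row.num_bins)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
        if e < s:
            raise ValueError(f"{path}: end < start at line {i}")
        if nb < 1:
            raise ValueError(f"{path}: num_bins < 1 at line {i}")
        if not np.isfinite(float(row.logR)):
            raise ValueError(f"{path}: non-finite logR at line {i}")
    samples = df["sample"].unique()
    if len(samples) != 1:
        raise ValueError(f"{path}: expected exactly one sample, found {list(samples)}")
    seg = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64) - 1,
            "end": df["end"].astype(np.int64),
            "n_bins": df["num_bins"].astype(np.int64),
            "logr": df["logR"].astype(float),
            "cn": df["cn"].astype(float) if "cn" in df.columns else np.nan,
        }
    )
    return SegmentProfile(str(samples[0]), seg)


def segments_to_bins(profile: SegmentProfile, bin_size: int) -> BinnedProfile:
    """Expand a segment profile onto a fixed bin grid, repeating each
    segment's mean log-ratio across its bins (inverse of averaging)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms, starts, ends, logr = [], [], [], []
    for r in profile.segments.itertuples(index=False):
        s = np.arange(r.start, r.end, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, r.end)
        chroms.extend([r.chrom] * len(s))
        starts.append(s)
        ends.append(e)
        logr.append(np.full(len(s), float(r.logr)))
    bins = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
            "logr": np.concatenate(logr),
        }
    )
    return BinnedProfile(profile.sample_id, bins)


def write_bed(regions: pd.DataFrame, path) -> None:
    """Export regions as BED (0-based half-open); extra columns pass through."""
    regions.to_csv(path, sep="\t", index=False, header=True)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _best_split(x: np.ndarray, min_size: int = 1) -> tuple[float, int]:
    """Best mean-shift split of ``x`` leaving both sides >= ``min_size``:
    (SSE reduction, split index)."""
    n = len(x)
    if n < 2 * min_size or n < 2:
        return 0.0, 0
    cs = np.cumsum(x)
    total = cs[-1]
    ssq = float(np.dot(x, x))
    sse_full = ssq - total * total / n
    i = np.arange(min_size, n - min_size + 1)
    left = cs[i - 1]
    sse_split = ssq - left * left / i - (total - left) ** 2 / (n - i)
    k = int(np.argmin(sse_split))
    gain = sse_full - float(sse_split[k])
    return gain, int(i[k])


def _best_interval(x: np.ndarray, min_size: int = 1) -> tuple[float, int, int]:
    """Best middle-interval extraction of ``x`` (CBS-style in-vs-out
    mean contrast), interval length >= ``min_size``: (SSE reduction,
    start, end)."""
    n = len(x)
    if n < 3 or n <= min_size:
        return 0.0, 0, 0
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    base = total * total / n
    best = (0.0, 0, 0)
    for length in range(min_size, n):
        s_in = cs[length:] - cs[:-length]
        red = s_in ** 2 / length + (total - s_in) ** 2 / (n - length) - base
        k = int(np.argmax(red))
        if red[k] > best[0]:
            best = (float(red[k]), k, k + length)
    return best


def _binary_segmentation(x: np.ndarray, threshold: float, min_size: int = 1) -> list[int]:
    """Recursive segmentation; returns sorted interior breakpoints.

    Each segment is split at the best single changepoint when that
    reduces the SSE by more than ``threshold``; otherwise the best
    middle-interval extraction (two changepoints, so twice the penalty)
    is tried, which catches short events far from both segment ends
    where the single-split contrast is diluted.
    """
    breaks: list[int] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        gain, k = _best_split(x[lo:hi], min_size)
        if gain > threshold:
            breaks.append(lo + k)
            stack.append((lo, lo + k))
            stack.append((lo + k, hi))
            continue
        gain2, i, j = _best_interval(x[lo:hi], min_size)
        if gain2 > 2 * threshold and 0 < i and j < hi - lo:
            breaks.extend([lo + i, lo + j])
            stack.append((lo, lo + i))
            stack.append((lo + i, lo + j))
            stack.append((lo + j, hi))
    return sorted(breaks)


def estimate_noise_sd(profile: BinnedProfile) -> float:
    """Robust per-bin noise SD from successive log-ratio differences."""
    x = profile.bins["logr"].to_numpy(dtype=float)
    if len(x) < 2:
        return 0.0
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _prune_breaks(x: np.ndarray, bounds: list[int], sigma: float, t_merge: float) -> list[int]:
    """Merge adjacent segments whose means are not significantly
    different (|t| < t_merge), smallest contrast first.  Counteracts the
    winner's-curse fragments a liberal split threshold produces."""
    bounds = list(bounds)
    if sigma <= 0:
        sigma = 1e-12
    while len(bounds) > 2:
        means, ns = [], []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            means.append(np.mean(x[lo:hi]))
            ns.append(hi - lo)
        t_stats = [
            abs(means[i] - means[i + 1]) / (sigma * np.sqrt(1.0 / ns[i] + 1.0 / ns[i + 1]))
            for i in range(len(means) - 1)
        ]
        k = int(np.argmin(t_stats))
        if t_stats[k] >= t_merge:
            break
        del bounds[k + 1]
    return bounds


def segment(
    profile: BinnedProfile,
    penalty: float = 1.0,
    t_merge: float = 2.5,
    min_seg_bins: int = 5,
) -> SegmentProfile:
    """Segment a binned profile by per-chromosome binary segmentation
    with a merge-back prune.

    Splits are accepted while they reduce the within-segment sum of
    squares by more than ``penalty * sigma^2 * log(n)`` (a BIC-style
    criterion, deliberately liberal), then adjacent segments whose mean
    difference is below ``t_merge`` noise standard errors are merged
    back; ``sigma`` is estimated robustly from successive bin
    differences.  Segments smaller than ``min_seg_bins`` are never
    created, so single-bin noise outliers cannot be isolated into
    spurious high-amplitude segments.  Chromosomes are segmented
    independently, so the result
    is invariant to chromosome input order.  Copy numbers are left
    unassigned (see :func:`estimate_tf`).
    """
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    sigma = estimate_noise_sd(profile)
    n_total = profile.n_bins
    threshold = max(penalty * sigma * sigma * np.log(max(n_total, 2)), 1e-10)
    # noise-free input admits exact changepoints anywhere; the minimum
    # size only exists to stop noise outliers from forming segments
    min_size = min_seg_bins if sigma > 1e-12 else 1

    rows = []
    for chrom, sub in profile.bins.groupby("chrom", sort=False):
        x = sub["logr"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        breaks = _binary_segmentation(x, threshold, min_size)
        bounds = _prune_breaks(x, [0, *breaks, len(x)], sigma, t_merge)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            rows.append(
                (chrom, starts[lo], ends[hi - 1], hi - lo, float(np.mean(x[lo:hi])), np.nan)
            )
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return SegmentProfile(profile.sample_id, seg, noise_sd=sigma)


# ---------------------------------------------------------------------------
# Tumor-fraction estimation
# ---------------------------------------------------------------------------

def expected_logr(tf: float, cn, min_logr: float = MIN_LOGR):
    """Expected log2 ratio of a region with tumor copy number ``cn``
    in plasma with tumor fraction ``tf``; floored at ``min_logr``."""
    mix = tf * np.asarray(cn, dtype=float) / 2.0 + (1.0 - tf)
    return np.maximum(np.log2(np.maximum(mix, 2.0 ** min_logr)), min_logr)


@dataclass
class TFEstimate:
    """Result of the grid-search tumor-fraction fit.

    ``model`` holds the per-segment copy-number assignment of the
    selected solution; ``detected`` is ``tf > detection_threshold``.
    """

    tf: float
    fit_score: float
    model: np.ndarray
    detected: bool
    detection_threshold: float = 0.0
    diploid_score: float = field(default=np.nan)


def _segment_noise_var(means: np.ndarray, weights: np.ndarray) -> float:
    """Robust per-bin noise variance from segment means: most segments
    are diploid (mean ~ a common baseline), so ``n * (m - median)^2`` is
    approximately ``sigma^2 * chi^2(1)`` for them; the median of that
    statistic over segments, divided by the chi^2(1) median 0.455,
    estimates ``sigma^2`` robustly against the altered minority.  The
    median is weighted by bin counts so a handful of large altered
    segments cannot dominate it."""
    order = np.argsort(means)
    cum = np.cumsum(weights[order])
    med = means[order][np.searchsorted(cum, cum[-1] / 2.0)]
    stat = weights * (means - med) ** 2
    order = np.argsort(stat)
    cum = np.cumsum(weights[order])
    wmed = stat[order][np.searchsorted(cum, cum[-1] / 2.0)]
    return float(wmed / 0.455)


def estimate_tf(
    segments: SegmentProfile,
    grid_step: float = 0.01,
    cn_max: int = 6,
    tf_max: float = 0.9,
    diploid_tolerance: float = 0.02,
    detection_threshold: float = 0.0,
    min_logr: float = MIN_LOGR,
    noise_sd: float | None = None,
    cn_penalty_factor: float = 2.0,
) -> TFEstimate:
    """Estimate tumor fraction by joint grid search over tf and copy numbers.

    For each candidate ``tf`` on the grid ``{0, grid_step, ..., tf_max}``
    every segment is assigned the integer copy number in ``0..cn_max``
    minimizing the squared deviation of its mean log-ratio from the
    mixture prediction, weighted by the segment's bin count; the ``tf``
    with the smallest total weighted score wins.

    Each segment called non-diploid incurs a BIC-style penalty
    ``cn_penalty_factor * sigma^2 * ln(n_bins_total)`` (``sigma`` from
    ``noise_sd`` or estimated robustly from the segment means), a prior
    toward diploid that stops dense low-tf copy-number ladders from
    fitting segment-mean noise; with noiseless input the penalty
    vanishes and the fit inverts the mixture exactly.

    The mixture model is invariant under halving ``tf`` while doubling
    every copy-number deviation from diploid (e.g. tf=0.4 with CN 3/1
    predicts the same log-ratios as tf=0.2 with CN 4/0), so exact score
    ties are broken toward the solution closest to diploid (smallest
    bin-weighted total |CN-2|) and then toward smaller ``tf``.  The
    all-diploid model (tf = 0) is returned whenever its score is within
    ``diploid_tolerance`` (relative) of the best score, which guards
    against spurious positivity on noise.
    """
    if not 0 < grid_step <= 0.05:
        raise ValueError("grid_step must be in (0, 0.05]")
    if cn_max < 3:
        raise ValueError("cn_max must be >= 3")
    means = segments.segments["logr"].to_numpy(dtype=float)
    weights = segments.segments["n_bins"].to_numpy(dtype=float)
    if len(means) == 0 or not np.isfinite(means).all():
        raise ValueError("segments must carry finite mean log-ratios")

    n_total = float(weights.sum())
    if noise_sd is None:
        noise_sd = segments.noise_sd
    sigma2 = noise_sd ** 2 if noise_sd is not None else _segment_noise_var(means, weights)
    lam = cn_penalty_factor * sigma2 * np.log(max(n_total, 2.0))

    n_steps = int(round(tf_max / grid_step))
    tf_grid = np.arange(n_steps + 1) * grid_step
    cn_grid = np.arange(cn_max + 1)
    # predictions: (T, C)
    pred = np.stack([expected_logr(tf, cn_grid, min_logr) for tf in tf_grid])
    # weighted residuals plus diploid prior: (T, S, C)
    resid = weights[None, :, None] * (means[None, :, None] - pred[:, None, :]) ** 2
    # diploid prior: lam per altered call, plus a fractional increment
    # per extra copy-number step so the degenerate tf/k branch (which
    # inflates every CN deviation k-fold) is systematically dispreferred
    cn_cost = (cn_grid != 2).astype(float) + 0.25 * np.abs(cn_grid - 2)
    penalized = resid + lam * cn_cost[None, None, :]
    best_cn = np.argmin(penalized, axis=2)                  # (T, S)
    scores = np.take_along_axis(penalized, best_cn[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    resid_scores = np.take_along_axis(resid, best_cn[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    devs = (np.abs(best_cn - 2) * weights[None, :]).sum(axis=1)

    best_score = float(scores.min())
    sel = int(np.argmin(scores))
    # Escape the degenerate branch: tf/k with k-fold inflated CN
    # deviations predicts the same log-ratios as tf (k = 2 always, k = 3
    # for gains), so noise decides between them by a coin flip.  Climb
    # to k*tf whenever that solution is statistically tied (within half
    # a penalty unit) and strictly closer to diploid.
    margin = 0.5 * lam + 1e-9
    moved = True
    while moved:
        moved = False
        for k in (2, 3):
            j = sel * k
            if j > n_steps:
                continue
            d = best_cn[sel] - 2
            if np.any(d % k != 0):
                continue  # not the k-fold degenerate signature
            if not np.array_equal(best_cn[j], 2 + d // k):
                continue
            if scores[j] <= scores[sel] + margin and devs[j] < devs[sel] - 1e-9:
                sel = j
                moved = True
                break

    score0 = float(scores[0])
    if score0 <= best_score * (1 + diploid_tolerance) + 1e-12:
        sel = 0
    tf = float(tf_grid[sel])
    model = best_cn[sel].astype(int)
    if sel == 0:
        model = np.full(len(means), 2, dtype=int)
    return TFEstimate(
        tf=tf,
        fit_score=float(resid_scores[sel]),
        model=model,
        detected=tf > detection_threshold,
        detection_threshold=detection_threshold,
        diploid_score=score0,
    )


def ctdna_status(estimate: TFEstimate, detection_threshold: float = 0.0) -> str:
    """ctDNA call from a tumor-fraction estimate: ``positive`` iff
    ``tf > detection_threshold`` (default 0), else ``negative``."""
    return "positive" if estimate.tf > detection_threshold else "negative"
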