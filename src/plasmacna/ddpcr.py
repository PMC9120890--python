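"""Droplet digital PCR quantification.

Each reaction is partitioned into at most 20 000 droplets; a target
present at concentration ``c`` copies/µL loads a droplet of volume ``v``
µL with at least one copy with probability ``1 - exp(-c v)``.  Observing
``k`` positive droplets out of ``n`` therefore inverts to the
Poisson-corrected concentration ``c = -ln(1 - k/n) / v``.  The mutant
allele fraction (MAF) is the mutant concentration over mutant plus
wildtype.  Wells are merged by summing droplet counts before applying
the Poisson correction; a timepoint is called mutation-positive only
when the merged wells contain at least two mutant-positive droplets, and
at least duplicate wells are required per timepoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MAX_DROPLETS = 20_000

#: vendor-standard droplet volume in microliters
DEFAULT_DROPLET_VOLUME_UL = 0.00085

#: minimum merged mutant-positive droplets for a positive call
MIN_MUTANT_DROPLETS = 2


@dataclass(frozen=True)
class DropletWell:
    """Droplet counts for one well of a mutant/wildtype duplex assay."""

    n_droplets: int
    k_mut: int
    k_wt: int
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL

    def __post_init__(self) -> None:
        if not 0 < self.n_droplets <= MAX_DROPLETS:
            raise ValueError(f"n_droplets must be in 1..{MAX_DROPLETS}")
        if not 0 <= self.k_mut <= self.n_droplets:
            raise ValueError("k_mut out of range")
        if not 0 <= self.k_wt <= self.n_droplets:
            raise ValueError("k_wt out of range")
        if self.droplet_volume_ul <= 0:
            raise ValueError("droplet_volume_ul must be positive")


@dataclass(frozen=True)
class MafResult:
    """Merged-well quantification: concentrations in copies/µL, MAF as a
    fraction, positivity under the two-droplet rule."""

    conc_mut: float
    conc_wt: float
    maf: float
    positive: bool
    n_wells: int
    k_mut: int
    k_wt: int
    droplet_volume_ul: float

    @property
    def maf_pct(self) -> float:
        return 100.0 * self.maf


def poisson_concentration(k: int, n: int, v_ul: float) -> float:
    """Poisson-corrected concentration (copies/µL) from ``k`` positive
    droplets out of ``n`` of volume ``v_ul`` µL: ``-ln(1 - k/n) / v_ul``.

    A saturated well (``k == n``) has unbounded concentration and raises.
    """
    if v_ul <= 0:
        raise ValueError("droplet volume must be positive")
    if not 0 <= k <= n or n <= 0:
        raise ValueError("require 0 <= k <= n with n > 0")
    if k == n:
        raise ValueError("saturated well (k == n): concentration unbounded")
    return -math.log1p(-k / n) / v_ul


def merge_wells(wells: list[DropletWell]) -> DropletWell:
    """Combine replicate wells by summing droplet counts component-wise.

    All wells must share the same droplet volume.  Note the merged counts
    may legitimately exceed the per-well droplet maximum.
    """
    if not wells:
        raise ValueError("no wells to merge")
    v = wells[0].droplet_volume_ul
    if any(not math.isclose(w.droplet_volume_ul, v, rel_tol=1e-9) for w in wells):
        raise ValueError("cannot merge wells with heterogeneous droplet volumes")
    merged = DropletWell.__new__(DropletWell)  # bypass the per-well droplet cap
    object.__setattr__(merged, "n_droplets", sum(w.n_droplets for w in wells))
    object.__setattr__(merged, "k_mut", sum(w.k_mut for w in wells))
    object.__setattr__(merged, "k_wt", sum(w.k_wt for w in wells))
    object.__setattr__(merged, "droplet_volume_ul", v)
    return merged


def call_maf(wells: list[DropletWell], require_duplicate: bool = True) -> MafResult:
    """Merge wells, quantify mutant and wildtype, and call positivity.

    Timepoints are analyzed at least in duplicate; fewer than two wells
    raises unless ``require_duplicate`` is disabled.  Positivity requires
    at least :data:`MIN_MUTANT_DROPLETS` merged mutant-positive droplets.
    """
    if require_duplicate and len(wells) < 2:
        raise ValueError(
            "timepoints must be analyzed at least in duplicate; "
            "pass require_duplicate=False to override"
        )
    m = merge_wells(wells)
    conc_mut = poisson_concentration(m.k_mut, m.n_droplets, m.droplet_volume_ul)
    conc_wt = poisson_concentration(m.k_wt, m.n_droplets, m.droplet_volume_ul)
    total = conc_mut + conc_wt
    maf = conc_mut / total if total > 0 else float("nan")
    return MafResult(
        conc_mut=conc_mut,
        conc_wt=conc_wt,
        maf=maf,
        positive=m.k_mut >= MIN_MUTANT_DROPLETS,
        n_wells=len(wells),
        k_mut=m.k_mut,
        k_wt=m.k_wt,
        droplet_volume_ul=m.droplet_volume_ul,
    )


def simulate_droplets(
    maf: float,
    total_copies_per_ul: float,
    n: int = MAX_DROPLETS,
    v_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    rng: np.random.Generator | None = None,
) -> DropletWell:
    """Simulate one well: droplet positivity is binomial with the Poisson
    loading probability ``1 - exp(-c v)`` for each allele."""
    if not 0 <= maf <= 1:
        raise ValueError("maf must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if total_copies_per_ul < 0:
        raise ValueError("total concentration must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    c_mut = maf * total_copies_per_ul
    c_wt = (1.0 - maf) * total_copies_per_ul
    p_mut = -math.expm1(-c_mut * v_ul)
    p_wt = -math.expm1(-c_wt * v_ul)
    k_mut = int(rng.binomial(n, p_mut))
    k_wt = int(rng.binomial(n, p_wt))
    return DropletWell(n_droplets=n, k_mut=k_mut, k_wt=k_wt, droplet_volume_ul=v_ul)
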