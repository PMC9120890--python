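"""Reference genome layout used throughout the package.

The default genome is the 22 human autosomes (hg19 lengths) with each
chromosome truncated to a whole number of 50-kb bins, matching the bin
grid of low-coverage WGS read counting.  Sex chromosomes are excluded to
avoid ploidy ambiguity in the log-ratio model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# hg19 autosome lengths in bp
_HG19_AUTOSOMES = [
    ("chr1", 249_250_621), ("chr2", 243_199_373), ("chr3", 198_022_430),
    ("chr4", 191_154_276), ("chr5", 180_915_260), ("chr6", 171_115_067),
    ("chr7", 159_138_663), ("chr8", 146_364_022), ("chr9", 141_213_431),
    ("chr10", 135_534_747), ("chr11", 135_006_516), ("chr12", 133_851_895),
    ("chr13", 115_169_878), ("chr14", 107_349_540), ("chr15", 102_531_392),
    ("chr16", 90_354_753), ("chr17", 81_195_210), ("chr18", 78_077_248),
    ("chr19", 59_128_983), ("chr20", 63_025_520), ("chr21", 48_129_895),
    ("chr22", 51_304_566),
]

DEFAULT_BIN_SIZE = 50_000


def default_genome(bin_size: int = DEFAULT_BIN_SIZE) -> list[tuple[str, int]]:
    """22 autosomes with lengths rounded down to a multiple of ``bin_size``."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    return [(c, (length // bin_size) * bin_size) for c, length in _HG19_AUTOSOMES]


def make_bins(genome: list[tuple[str, int]], bin_size: int) -> pd.DataFrame:
    """Tile a genome into fixed-size bins.

    Returns a DataFrame with columns ``chrom``, ``start``, ``end``
    (0-based half-open).  The terminal bin of a chromosome may be shorter
    than ``bin_size`` when the length is not a multiple of it.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not genome:
        raise ValueError("genome must be non-empty")
    chroms, starts, ends = [], [], []
    for chrom, length in genome:
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        s = np.arange(0, length, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, length)
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype="object"),
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
        }
    )


def genome_length(genome: list[tuple[str, int]]) -> int:
    return int(sum(length for _, length in genome))
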