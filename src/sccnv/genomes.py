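"""Reference genome metadata for simulation and testing.

Provides hg19 chromosome lengths, a deterministic synthetic window grid
(scaled-down by default so full-pipeline tests run in seconds: same
20-kb windows, 10% chromosome lengths), and a synthetic-approximate
cytogenetic band table.

The band table is SYNTHETIC: band boundaries are approximate values
chosen to be internally consistent across the package (karyotype
fixtures, rendering and parsing all use this same table), not exact
UCSC cytoBand coordinates.  Only the bands required by the bundled
cell-line karyotypes are included; positions without a band fall back
to Mb-coordinate labels.
"""

from __future__ import annotations

from typing import Dict, Mapping

import numpy as np

from .calling import BandTable
from .grid import WindowGrid, make_window_grid

#: hg19 (GRCh37) chromosome lengths, bp
HG19_CHROM_LENGTHS: Dict[str, int] = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560,
}
HG19_CHRY_LENGTH = 59_373_566

# Synthetic-approximate band boundaries (Mb, full scale), contiguous only
# where the bundled karyotypes need labels.
_BAND_DATA_MB = {
    "chr1": [("p31.1", 68.9, 84.9), ("p22.3", 84.9, 88.1)],
    "chr4": [("p16.3", 0.0, 4.5), ("p16.2", 4.5, 6.0), ("p16.1", 6.0, 11.3)],
    "chr6": [("q15", 88.0, 93.1), ("q16.1", 93.1, 99.5)],
    "chr12": [("p13.33", 0.0, 3.3), ("p13.32", 3.3, 5.4), ("p13.31", 5.4, 10.1),
              ("p13.2", 10.1, 12.8), ("p13.1", 12.8, 14.8), ("p12.3", 14.8, 19.9),
              ("p12.2", 19.9, 21.3), ("p12.1", 21.3, 26.8)],
    "chr16": [("p13", 0.0, 14.2), ("p12.3", 14.2, 16.7), ("p12.2", 16.7, 21.2),
              ("p12.1", 21.2, 24.2), ("p11.2", 24.2, 34.6), ("p11.1", 34.6, 36.6)],
}


def simulation_chrom_lengths(scale: float = 0.1,
                             genome: Mapping[str, int] = HG19_CHROM_LENGTHS,
                             ) -> Dict[str, int]:
    """Chromosome lengths scaled by ``scale`` (chrY excluded by design)."""
    return {c: int(round(length * scale)) for c, length in genome.items()}


def synthetic_band_table(scale: float = 0.1) -> BandTable:
    """Synthetic-approximate band table on the (scaled) simulation genome."""
    rows = []
    for chrom, bands in _BAND_DATA_MB.items():
        for band, lo, hi in bands:
            rows.append((chrom, int(round(lo * 1e6 * scale)),
                         int(round(hi * 1e6 * scale)), band, "gneg"))
    return BandTable(rows)


def _synthetic_gc(n: int, seed: int) -> np.ndarray:
    """Smooth AR(1) GC track around the genome-wide mean of ~0.41."""
    rng = np.random.default_rng(seed)
    phi, sd, mean = 0.98, 0.05, 0.41
    eps = rng.normal(0.0, sd * np.sqrt(1 - phi ** 2), size=n)
    z = np.empty(n)
    z[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        z[i] = phi * z[i - 1] + eps[i]
    return np.clip(mean + z, 0.30, 0.60)


def synthetic_grid(scale: float = 0.1, window_size: int = 20_000,
                   genome: Mapping[str, int] = HG19_CHROM_LENGTHS) -> WindowGrid:
    """Deterministic annotated window grid over the scaled simulation genome.

    GC fractions are a fixed property of the synthetic genome (seeded by
    its dimensions), identical for every simulation that uses the same
    scale and window size.
    """
    lengths = simulation_chrom_lengths(scale, genome)
    grid = make_window_grid(lengths, window_size,
                            genome_id=f"synthetic-hg19-x{scale:g}")
    gc_seed = (hash((round(scale, 6), window_size, len(lengths))) & 0x7FFFFFFF)
    gc = np.empty(grid.n_windows)
    for k, (chrom, sl) in enumerate(grid.chrom_slices.items()):
        gc[sl] = _synthetic_gc(sl.stop - sl.start, gc_seed + k)
    grid.gc_fraction = gc
    return grid
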