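"""Quality metrics: MAPD, coverage uniformity, GC read distribution,
between-profile correlation.

MAPD (median absolute pairwise difference) is the median of
|x_{i+1} - x_i| over pairs of adjacent windows on the same chromosome,
where x is the log2 copy-number ratio.  It is a robust per-sample noise
statistic: for i.i.d. Gaussian x with standard deviation sigma, MAPD
equals sigma * sqrt(2) * 0.6745 ~= 0.9539 sigma.  Samples with MAPD
above 0.4 (evaluated in 100-kb windows by default), or with fewer than
90% of windows reaching 20% of the mean count, are rejected for CNV
analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

from .errors import InsufficientDataError
from .grid import WindowGrid, aggregate_grid
from .counts import WindowCounts, aggregate_counts
from .normalize import NormalizedProfile, normalize_counts

#: median of |N(0,1)|; MAPD of i.i.d. Gaussian x with SD s is s*sqrt(2)*MEDIAN_ABS_NORMAL
MEDIAN_ABS_NORMAL = 0.6744897501960817
MAPD_IID_FACTOR = np.sqrt(2.0) * MEDIAN_ABS_NORMAL

DEFAULT_MAPD_MAX = 0.4
DEFAULT_COVERAGE_MIN = 0.90


@dataclass
class QcReport:
    mapd_by_window_size: Dict[int, float]
    coverage_fraction_at_20pct: float
    qc_pass_mapd: bool
    qc_pass_coverage: bool
    evaluation_window_size: int
    gc_histogram: Dict[float, float] = field(default_factory=dict)

    @property
    def qc_pass(self) -> bool:
        return self.qc_pass_mapd and self.qc_pass_coverage

    def to_json(self) -> str:
        d = dict(vars(self))
        d["mapd_by_window_size"] = {str(k): v for k, v in d["mapd_by_window_size"].items()}
        d["gc_histogram"] = {format(k, ".2f"): v for k, v in d["gc_histogram"].items()}
        d["qc_pass"] = self.qc_pass
        return json.dumps(d, indent=2)

    def as_text(self) -> str:
        lines = [f"coverage_fraction_at_20pct={self.coverage_fraction_at_20pct:.4f}",
                 f"qc_pass_mapd={self.qc_pass_mapd}",
                 f"qc_pass_coverage={self.qc_pass_coverage}",
                 f"evaluation_window_size={self.evaluation_window_size}"]
        for k, v in self.mapd_by_window_size.items():
            lines.append(f"mapd[{k}]={v:.4f}")
        return "\n".join(lines) + "\n"


def _adjacent_diffs(profile: NormalizedProfile, skip_masked: bool = True) -> np.ndarray:
    grid = profile.grid
    if grid is None:
        raise InsufficientDataError("profile carries no grid; cannot find adjacency")
    diffs = []
    for _, sl in grid.chrom_slices.items():
        x = profile.log2_ratio[sl]
        m = profile.mask[sl]
        if skip_masked:
            xv = x[~m]
            if xv.size >= 2:
                diffs.append(np.abs(np.diff(xv)))
        else:
            ok = (~m[:-1]) & (~m[1:])
            if ok.any():
                diffs.append(np.abs(np.diff(x))[ok])
    if not diffs:
        return np.empty(0)
    return np.concatenate(diffs)


def mapd(profile: NormalizedProfile, skip_masked: bool = True) -> float:
    """Median |x_{i+1} - x_i| over adjacent unmasked windows per chromosome.

    Adjacency never crosses a chromosome boundary.  By default masked
    windows are skipped (the next unmasked window on the chromosome
    counts as adjacent); with ``skip_masked=False`` pairs spanning a
    masked window are dropped instead.
    """
    d = _adjacent_diffs(profile, skip_masked=skip_masked)
    if d.size < 2:
        raise InsufficientDataError("fewer than 2 usable adjacent window pairs")
    return float(np.median(d))


def mapd_profile_over_sizes(sample_wc: WindowCounts, control_wc: WindowCounts,
                            grid: WindowGrid, factors: Sequence[int],
                            span: float = 0.3) -> Dict[int, float]:
    """MAPD after re-aggregating counts to several window sizes.

    Returns mapping window size (bp) -> MAPD.  Each factor re-aggregates
    the raw counts, re-runs GC correction and control normalization on
    the aggregated grid, and recomputes MAPD.
    """
    out: Dict[int, float] = {}
    for f in factors:
        g = aggregate_grid(grid, f)
        s = aggregate_counts(sample_wc, grid, f, agg_grid=g)
        k = aggregate_counts(control_wc, grid, f, agg_grid=g)
        prof = normalize_counts(s, k, g, span=span)
        out[g.window_size] = mapd(prof)
    return out


def coverage_uniformity(wc: WindowCounts, grid: WindowGrid) -> float:
    """Fraction of usable windows with count >= 20% of the mean count."""
    c = np.asarray(wc.counts, dtype=float)[grid.usable]
    if c.size == 0:
        raise InsufficientDataError("no usable windows")
    mean = c.mean()
    if mean <= 0:
        return 0.0
    return float(np.mean(c >= 0.2 * mean))


def profile_correlation(a: NormalizedProfile, b: NormalizedProfile) -> float:
    """Pearson correlation of the ratio over jointly unmasked windows."""
    ok = (~a.mask) & (~b.mask)
    if int(ok.sum()) < 3:
        raise InsufficientDataError("fewer than 3 jointly unmasked windows")
    return float(np.corrcoef(a.ratio[ok], b.ratio[ok])[0, 1])


def gc_read_distribution(wc: WindowCounts, grid: WindowGrid,
                         bin_width: float = 0.01) -> Dict[float, float]:
    """Fraction of kept reads per GC bin; values sum to 1."""
    c = np.asarray(wc.counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise InsufficientDataError("no reads to histogram")
    bins = np.floor(grid.gc_fraction / bin_width).astype(int)
    out: Dict[float, float] = {}
    for b in np.unique(bins):
        out[round(float(b * bin_width), 10)] = float(c[bins == b].sum() / total)
    return out


def write_gc_histogram(hist: Dict[float, float], path) -> None:
    """Two-column TSV: GC bin lower edge, read fraction."""
    with open(path, "w") as fh:
        fh.write("#gc_bin\tread_fraction\n")
        for gc in sorted(hist):
            fh.write(f"{gc:.2f}\t{hist[gc]:.6g}\n")


def compute_qc_report(sample_wc: WindowCounts, control_wc: WindowCounts,
                      grid: WindowGrid, qc_window_size: int = 100_000,
                      extra_factors: Sequence[int] = (), span: float = 0.3,
                      mapd_max: float = DEFAULT_MAPD_MAX,
                      coverage_min: float = DEFAULT_COVERAGE_MIN) -> QcReport:
    """Full QC: MAPD at the evaluation window size (plus any extra
    aggregation factors), coverage rule, GC histogram."""
    qc_factor = max(1, qc_window_size // grid.window_size)
    factors = sorted({qc_factor, *extra_factors})
    mapds = mapd_profile_over_sizes(sample_wc, control_wc, grid, factors, span=span)
    eval_size = grid.window_size * qc_factor
    cov = coverage_uniformity(sample_wc, grid)
    return QcReport(
        mapd_by_window_size=mapds,
        coverage_fraction_at_20pct=cov,
        qc_pass_mapd=bool(mapds[eval_size] <= mapd_max),
        qc_pass_coverage=bool(cov >= coverage_min),
        evaluation_window_size=eval_size,
        gc_histogram=gc_read_distribution(sample_wc, grid),
    )
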