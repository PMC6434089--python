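"""GC correction and control normalization of window counts.

Counts are first corrected for GC bias by locally weighted regression
(LOESS) of count on window GC fraction, fitted over usable, non-zero
autosomal windows; the correction is multiplicative (count times
median-fit over fit-at-GC), which preserves non-negativity.  The
corrected sample profile is then divided, after depth scaling, by a
corrected control profile; log2 of that ratio is the copy-number signal
x_i (approximately log2(CN/2) on autosomes).

Sample and control are corrected independently; ratios are formed
afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InsufficientDataError
from .grid import WindowGrid
from .counts import WindowCounts

#: minimum usable non-zero autosomal windows for a LOESS fit
MIN_LOESS_WINDOWS = 100


@dataclass
class NormalizedProfile:
    """GC-corrected, control-normalized per-window ratios.

    ``mask`` is True for *excluded* windows (unusable, zero in sample or
    zero in control).  ``ratio`` and ``log2_ratio`` are NaN exactly on
    masked windows and finite everywhere else.
    """

    sample_id: str
    grid_ref: str
    corrected_counts: np.ndarray
    ratio: np.ndarray
    log2_ratio: np.ndarray
    mask: np.ndarray
    grid: Optional[WindowGrid] = field(default=None, repr=False)

    @property
    def x(self) -> np.ndarray:
        """Unmasked log2 ratios (convenience accessor)."""
        return self.log2_ratio[~self.mask]


def gc_loess_correct(wc: WindowCounts, grid: WindowGrid, span: float = 0.3) -> np.ndarray:
    """Remove GC-dependent count bias by LOESS.

    Fits f(gc) on usable non-zero autosomal windows and returns
    ``count * median(f) / f(gc)`` for every window; windows outside the
    fitted GC range take the nearest fitted value.  With degenerate GC
    spread the correction is the identity (with a warning).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    counts = np.asarray(wc.counts, dtype=float)
    sel = grid.usable & grid.autosomal() & (counts > 0)
    n_sel = int(sel.sum())
    if n_sel < MIN_LOESS_WINDOWS:
        raise InsufficientDataError(
            f"GC LOESS needs >= {MIN_LOESS_WINDOWS} usable non-zero autosomal "
            f"windows, found {n_sel}")
    gc = grid.gc_fraction
    spread = float(np.ptp(gc[sel]))
    if spread < 1e-9:
        warnings.warn("all windows share one GC value; GC correction is the identity",
                      stacklevel=2)
        return counts.copy()
    # delta makes the fit linear-time without visibly changing it
    fit = lowess(counts[sel], gc[sel], frac=span, delta=0.01 * spread,
                 return_sorted=True)
    xs, fs = fit[:, 0], fit[:, 1]
    xs, uniq = np.unique(xs, return_index=True)
    fs = fs[uniq]
    f_all = np.interp(gc, xs, fs)  # clamps to nearest fitted value at the edges
    med = float(np.median(fs))
    if med <= 0:
        warnings.warn("LOESS fit is non-positive at the median; skipping GC correction",
                      stacklevel=2)
        return counts.copy()
    f_all = np.maximum(f_all, 0.01 * med)
    corrected = counts * (med / f_all)
    return np.maximum(corrected, 0.0)


def normalize_to_control(sample: np.ndarray, control: np.ndarray,
                         grid: WindowGrid, sample_id: str = "sample") -> NormalizedProfile:
    """Form depth-scaled sample/control ratios and their log2.

    r_i = (s_i / S) / (k_i / K) with S, K the unmasked totals.  Windows
    that are unusable or zero on either side are masked, never infinite.
    """
    sample = np.asarray(sample, dtype=float)
    control = np.asarray(control, dtype=float)
    if sample.shape != control.shape or sample.size != grid.n_windows:
        raise InsufficientDataError("sample/control/grid sizes disagree")
    if float(control.sum()) <= 0:
        raise InsufficientDataError("control profile has zero total count")
    mask = (~grid.usable) | (sample <= 0) | (control <= 0)
    if mask.all():
        raise InsufficientDataError("every window is masked; nothing to normalize")
    S = float(sample[~mask].sum())
    K = float(control[~mask].sum())
    ratio = np.full(sample.size, np.nan)
    log2r = np.full(sample.size, np.nan)
    ok = ~mask
    ratio[ok] = (sample[ok] / S) / (control[ok] / K)
    # Recentre on the median unmasked window: total-count scaling is
    # perturbed by large CNVs themselves (a trisomy inflates S), while
    # the median window of a mostly-diploid genome sits at ratio 1.
    med = float(np.median(ratio[ok]))
    if med > 0:
        ratio[ok] /= med
    log2r[ok] = np.log2(ratio[ok])
    return NormalizedProfile(sample_id=sample_id, grid_ref=grid.checksum(),
                             corrected_counts=sample, ratio=ratio,
                             log2_ratio=log2r, mask=mask, grid=grid)


def normalize_counts(sample_wc: WindowCounts, control_wc: WindowCounts,
                     grid: WindowGrid, span: float = 0.3) -> NormalizedProfile:
    """GC-correct sample and control independently, then normalize."""
    s = gc_loess_correct(sample_wc, grid, span=span)
    k = gc_loess_correct(control_wc, grid, span=span)
    return normalize_to_control(s, k, grid, sample_id=sample_wc.sample_id)


def write_profile(profile: NormalizedProfile, grid: WindowGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={profile.sample_id}\n")
        fh.write(f"#grid={profile.grid_ref}\n")
        fh.write("#chrom\tstart\tend\tratio\tlog2_ratio\tmask\n")
        for i in range(grid.n_windows):
            r = profile.ratio[i]
            x = profile.log2_ratio[i]
            fh.write(f"{grid.chrom[i]}\t{grid.start[i]}\t{grid.end[i]}\t"
                     f"{'NA' if np.isnan(r) else format(r, '.6g')}\t"
                     f"{'NA' if np.isnan(x) else format(x, '.6g')}\t"
                     f"{int(profile.mask[i])}\n")
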