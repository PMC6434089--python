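"""Circular binary segmentation (CBS) of per-window log2 ratios.

Each chromosome is segmented recursively: the arc (i, j) maximizing a
pooled-variance two-sample t statistic between the arc and its
complement is found exhaustively; the split is accepted when its
permutation p-value (random shufflings of the values within the piece
under test) is below ``alpha``, and the recursion continues on the
resulting pieces.  Circular arcs are covered implicitly: the statistic
of an arc equals that of its (wrapping) complement, so enumerating
0 <= i < j <= n reaches every circular split.

Afterwards adjacent segments whose means differ by less than
``prune_sd`` standard errors of the mean difference are merged; the
per-window noise SD behind that standard error is estimated robustly
from the sample's own MAPD as MAPD / (0.6745 * sqrt(2)).

Permutation p-values use the sequential Monte-Carlo rule of Besag &
Clifford: sampling stops at the 10th exceedance or after
min(n_permutations, 10/alpha) shufflings, and the p estimate is the
exceedance fraction at the stop.  Everything is deterministic given
the configuration seed; each (chromosome, piece) gets its own seed
stream so decisions at one site do not perturb another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .errors import InvalidParameterError
from .normalize import NormalizedProfile
from .qc import MAPD_IID_FACTOR, mapd

_T_CAP = 1e12  # stands in for an infinite t on zero-variance splits


@dataclass
class CbsConfig:
    alpha: float = 0.01
    n_permutations: int = 10_000
    min_segment_windows: int = 3
    seed: int = 0
    prune_sd: float = 1.5
    circular: bool = True

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise InvalidParameterError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_permutations < 100:
            raise InvalidParameterError("n_permutations must be >= 100")


@dataclass
class Segment:
    chrom: str
    start_window: int
    end_window: int
    start_bp: int
    end_bp: int
    mean_log2_ratio: float
    n_windows: int

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class SegmentSet:
    segments: List[Segment]
    seed: int = 0
    config: Optional[CbsConfig] = None

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def __getitem__(self, idx):
        return self.segments[idx]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#seed={self.seed}\n")
            fh.write("#chrom\tstart_bp\tend_bp\tn_windows\tmean_log2_ratio\n")
            for s in self.segments:
                fh.write(f"{s.chrom}\t{s.start_bp}\t{s.end_bp}\t{s.n_windows}\t"
                         f"{s.mean_log2_ratio:.6g}\n")

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.segments:
                fh.write(f"{s.chrom}\t{s.start_bp}\t{s.end_bp}\t"
                         f"{s.mean_log2_ratio:.4f}\n")


def arc_statistic(x: Sequence[float], i: int, j: int) -> float:
    """|t| comparing mean of x[i:j] against the complement, pooled variance.

    Returns a large finite cap instead of infinity when the pooled
    variance vanishes while the means differ.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not (0 <= i < j <= n):
        raise InvalidParameterError(f"invalid arc ({i}, {j}) for n={n}")
    k = j - i
    if k == n:
        raise InvalidParameterError("arc complement is empty")
    arc = x[i:j]
    comp = np.concatenate([x[:i], x[j:]])
    m1, m2 = arc.mean(), comp.mean()
    ss = float(((arc - m1) ** 2).sum() + ((comp - m2) ** 2).sum())
    dof = n - 2
    if dof <= 0 or ss <= 1e-300 * n:
        return 0.0 if abs(m1 - m2) < 1e-12 else _T_CAP
    s2 = ss / dof
    return float(abs(m1 - m2) / np.sqrt(s2 * (1.0 / k + 1.0 / (n - k))))


# The pooled-variance |t| of arc (i, j) is a strictly increasing function
# of v = u^2 * (1/k + 1/(n-k)), where u is the mean-centered arc sum
# (u = C[j] - C[i] with C the centered cumulative sum) and k = j - i:
#     t^2 = (n-2) * v / (ss_tot - v).
# The kernels therefore maximize v, which needs only a subtraction, a
# multiply and a compare per arc, and convert to t once at the end.


@njit(cache=True)
def _centered_cumsum(x):  # pragma: no cover - numba
    n = x.size
    mean = 0.0
    for a in range(n):
        mean += x[a]
    mean /= n
    csc = np.empty(n + 1)
    csc[0] = 0.0
    ss_tot = 0.0
    for a in range(n):
        d = x[a] - mean
        csc[a + 1] = csc[a] + d
        ss_tot += d * d
    return csc, ss_tot


@njit(cache=True)
def _v_to_t(v, ss_tot, n):  # pragma: no cover - numba
    if v <= 0.0:
        return 0.0
    denom = ss_tot - v
    if n - 2 <= 0 or denom <= 1e-300 * n:
        return 1e12
    return np.sqrt((n - 2) * v / denom)


@njit(cache=True)
def _arc_weights(n):  # pragma: no cover - numba
    w = np.zeros(n + 1)
    for k in range(1, n):
        w[k] = 1.0 / k + 1.0 / (n - k)
    return w


@njit(cache=True)
def _scan_best_arc(x, min_seg, circular):  # pragma: no cover - numba
    """Exhaustive max-|T| arc with tie-break (smallest i, then j).

    Returns (t, v, i, j); (i, j) == (-1, -1) when no admissible arc.
    """
    n = x.size
    csc, ss_tot = _centered_cumsum(x)
    w = _arc_weights(n)
    best_v = -1.0
    best_i = -1
    best_j = -1
    for k in range(min_seg, n - min_seg + 1):
        # Admissible arc starts for this length, ascending: i = 0 (a
        # single cut at k) then min_seg..n-k-min_seg (two interior
        # cuts).  Arcs ending at n are complements of (0, i) — the same
        # split — and are not enumerated twice.
        u = csc[k] - csc[0]
        bu2 = u * u
        bi = 0
        if circular:
            for i in range(min_seg, n - k - min_seg + 1):
                u = csc[i + k] - csc[i]
                u2 = u * u
                if u2 > bu2:
                    bu2 = u2
                    bi = i
        v = bu2 * w[k]
        j = bi + k
        if v > best_v or (v == best_v and
                          (bi < best_i or (bi == best_i and j < best_j))):
            best_v = v
            best_i = bi
            best_j = j
    if best_i < 0:
        return -1.0, -1.0, -1, -1
    return _v_to_t(best_v, ss_tot, n), best_v, best_i, best_j


@njit(cache=True)
def _max_arc_v(csc, n, w, min_seg, circular):  # pragma: no cover - numba
    """Max v over admissible arcs (permutation inner loop)."""
    best_v = -1.0
    for k in range(min_seg, n - min_seg + 1):
        u = csc[k] - csc[0]
        bu2 = u * u
        if circular:
            for i in range(min_seg, n - k - min_seg + 1):
                u = csc[i + k] - csc[i]
                u2 = u * u
                if u2 > bu2:
                    bu2 = u2
        v = bu2 * w[k]
        if v > best_v:
            best_v = v
    return best_v


@njit(cache=True)
def _permutation_exceedances(x, obs_v, min_seg, circular, m_limit, h,
                             seed):  # pragma: no cover - numba
    """Sequential Monte-Carlo permutation test (Besag-Clifford).

    Compares the arc criterion v (monotone in |t|; the total SS is
    permutation-invariant, so v-comparison equals t-comparison).  Stops
    at the ``h``-th exceedance or after ``m_limit`` permutations; the
    p-value estimate is exceed/m at the stop.
    """
    np.random.seed(seed)
    y = x.copy()
    n = y.size
    w = _arc_weights(n)
    exceed = 0
    m = 0
    for p in range(m_limit):
        # Fisher-Yates shuffle of y in place
        for a in range(n - 1, 0, -1):
            b = np.random.randint(0, a + 1)
            tmp = y[a]
            y[a] = y[b]
            y[b] = tmp
        csc, _ = _centered_cumsum(y)
        v = _max_arc_v(csc, n, w, min_seg, circular)
        m += 1
        if v >= obs_v - 1e-12:
            exceed += 1
            if exceed >= h:
                return exceed, m
    return exceed, m


def best_arc(x: np.ndarray, min_seg: int, circular: bool = True,
             ) -> Tuple[float, int, int]:
    """Best arc (max |T|) under the width constraints; (-1,-1) if none."""
    t, _v, i, j = _scan_best_arc(np.ascontiguousarray(x, dtype=np.float64),
                                 min_seg, circular)
    return float(t), int(i), int(j)


#: exceedances at which the sequential permutation test stops
_SEQ_H = 10


def _split_significant(x: np.ndarray, obs_v: float, cfg: CbsConfig,
                       site_seed: int) -> bool:
    m_limit = min(cfg.n_permutations, int(np.ceil(_SEQ_H / cfg.alpha)))
    exceed, m = _permutation_exceedances(
        np.ascontiguousarray(x, dtype=np.float64), obs_v,
        cfg.min_segment_windows, cfg.circular, m_limit, _SEQ_H, site_seed)
    return exceed / m < cfg.alpha


def _segment_piece(x: np.ndarray, lo: int, hi: int, cfg: CbsConfig,
                   chrom_idx: int, boundaries: List[int]) -> None:
    n = hi - lo
    if n < 2 * cfg.min_segment_windows:
        return
    t, v, i, j = _scan_best_arc(np.ascontiguousarray(x[lo:hi], dtype=np.float64),
                                cfg.min_segment_windows, cfg.circular)
    if i < 0 or t <= 0:
        return
    site_seed = int(np.random.SeedSequence(
        [cfg.seed, chrom_idx, lo, hi]).generate_state(1)[0] % (2 ** 31))
    if not _split_significant(x[lo:hi], float(v), cfg, site_seed):
        return
    cuts = sorted({lo + i, lo + j} - {lo, hi})
    for c in cuts:
        boundaries.append(c)
    edges = [lo] + cuts + [hi]
    for a, b in zip(edges[:-1], edges[1:]):
        _segment_piece(x, a, b, cfg, chrom_idx, boundaries)


def _prune_segments(x: np.ndarray, edges: List[int], noise_sd: float,
                    prune_sd: float) -> List[int]:
    """Merge adjacent segments whose mean difference is insignificant.

    The scale is the standard error of the difference of the two
    segment means, noise_sd * sqrt(1/n1 + 1/n2): a pair merges when the
    difference is below ``prune_sd`` such units.  (Per-window SD units
    would make the threshold independent of segment length and swallow
    genuine half-copy steps whenever per-window noise is comparable to
    log2(3/2).)
    """
    edges = list(edges)
    while len(edges) > 2:
        ns = np.diff(edges)
        means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
        se = noise_sd * np.sqrt(1.0 / ns[:-1] + 1.0 / ns[1:])
        z = np.abs(np.diff(means)) / np.maximum(se, 1e-300)
        k = int(np.argmin(z))
        if z[k] < prune_sd:
            del edges[k + 1]
        else:
            break
    return edges


def cbs_segment(profile: NormalizedProfile, cfg: Optional[CbsConfig] = None) -> SegmentSet:
    """Segment every chromosome of a normalized profile.

    Returns segments that partition the unmasked windows of each
    chromosome; ``start_window``/``end_window`` index the unmasked
    windows globally (half-open), ``start_bp``/``end_bp`` are the grid
    coordinates of the first and last member window.
    """
    if cfg is None:
        cfg = CbsConfig()
    grid = profile.grid
    if grid is None:
        raise InvalidParameterError("profile must carry its grid for segmentation")
    try:
        noise_sd = mapd(profile) / MAPD_IID_FACTOR
    except Exception:
        noise_sd = 0.0
    segments: List[Segment] = []
    unmasked_offset = 0
    for chrom_idx, (chrom, sl) in enumerate(grid.chrom_slices.items()):
        keep = ~profile.mask[sl]
        x = profile.log2_ratio[sl][keep]
        if x.size == 0:
            continue
        grid_idx = np.arange(sl.start, sl.stop)[keep]
        boundaries: List[int] = []
        _segment_piece(x, 0, x.size, cfg, chrom_idx, boundaries)
        edges = [0] + sorted(boundaries) + [x.size]
        if noise_sd > 0 and cfg.prune_sd > 0:
            edges = _prune_segments(x, edges, noise_sd, cfg.prune_sd)
        for a, b in zip(edges[:-1], edges[1:]):
            segments.append(Segment(
                chrom=chrom,
                start_window=unmasked_offset + a,
                end_window=unmasked_offset + b,
                start_bp=int(grid.start[grid_idx[a]]),
                end_bp=int(grid.end[grid_idx[b - 1]]),
                mean_log2_ratio=float(x[a:b].mean()),
                n_windows=b - a,
            ))
        unmasked_offset += x.size
    return SegmentSet(segments=segments, seed=cfg.seed, config=cfg)
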