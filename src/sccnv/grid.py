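"""Fixed-size genomic window grids.

The whole analysis is window-based: every chromosome is tiled with
fixed-size windows (20 kbp by default), each annotated with its GC and N
fraction and a usability flag.  Trailing partial windows are kept in the
grid but marked unusable, so window indices are reproducible from the
chromosome lengths alone.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping

import numpy as np

from .errors import ConfigurationError, InvalidParameterError

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def is_autosome(chrom: str) -> bool:
    return chrom not in _SEX_CHROMS


@dataclass
class WindowGrid:
    """Ordered window tiling of a genome with GC/N annotation.

    Arrays are parallel, one entry per window, ordered by chromosome (in
    insertion order) and position.  ``usable`` is False for trailing
    partial windows and for windows whose N fraction exceeds the filter.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc_fraction: np.ndarray
    n_fraction: np.ndarray
    usable: np.ndarray
    window_size: int
    genome_id: str = ""
    _chrom_slices: Dict[str, slice] = field(default=None, repr=False, compare=False)

    @property
    def n_windows(self) -> int:
        return self.start.size

    @property
    def width(self) -> np.ndarray:
        return self.end - self.start

    @property
    def chrom_slices(self) -> Dict[str, slice]:
        """Mapping chromosome -> slice of contiguous window indices."""
        if self._chrom_slices is None:
            slices: Dict[str, slice] = {}
            chroms = self.chrom
            lo = 0
            for i in range(1, chroms.size + 1):
                if i == chroms.size or chroms[i] != chroms[lo]:
                    slices[str(chroms[lo])] = slice(lo, i)
                    lo = i
            object.__setattr__(self, "_chrom_slices", slices)
        return self._chrom_slices

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: int(self.end[s][-1]) for c, s in self.chrom_slices.items()}

    def checksum(self) -> str:
        """Short digest of the window coordinates; identifies the grid."""
        h = hashlib.md5()
        h.update(str(self.window_size).encode())
        for c, s in self.chrom_slices.items():
            h.update(c.encode())
            h.update(self.start[s].tobytes())
            h.update(self.end[s].tobytes())
        return h.hexdigest()[:12]

    def autosomal(self) -> np.ndarray:
        """Boolean mask of windows on autosomes."""
        auto = np.array([is_autosome(c) for c in self.chrom_slices], dtype=bool)
        out = np.empty(self.n_windows, dtype=bool)
        for flag, (c, s) in zip(auto, self.chrom_slices.items()):
            out[s] = flag
        return out


def make_window_grid(chrom_lengths: Mapping[str, int], window_size: int,
                     genome_id: str = "") -> WindowGrid:
    """Tile every chromosome with fixed-size windows.

    The last window of a chromosome may be shorter than ``window_size``;
    it is kept (so indices are length-derivable) but flagged unusable.
    GC fraction is initialised to a flat placeholder until annotated.
    """
    if not isinstance(window_size, (int, np.integer)) or window_size <= 0:
        raise InvalidParameterError(f"window_size must be a positive integer, got {window_size!r}")
    chroms, starts, ends, usable = [], [], [], []
    for chrom, length in chrom_lengths.items():
        length = int(length)
        if length <= 0:
            raise InvalidParameterError(f"chromosome {chrom} has non-positive length {length}")
        s = np.arange(0, length, window_size, dtype=np.int64)
        e = np.minimum(s + window_size, length)
        chroms.append(np.full(s.size, chrom, dtype=object))
        starts.append(s)
        ends.append(e)
        usable.append(e - s == window_size)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    n = start.size
    return WindowGrid(
        chrom=np.concatenate(chroms),
        start=start,
        end=end,
        gc_fraction=np.full(n, 0.4),
        n_fraction=np.zeros(n),
        usable=np.concatenate(usable),
        window_size=int(window_size),
        genome_id=genome_id,
    )


def annotate_from_fasta(grid: WindowGrid, fasta, n_max: float = 0.0,
                        gc_over_non_n: bool = False) -> WindowGrid:
    """Annotate GC and N fractions from a reference FASTA.

    ``fasta`` is a path or an open :class:`pyfaidx.Fasta`.  A window with
    ``n_fraction > n_max`` (default 0: any N disqualifies) is marked
    unusable, as are trailing partial windows.  GC is computed over the
    full window length by default; set ``gc_over_non_n`` to divide by the
    non-N base count instead.  Idempotent.
    """
    import pyfaidx

    if not isinstance(fasta, pyfaidx.Fasta):
        fasta = pyfaidx.Fasta(str(fasta))
    gc = np.empty(grid.n_windows)
    nf = np.empty(grid.n_windows)
    for chrom, sl in grid.chrom_slices.items():
        if chrom not in fasta:
            raise ConfigurationError(f"chromosome {chrom!r} missing from reference FASTA")
        seq = str(fasta[chrom][:]).upper()
        chrom_len = int(grid.end[sl][-1])
        if len(seq) < chrom_len:
            raise ConfigurationError(
                f"reference sequence for {chrom!r} is shorter than the grid ({len(seq)} < {chrom_len})")
        for i in range(sl.start, sl.stop):
            w = seq[grid.start[i]:grid.end[i]]
            width = len(w)
            n_count = w.count("N")
            gc_count = w.count("G") + w.count("C")
            denom = (width - n_count) if gc_over_non_n else width
            gc[i] = gc_count / denom if denom > 0 else 0.0
            nf[i] = n_count / width
    usable = (grid.width == grid.window_size) & (nf <= n_max)
    return replace(grid, gc_fraction=gc, n_fraction=nf, usable=usable, _chrom_slices=None)


def aggregation_groups(grid: WindowGrid, factor: int) -> np.ndarray:
    """Group index per window when merging runs of ``factor`` windows.

    Groups never cross chromosome boundaries; the last group of a
    chromosome may contain fewer than ``factor`` members.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise InvalidParameterError(f"aggregation factor must be an integer >= 1, got {factor!r}")
    groups = np.empty(grid.n_windows, dtype=np.int64)
    offset = 0
    for _, sl in grid.chrom_slices.items():
        n = sl.stop - sl.start
        g = np.arange(n) // factor
        groups[sl] = g + offset
        offset += int(g[-1]) + 1
    return groups


def aggregate_grid(grid: WindowGrid, factor: int) -> WindowGrid:
    """Merge consecutive runs of ``factor`` windows within each chromosome.

    Merged GC/N fractions are length-weighted means; a merged window is
    usable only if every member is usable.
    """
    if factor == 1:
        return grid
    groups = aggregation_groups(grid, factor)
    n_groups = int(groups[-1]) + 1
    width = grid.width.astype(float)
    tot_w = np.bincount(groups, weights=width, minlength=n_groups)
    gc = np.bincount(groups, weights=width * grid.gc_fraction, minlength=n_groups) / tot_w
    nf = np.bincount(groups, weights=width * grid.n_fraction, minlength=n_groups) / tot_w
    usable = np.bincount(groups, weights=(~grid.usable).astype(float), minlength=n_groups) == 0
    first = np.searchsorted(groups, np.arange(n_groups), side="left")
    last = np.searchsorted(groups, np.arange(n_groups), side="right") - 1
    return WindowGrid(
        chrom=grid.chrom[first].copy(),
        start=grid.start[first].copy(),
        end=grid.end[last].copy(),
        gc_fraction=gc,
        n_fraction=nf,
        usable=usable,
        window_size=grid.window_size * int(factor),
        genome_id=grid.genome_id,
    )


def write_grid(grid: WindowGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#genome_id={grid.genome_id}\n")
        fh.write(f"#window_size={grid.window_size}\n")
        fh.write(f"#checksum={grid.checksum()}\n")
        fh.write("#chrom\tstart\tend\tgc\tn\tusable\n")
        for i in range(grid.n_windows):
            fh.write(f"{grid.chrom[i]}\t{grid.start[i]}\t{grid.end[i]}\t"
                     f"{grid.gc_fraction[i]:.6g}\t{grid.n_fraction[i]:.6g}\t"
                     f"{int(grid.usable[i])}\n")


def read_grid(path) -> WindowGrid:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k] = v
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ConfigurationError(f"empty grid file: {path}")
    chrom = np.array([r[0] for r in rows], dtype=object)
    return WindowGrid(
        chrom=chrom,
        start=np.array([int(r[1]) for r in rows], dtype=np.int64),
        end=np.array([int(r[2]) for r in rows], dtype=np.int64),
        gc_fraction=np.array([float(r[3]) for r in rows]),
        n_fraction=np.array([float(r[4]) for r in rows]),
        usable=np.array([bool(int(r[5])) for r in rows]),
        window_size=int(meta.get("window_size", 0)),
        genome_id=meta.get("genome_id", ""),
    )
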