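"""Per-window read counting from single-end alignments.

Reads are kept when they are uniquely mapped (primary alignment, MAPQ at
or above the threshold), span at least ``len_min`` reference bases, and
are not duplicates.  Duplicates are defined for single-end data as reads
sharing (chromosome, leftmost aligned position, strand); the
highest-MAPQ read of a group survives, ties broken by read-name order.
Each kept read increments exactly one window, chosen by its leftmost
aligned base.  Unusable windows still accumulate counts — filtering
happens downstream in normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigurationError, GridMismatchError
from .grid import WindowGrid, aggregation_groups

KITS = ("MALBAC", "PicoPLEX", "GenomePlex", "MDA", "bulk", "none")
SAMPLE_TYPES = ("gDNA", "single_cell", "multi_cell", "bulk")


@dataclass
class WindowCounts:
    """Filtered read counts aligned to a :class:`WindowGrid`."""

    sample_id: str
    counts: np.ndarray
    grid_ref: str
    kit: str = "none"
    sample_type: str = "single_cell"
    total_filtered_reads: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.total_filtered_reads == 0:
            self.total_filtered_reads = int(round(float(self.counts.sum())))


@dataclass
class ReadFilterStats:
    """Per-category read rejection tallies; each read counted once."""

    n_total: int = 0
    n_unmapped: int = 0
    n_low_mapq: int = 0
    n_short: int = 0
    n_duplicate: int = 0
    n_kept: int = 0

    def as_text(self) -> str:
        return "".join(f"{k}={v}\n" for k, v in vars(self).items())


def _is_sorted_by_coordinate(header) -> bool:
    hd = header.get("HD", {})
    return hd.get("SO") == "coordinate"


def filter_and_count(alignments, grid: WindowGrid, mapq_min: int = 10,
                     len_min: int = 35, dedup: bool = True,
                     sample_id: Optional[str] = None, kit: str = "none",
                     sample_type: str = "single_cell",
                     ) -> Tuple[WindowCounts, ReadFilterStats]:
    """Apply read filters to a BAM/SAM file and count reads per window.

    ``alignments`` is a path or an open :class:`pysam.AlignmentFile`.
    Filters are applied in order (each read lands in the first failing
    category): mapped/primary, MAPQ, aligned reference length, duplicate.
    Duplicate detection requires coordinate-sorted input.
    """
    import pysam

    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        if sample_id is None:
            sample_id = alignments.filename.decode() if isinstance(
                alignments.filename, bytes) else str(alignments.filename)
    if sample_id is None:
        sample_id = "sample"

    missing = [c for c in grid.chrom_slices if c not in alignments.references]
    if missing:
        raise ConfigurationError(
            "grid chromosomes missing from alignment header: " + ", ".join(missing))
    if dedup and not _is_sorted_by_coordinate(alignments.header.to_dict()):
        raise ConfigurationError(
            "duplicate removal requires a coordinate-sorted input (HD SO:coordinate)")

    slices = grid.chrom_slices
    starts_by_chrom = {c: grid.start[s] for c, s in slices.items()}
    ends_by_chrom = {c: grid.end[s] for c, s in slices.items()}

    stats = ReadFilterStats()
    counts = np.zeros(grid.n_windows, dtype=np.int64)

    # Streaming duplicate groups: all candidate reads at one (chrom, pos),
    # split by strand when flushed.
    group_key = None
    group: list = []

    def flush():
        nonlocal group
        if not group:
            return
        for strand in (False, True):
            members = [g for g in group if g[0] == strand]
            if not members:
                continue
            if dedup:
                members.sort(key=lambda g: (-g[1], g[2]))
                stats.n_duplicate += len(members) - 1
                members = members[:1]
            for _, _, _, widx in members:
                counts[widx] += 1
                stats.n_kept += 1
        group = []

    for read in alignments.fetch(until_eof=True):
        stats.n_total += 1
        chrom = read.reference_name
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or chrom not in slices):
            stats.n_unmapped += 1
            continue
        if read.mapping_quality < mapq_min:
            stats.n_low_mapq += 1
            continue
        ref_len = read.reference_length or 0
        if ref_len < len_min:
            stats.n_short += 1
            continue
        if read.is_duplicate:
            stats.n_duplicate += 1
            continue
        pos = read.reference_start
        sl = slices[chrom]
        cs = starts_by_chrom[chrom]
        widx = int(np.searchsorted(cs, pos, side="right")) - 1
        if widx < 0 or pos >= ends_by_chrom[chrom][widx]:
            stats.n_unmapped += 1  # off the tiled region
            continue
        widx += sl.start
        key = (chrom, pos)
        if key != group_key:
            flush()
            group_key = key
        group.append((read.is_reverse, read.mapping_quality, read.query_name, widx))
    flush()

    wc = WindowCounts(sample_id=sample_id, counts=counts, grid_ref=grid.checksum(),
                      kit=kit, sample_type=sample_type,
                      total_filtered_reads=stats.n_kept)
    return wc, stats


def aggregate_counts(wc: WindowCounts, grid: WindowGrid, factor: int,
                     agg_grid: Optional[WindowGrid] = None) -> WindowCounts:
    """Sum counts over runs of ``factor`` grid windows (for multi-size MAPD)."""
    from .grid import aggregate_grid

    groups = aggregation_groups(grid, factor)
    agg = np.bincount(groups, weights=wc.counts.astype(float),
                      minlength=int(groups[-1]) + 1)
    if agg_grid is None:
        agg_grid = aggregate_grid(grid, factor)
    if np.allclose(agg, np.round(agg)):
        agg = np.round(agg).astype(np.int64)
    return WindowCounts(sample_id=wc.sample_id, counts=agg,
                        grid_ref=agg_grid.checksum(), kit=wc.kit,
                        sample_type=wc.sample_type,
                        total_filtered_reads=wc.total_filtered_reads)


def pool_counts(counts_list, sample_id: str = "pooled") -> WindowCounts:
    """Pool several count profiles (e.g. reference controls) by summing."""
    first = counts_list[0]
    if any(wc.grid_ref != first.grid_ref for wc in counts_list):
        raise GridMismatchError("cannot pool counts from different grids")
    total = np.sum([np.asarray(wc.counts) for wc in counts_list], axis=0)
    return WindowCounts(sample_id=sample_id, counts=total,
                        grid_ref=first.grid_ref, kit=first.kit,
                        sample_type=first.sample_type)


def write_counts(wc: WindowCounts, grid: WindowGrid, path) -> None:
    """Serialize counts as TSV with a '#key=value' metadata header."""
    with open(path, "w") as fh:
        fh.write(f"#sample_id={wc.sample_id}\n")
        fh.write(f"#kit={wc.kit}\n")
        fh.write(f"#sample_type={wc.sample_type}\n")
        fh.write(f"#grid={wc.grid_ref}\n")
        fh.write(f"#total_filtered_reads={wc.total_filtered_reads}\n")
        fh.write("#chrom\tstart\tend\tcount\n")
        for i in range(grid.n_windows):
            c = wc.counts[i]
            c = int(c) if float(c).is_integer() else float(c)
            fh.write(f"{grid.chrom[i]}\t{grid.start[i]}\t{grid.end[i]}\t{c}\n")


def read_counts(path, grid: WindowGrid) -> WindowCounts:
    """Read a count table back; refuses a table written on a different grid."""
    meta = {}
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k] = v
                continue
            vals.append(float(line.split("\t")[3]))
    if meta.get("grid") != grid.checksum():
        raise GridMismatchError(
            f"count table was written on grid {meta.get('grid')!r}, "
            f"not the supplied grid {grid.checksum()!r}")
    counts = np.array(vals)
    if np.allclose(counts, np.round(counts)):
        counts = np.round(counts).astype(np.int64)
    return WindowCounts(sample_id=meta.get("sample_id", "sample"), counts=counts,
                        grid_ref=meta["grid"], kit=meta.get("kit", "none"),
                        sample_type=meta.get("sample_type", "single_cell"),
                        total_filtered_reads=int(meta.get("total_filtered_reads", 0)))
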