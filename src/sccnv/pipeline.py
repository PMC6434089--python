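"""End-to-end orchestration: count -> GC-correct -> normalize -> QC gate
-> CBS -> call -> karyotype report.

The QC gate aborts (``QcFailureError``) when MAPD at the evaluation
window size exceeds 0.4 or fewer than 90% of windows reach 20% of the
mean count, unless ``force`` is set — in which case calls are still
emitted and the report flags the failure.  Every run records the exact
thresholds used so results are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import List, Optional, Union

from . import __version__
from .calling import BandTable, CallingConfig, CnvCall, call_cnvs, render_karyotype, write_calls
from .counts import WindowCounts, filter_and_count, read_counts, write_counts
from .errors import QcFailureError
from .grid import WindowGrid
from .normalize import NormalizedProfile, normalize_counts, write_profile
from .qc import DEFAULT_COVERAGE_MIN, DEFAULT_MAPD_MAX, QcReport, compute_qc_report
from .segment import CbsConfig, SegmentSet, cbs_segment


@dataclass
class PipelineConfig:
    window_size: int = 20_000
    qc_window_size: int = 100_000
    mapq_min: int = 10
    len_min: int = 35
    loess_span: float = 0.3
    mapd_max: float = DEFAULT_MAPD_MAX
    coverage_min: float = DEFAULT_COVERAGE_MIN
    cbs: CbsConfig = field(default_factory=CbsConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    sex_of_control: str = "XX"
    sample_sex: Optional[str] = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.md5(json.dumps(self.to_dict(), sort_keys=True,
                                      default=str).encode()).hexdigest()[:12]

    def to_file(self, path) -> None:
        """Flat ``key=value`` serialization (nested fields dot-prefixed)."""
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                if isinstance(value, dict):
                    for k2, v2 in value.items():
                        if isinstance(v2, (list, tuple)):
                            continue
                        fh.write(f"{key}.{k2}={v2}\n")
                elif not isinstance(value, (list, tuple)):
                    fh.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Read a key=value config file; keyword overrides win over the
        file, the file wins over defaults."""
        def coerce(text):
            text = text.strip()
            low = text.lower()
            if low in ("true", "false"):
                return low == "true"
            if low in ("none", ""):
                return None
            for cast in (int, float):
                try:
                    return cast(text)
                except ValueError:
                    continue
            return text

        top, nested = {}, {"cbs": {}, "calling": {}}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, value = line.split("=", 1)
                key = key.strip()
                if "." in key:
                    group, sub = key.split(".", 1)
                    if group in nested:
                        nested[group][sub] = coerce(value)
                else:
                    top[key] = coerce(value)
        top = {k: v for k, v in top.items()
               if k in {f.name for f in dataclasses.fields(cls)}
               and k not in ("cbs", "calling")}
        nested["cbs"] = {k: v for k, v in nested["cbs"].items()
                         if k in {f.name for f in dataclasses.fields(CbsConfig)}}
        nested["calling"] = {k: v for k, v in nested["calling"].items()
                             if k in {f.name for f in dataclasses.fields(CallingConfig)}}
        cfg = cls(cbs=CbsConfig(**nested["cbs"]),
                  calling=CallingConfig(**nested["calling"]), **top)
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, value)
        return cfg


@dataclass
class PipelineResult:
    qc: QcReport
    profile: NormalizedProfile
    segments: SegmentSet
    calls: List[CnvCall]
    karyotype: str
    summary: dict


def _as_counts(source: Union[WindowCounts, str, os.PathLike], grid: WindowGrid,
               cfg: PipelineConfig) -> WindowCounts:
    if isinstance(source, WindowCounts):
        return source
    path = str(source)
    if path.endswith((".bam", ".sam", ".cram")):
        wc, _ = filter_and_count(path, grid, mapq_min=cfg.mapq_min,
                                 len_min=cfg.len_min)
        return wc
    return read_counts(path, grid)


def run_pipeline(sample: Union[WindowCounts, str], control: Union[WindowCounts, str],
                 grid: WindowGrid, cfg: Optional[PipelineConfig] = None,
                 band_table: Optional[BandTable] = None, force: bool = False,
                 outdir: Optional[str] = None) -> PipelineResult:
    """Run the full analysis on one sample against one control.

    ``sample``/``control`` may be WindowCounts, count-table paths or
    BAM/SAM paths.  Raises :class:`QcFailureError` on a failed quality
    gate unless ``force`` is given.  With ``outdir`` set, all
    intermediate artifacts are written with provenance metadata.
    """
    if cfg is None:
        cfg = PipelineConfig(window_size=grid.window_size)
    sample_wc = _as_counts(sample, grid, cfg)
    control_wc = _as_counts(control, grid, cfg)

    qc = compute_qc_report(sample_wc, control_wc, grid,
                           qc_window_size=cfg.qc_window_size,
                           span=cfg.loess_span, mapd_max=cfg.mapd_max,
                           coverage_min=cfg.coverage_min)
    if not qc.qc_pass and not force:
        raise QcFailureError(
            f"sample failed QC: MAPD[{qc.evaluation_window_size}]="
            f"{qc.mapd_by_window_size[qc.evaluation_window_size]:.3f} "
            f"(max {cfg.mapd_max}), coverage fraction "
            f"{qc.coverage_fraction_at_20pct:.3f} (min {cfg.coverage_min})",
            report=qc)

    profile = normalize_counts(sample_wc, control_wc, grid, span=cfg.loess_span)
    cbs_cfg = dataclasses.replace(cfg.cbs, seed=cfg.seed)
    segments = cbs_segment(profile, cbs_cfg)
    calls = call_cnvs(segments, cfg.calling)
    karyotype = render_karyotype(
        calls, sex_of_control=cfg.sex_of_control, chrom_lengths=grid.chrom_lengths,
        band_table=band_table, whole_chrom_fraction=cfg.calling.whole_chrom_fraction,
        sample_sex=cfg.sample_sex, label_margin=2 * grid.window_size)

    summary = {
        "sample_id": sample_wc.sample_id,
        "karyotype": karyotype,
        "n_calls": len(calls),
        "qc_pass": qc.qc_pass,
        "qc_pass_mapd": qc.qc_pass_mapd,
        "qc_pass_coverage": qc.qc_pass_coverage,
        "forced": bool(force and not qc.qc_pass),
        "thresholds": {
            "loss_log2": cfg.calling.loss_log2,
            "gain_log2": cfg.calling.gain_log2,
            "min_size_bp": cfg.calling.min_size_bp,
            "mapd_max": cfg.mapd_max,
            "coverage_min": cfg.coverage_min,
        },
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
    }
    result = PipelineResult(qc=qc, profile=profile, segments=segments,
                            calls=calls, karyotype=karyotype, summary=summary)
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        write_counts(sample_wc, grid, os.path.join(outdir, "sample_counts.tsv"))
        write_counts(control_wc, grid, os.path.join(outdir, "control_counts.tsv"))
        write_profile(profile, grid, os.path.join(outdir, "profile.tsv"))
        segments.write_tsv(os.path.join(outdir, "segments.tsv"))
        write_calls(calls, os.path.join(outdir, "calls.tsv"))
        with open(os.path.join(outdir, "qc.json"), "w") as fh:
            fh.write(qc.to_json())
        cfg.to_file(os.path.join(outdir, "config.txt"))
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
    return result


def plot_genome(profile: NormalizedProfile, segments: Optional[SegmentSet],
                path, gain_log2: float = 0.37, loss_log2: float = -0.51,
                exclude_chroms=("chrY", "Y")) -> None:
    """Genome-wide log2-ratio scatter with segment means overlaid.

    Adjacent chromosomes alternate color; the gain/loss cutoffs are drawn
    as dashed lines; chromosome Y is excluded by default.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = profile.grid
    fig, ax = plt.subplots(figsize=(14, 4))
    offset = 0
    offsets = {}
    ticks, labels = [], []
    colors = ("#1f77b4", "#ff7f0e")
    for k, (chrom, sl) in enumerate(grid.chrom_slices.items()):
        if chrom in exclude_chroms:
            continue
        offsets[chrom] = offset - int(grid.start[sl][0])
        x = profile.log2_ratio[sl]
        m = profile.mask[sl]
        pos = offset + (grid.start[sl] + grid.end[sl]) / 2 - grid.start[sl][0]
        ax.plot(pos[~m], x[~m], ".", ms=1.5, color=colors[k % 2], rasterized=True)
        width = int(grid.end[sl][-1]) - int(grid.start[sl][0])
        ticks.append(offset + width / 2)
        labels.append(chrom.removeprefix("chr"))
        offset += width
    if segments is not None:
        for s in segments:
            if s.chrom not in offsets:
                continue
            o = offsets[s.chrom]
            ax.plot([o + s.start_bp, o + s.end_bp],
                    [s.mean_log2_ratio] * 2, "-", color="red", lw=1.8)
    for y, style in ((gain_log2, "--"), (loss_log2, "--"), (0.0, ":")):
        ax.axhline(y, color="grey", ls=style, lw=0.8)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlim(0, offset)
    ax.set_ylim(-2.5, 2.5)
    ax.set_ylabel("log2 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
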