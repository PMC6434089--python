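"""Threshold-based CNV calling, karyotype rendering and concordance.

Segments become calls when their mean log2 ratio is below the loss
cutoff (−0.51, ratio ≈ 0.70) or above the gain cutoff (+0.37, ratio ≈
1.29) *and*, after merging adjacent same-direction passing segments,
the event spans more than the minimum size (4 Mbp).  The asymmetric
cutoffs tolerate mosaicism: they correspond to copy numbers of roughly
1.40 and 2.58 against a diploid control.

Calls are rendered in a simplified karyotype dialect mirroring clinical
reporting: modal chromosome number, sex token, then whole-chromosome
events as +N/−N and partial events as del(...)/dup(...) with
cytogenetic band labels when a band table is available (Mb coordinates
otherwise).  Chromosome Y is excluded from calling by default; when the
control is female and the sample male, the expected whole-X dosage loss
is absorbed into the sex token rather than reported as a CNV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import ConfigurationError, InvalidParameterError
from .segment import Segment, SegmentSet

_CHRY = {"chrY", "Y"}
_CHRX = {"chrX", "X"}


@dataclass
class CallingConfig:
    loss_log2: float = -0.51
    gain_log2: float = 0.37
    min_size_bp: int = 4_000_000
    whole_chrom_fraction: float = 0.8
    exclude_chroms: Tuple[str, ...] = ("chrY", "Y")
    #: same-direction passing segments separated by a neutral gap up to
    #: this size still merge into one event (segmentation can cut a
    #: single CNV with a short noise dip); None -> min_size_bp // 4.
    merge_gap_bp: Optional[int] = None

    def __post_init__(self):
        if not (self.loss_log2 < 0 < self.gain_log2):
            raise InvalidParameterError("need loss_log2 < 0 < gain_log2")
        if self.min_size_bp <= 0:
            raise InvalidParameterError("min_size_bp must be positive")
        if self.merge_gap_bp is None:
            self.merge_gap_bp = self.min_size_bp // 4


@dataclass
class CnvCall:
    chrom: str
    start_bp: int
    end_bp: int
    kind: str  # "gain" | "loss"
    mean_log2_ratio: float
    band_label: str = ""

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class KaryotypeSpec:
    """Ground-truth karyotype: sex token plus explicit copy-number events."""

    sex: str  # "XX" | "XY" | "XO"
    events: List[Tuple[str, int, int, int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end, cn in self.events:
            if cn < 0 or end <= start:
                raise InvalidParameterError(f"bad event {(chrom, start, end, cn)}")
            for s, e in by_chrom.get(chrom, []):
                if start < e and s < end:
                    raise InvalidParameterError(f"overlapping events on {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))

    def copy_number(self, chrom: str) -> int:
        """Baseline CN of a chromosome before events (control-independent)."""
        if chrom in _CHRX:
            return 1 if self.sex in ("XY", "XO") else 2
        if chrom in _CHRY:
            return 1 if self.sex == "XY" else 0
        return 2

    def expected_calls(self, chrom_lengths: Mapping[str, int]) -> List[CnvCall]:
        """Dosage events a CNV caller should report (sex-typical X/Y excluded).

        45,XO is a real monosomy, so sex == "XO" contributes a whole-X
        loss; a normal XY male contributes nothing.
        """
        calls = []
        for chrom, start, end, cn in self.events:
            base = self.copy_number(chrom)
            if cn == base:
                continue
            kind = "gain" if cn > base else "loss"
            calls.append(CnvCall(chrom, start, end, kind, 0.0))
        if self.sex == "XO":
            xc = "chrX" if any(c.startswith("chr") for c in chrom_lengths) else "X"
            if not any(c.chrom in _CHRX for c in calls):
                calls.append(CnvCall(xc, 0, int(chrom_lengths[xc]), "loss", 0.0))
        return calls


@dataclass
class ConcordanceResult:
    n_true_positive: int
    n_false_positive: int
    n_false_negative: int
    matched_pairs: List[Tuple[CnvCall, CnvCall]] = field(default_factory=list)


def call_cnvs(segments: Union[SegmentSet, Sequence[Segment]],
              cfg: Optional[CallingConfig] = None) -> List[CnvCall]:
    """Screen segments through the log2-ratio and size thresholds.

    Strict inequalities at both cutoffs and at the size filter.
    Same-direction passing segments merge before the size test when
    contiguous, and also across a neutral gap of at most
    ``merge_gap_bp`` (segmentation may cut one biological event with a
    short noise dip); the event-level size filter then applies to the
    merged span.
    """
    if cfg is None:
        cfg = CallingConfig()
    # per chromosome: classify passing segments
    passing: List[Tuple[str, int, int, str, float, int]] = []
    for seg in segments:
        if seg.chrom in cfg.exclude_chroms:
            continue
        if seg.mean_log2_ratio > cfg.gain_log2:
            kind = "gain"
        elif seg.mean_log2_ratio < cfg.loss_log2:
            kind = "loss"
        else:
            continue
        passing.append((seg.chrom, seg.start_bp, seg.end_bp, kind,
                        seg.mean_log2_ratio, seg.n_windows))

    calls: List[CnvCall] = []
    pending: Optional[CnvCall] = None
    pending_weight = 0

    def close():
        nonlocal pending, pending_weight
        if pending is not None and pending.size_bp > cfg.min_size_bp:
            calls.append(pending)
        pending, pending_weight = None, 0

    for chrom, start, end, kind, mean, n in passing:
        if (pending is not None and pending.kind == kind
                and pending.chrom == chrom
                and start - pending.end_bp <= cfg.merge_gap_bp):
            pending.mean_log2_ratio = (
                pending.mean_log2_ratio * pending_weight + mean * n
            ) / (pending_weight + n)
            pending.end_bp = end
            pending_weight += n
        else:
            close()
            pending = CnvCall(chrom, start, end, kind, mean)
            pending_weight = n
    close()
    return calls


# ---------------------------------------------------------------------------
# Cytogenetic band tables (UCSC cytoBand.txt format)

class BandTable:
    """Chromosome band intervals: (chrom, start, end, band, stain)."""

    def __init__(self, rows: Sequence[Tuple[str, int, int, str, str]]):
        self.by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
        for chrom, start, end, band, _stain in rows:
            self.by_chrom.setdefault(chrom, []).append((int(start), int(end), band))
        for v in self.by_chrom.values():
            v.sort()

    @classmethod
    def read(cls, path) -> "BandTable":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append((f[0], int(f[1]), int(f[2]), f[3],
                             f[4] if len(f) > 4 else ""))
        return cls(rows)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, bands in self.by_chrom.items():
                for start, end, band in bands:
                    fh.write(f"{chrom}\t{start}\t{end}\t{band}\tgneg\n")

    def _chrom_key(self, chrom: str) -> Optional[str]:
        for cand in (chrom, f"chr{chrom}", chrom.removeprefix("chr")):
            if cand in self.by_chrom:
                return cand
        return None

    def band_at(self, chrom: str, pos: int) -> Optional[str]:
        key = self._chrom_key(chrom)
        if key is None:
            return None
        for start, end, band in self.by_chrom[key]:
            if start <= pos < end:
                return band
        return None

    def band_span(self, chrom: str, band_start: str, band_end: str) -> Tuple[int, int]:
        """bp interval covered by the band range band_start..band_end."""
        key = self._chrom_key(chrom)
        if key is None:
            raise ConfigurationError(f"no bands for chromosome {chrom!r}")
        coords = []
        for name in (band_start, band_end):
            hit = [(s, e) for s, e, b in self.by_chrom[key] if b == name]
            if not hit:
                raise ConfigurationError(f"band {chrom}{name} not in table")
            coords.append(hit[0])
        lo = min(c[0] for c in coords)
        hi = max(c[1] for c in coords)
        return lo, hi


def _display_chrom(chrom: str) -> str:
    return chrom.removeprefix("chr")


def _chrom_sort_key(chrom: str) -> Tuple[int, str]:
    c = _display_chrom(chrom)
    return (int(c), "") if c.isdigit() else (100, c)


def _event_label(call: CnvCall, band_table: Optional[BandTable],
                 label_margin: int = 0) -> str:
    c = _display_chrom(call.chrom)
    if band_table is not None:
        # Nudge lookup positions inward: estimated breakpoints are
        # window-quantized and noisy, and a boundary off by a few
        # windows must not flip the reported band.
        margin = min(max(int(label_margin), call.size_bp // 20),
                     call.size_bp // 3)
        b1 = band_table.band_at(call.chrom, call.start_bp + margin)
        b2 = band_table.band_at(call.chrom,
                                max(call.start_bp, call.end_bp - 1 - margin))
        if b1 and b2:
            inner = f"{c}{b1}" if b1 == b2 else f"{c}{b1}-{b2}"
            return inner
    return f"{c}:{call.start_bp / 1e6:.2f}-{call.end_bp / 1e6:.2f}Mb"


def render_karyotype(calls: Sequence[CnvCall], sex_of_control: str,
                     chrom_lengths: Mapping[str, int],
                     band_table: Optional[BandTable] = None,
                     whole_chrom_fraction: float = 0.8,
                     sample_sex: Optional[str] = None,
                     label_margin: int = 0) -> str:
    """Render calls as a karyotype-style string, e.g. ``47,XX,+21``.

    A call covering at least ``whole_chrom_fraction`` of its chromosome
    is reported as a whole-chromosome event; the modal count is 46
    adjusted by whole-autosome events.  A whole-X loss against a female
    control renders as XO unless ``sample_sex`` says the sample is male,
    in which case the dosage difference is expected and dropped.
    """
    # Whole-chromosome detection works on the combined same-direction
    # coverage of a chromosome: an aneuploidy split by a short neutral
    # dip is still one aneuploidy.
    combined: Dict[Tuple[str, str], int] = {}
    for call in calls:
        if call.chrom not in chrom_lengths:
            raise ConfigurationError(f"no chromosome length for {call.chrom!r}")
        combined[(call.chrom, call.kind)] = (
            combined.get((call.chrom, call.kind), 0) + call.size_bp)
    whole: List[CnvCall] = []
    partial: List[CnvCall] = []
    seen_whole = set()
    for call in calls:
        key = (call.chrom, call.kind)
        if combined[key] >= whole_chrom_fraction * chrom_lengths[call.chrom]:
            if key not in seen_whole:
                seen_whole.add(key)
                whole.append(CnvCall(call.chrom, 0,
                                     int(chrom_lengths[call.chrom]),
                                     call.kind, call.mean_log2_ratio))
        else:
            partial.append(call)

    sex = sample_sex or sex_of_control
    modal = 46
    tokens_aneuploid: List[str] = []
    for call in sorted(whole, key=lambda c: _chrom_sort_key(c.chrom)):
        c = _display_chrom(call.chrom)
        if call.chrom in _CHRX:
            if call.kind == "loss":
                if sample_sex == "XY":
                    continue  # male vs female control: expected dosage
                sex = "XO"
                modal -= 1
            else:
                tokens_aneuploid.append("+X")
                modal += 1
            continue
        if call.kind == "gain":
            tokens_aneuploid.append(f"+{c}")
            modal += 1
        else:
            tokens_aneuploid.append(f"-{c}")
            modal -= 1
    # Partial calls in the same direction as a whole-chromosome event on
    # the same chromosome are part of that aneuploidy, not a second CNV.
    whole_keys = {(c.chrom, c.kind) for c in whole}
    partial = [c for c in partial if (c.chrom, c.kind) not in whole_keys]
    tokens_partial = []
    for call in sorted(partial, key=lambda c: (_chrom_sort_key(c.chrom), c.start_bp)):
        op = "dup" if call.kind == "gain" else "del"
        tokens_partial.append(f"{op}({_event_label(call, band_table, label_margin)})")
    out = f"{modal},{sex}"
    for t in tokens_aneuploid:
        out += f",{t}"
    for t in tokens_partial:
        out += f", {t}"
    return out


_EVENT_RE = re.compile(r"^(del|dup)\(([0-9XY]+)([pq][0-9.]+)(?:-([pq][0-9.]+))?\)$")
_MB_RE = re.compile(r"^(del|dup)\(([0-9XY]+):([0-9.]+)-([0-9.]+)Mb\)$")


def parse_karyotype(text: str, chrom_lengths: Mapping[str, int],
                    band_table: Optional[BandTable] = None) -> List[CnvCall]:
    """Parse the simplified karyotype dialect back into calls.

    Accepts strings like ``45,XO``, ``47,XX,+21``, ``+21, −22`` or
    ``46,XX, del(16p12.1-p11.2)``; the modal-number token, when present,
    is not trusted (printed reports occasionally contradict it).
    """
    def canon(chrom: str) -> str:
        for cand in (chrom, f"chr{chrom}"):
            if cand in chrom_lengths:
                return cand
        raise ConfigurationError(f"unknown chromosome {chrom!r} in karyotype")

    calls: List[CnvCall] = []
    tokens = [t.strip().replace("−", "-") for t in text.split(",") if t.strip()]
    for tok in tokens:
        if tok.isdigit():
            continue
        if tok in ("XX", "XY"):
            continue
        if tok in ("XO", "X0"):
            chrom = canon("X")
            calls.append(CnvCall(chrom, 0, int(chrom_lengths[chrom]), "loss", 0.0))
            continue
        if tok.startswith(("+", "-")):
            chrom = canon(tok[1:])
            kind = "gain" if tok[0] == "+" else "loss"
            calls.append(CnvCall(chrom, 0, int(chrom_lengths[chrom]), kind, 0.0))
            continue
        m = _EVENT_RE.match(tok)
        if m:
            op, chrom, b1, b2 = m.groups()
            if band_table is None:
                raise ConfigurationError(f"band table needed to parse {tok!r}")
            lo, hi = band_table.band_span(chrom, b1, b2 or b1)
            calls.append(CnvCall(canon(chrom), lo, hi,
                                 "gain" if op == "dup" else "loss", 0.0))
            continue
        m = _MB_RE.match(tok)
        if m:
            op, chrom, lo, hi = m.groups()
            calls.append(CnvCall(canon(chrom), int(float(lo) * 1e6),
                                 int(float(hi) * 1e6),
                                 "gain" if op == "dup" else "loss", 0.0))
            continue
        raise ConfigurationError(f"cannot parse karyotype token {tok!r}")
    return calls


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp)
    if inter <= 0:
        return 0.0
    return min(inter / a.size_bp, inter / b.size_bp)


def concordance(detected: Union[str, Sequence[CnvCall]],
                confirmed: Union[str, KaryotypeSpec, Sequence[CnvCall]],
                chrom_lengths: Mapping[str, int],
                reciprocal_overlap: float = 0.5,
                whole_chrom_fraction: float = 0.8,
                band_table: Optional[BandTable] = None) -> ConcordanceResult:
    """Score detected calls against confirmed events.

    A pair matches when directions agree and reciprocal overlap reaches
    the threshold; a confirmed whole-chromosome event matches any
    same-direction call covering at least ``whole_chrom_fraction`` of
    that chromosome.  Matching is one-to-one and greedy by overlap.
    """
    if isinstance(detected, str):
        detected = parse_karyotype(detected, chrom_lengths, band_table)
    if isinstance(confirmed, str):
        confirmed = parse_karyotype(confirmed, chrom_lengths, band_table)
    elif isinstance(confirmed, KaryotypeSpec):
        confirmed = confirmed.expected_calls(chrom_lengths)
    detected = list(detected)
    confirmed = list(confirmed)

    def matches(d: CnvCall, c: CnvCall) -> bool:
        if d.kind != c.kind or d.chrom != c.chrom:
            return False
        if c.size_bp >= whole_chrom_fraction * chrom_lengths[c.chrom]:
            return d.size_bp >= whole_chrom_fraction * chrom_lengths[c.chrom]
        return _reciprocal_overlap(d, c) >= reciprocal_overlap

    pairs: List[Tuple[CnvCall, CnvCall]] = []
    unmatched_det = list(detected)
    for c in confirmed:
        cand = [(d, _reciprocal_overlap(d, c)) for d in unmatched_det if matches(d, c)]
        if cand:
            cand.sort(key=lambda dc: -dc[1])
            d = cand[0][0]
            unmatched_det.remove(d)
            pairs.append((d, c))
    tp = len(pairs)
    return ConcordanceResult(n_true_positive=tp,
                             n_false_positive=len(unmatched_det),
                             n_false_negative=len(confirmed) - tp,
                             matched_pairs=pairs)


def write_calls_bed(calls: Sequence[CnvCall], path) -> None:
    """BED with the call kind as name and mean log2 ratio as score."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start_bp}\t{c.end_bp}\t{c.kind}\t"
                     f"{c.mean_log2_ratio:.4f}\n")


def write_calls(calls: Sequence[CnvCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart_bp\tend_bp\tkind\tmean_log2_ratio\tsize_bp\tband\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start_bp}\t{c.end_bp}\t{c.kind}\t"
                     f"{c.mean_log2_ratio:.4f}\t{c.size_bp}\t{c.band_label}\n")
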