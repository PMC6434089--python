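"""Synthetic per-window counts emulating WGA amplification noise.

Generative model per window i:

    mu_i = D * (CN_i / 2) * g(gc_i) * b_i,     count_i ~ Poisson(mu_i)

where D is the mean read count per window, CN the karyotype copy
number, g a smooth multiplicative GC-response curve, and log2 b an
AR(1) Gaussian process along windows (restarted per chromosome) with
marginal SD sigma.  The bias process splits into a component shared
between repeats of the same kit and a repeat-private component, so the
between-repeat correlation is tunable; a dropout probability zeroes a
window's expectation outright (MDA-like locus loss).  Sequencing-
sampling noise (Poisson, depth-dependent) is thereby separated from
amplification bias (depth-independent), which is exactly the axis on
which WGA chemistries differ.

All samples and the control additionally share a deterministic
long-wavelength coverage track of the genome itself (a mappability/
accessibility stand-in, :func:`genomic_wave`): it divides out of
control-normalized ratios, so CNV calling never sees it, but it
dominates the correlation between depth-normalized repeat profiles,
which is how reproducibility is read out.  The control is otherwise a
pure-Poisson diploid reference with no amplification bias; each kit's
``bias_sd_log2`` is calibrated *through the full normalization path*
(sample + control), so the per-kit MAPD targets absorb control
sampling noise.

Kit parameter defaults are calibrated against the published per-kit
noise levels: MAPD in 100-kb windows (bulk 0.20, PicoPLEX 0.24, MALBAC
0.31, GenomePlex 0.42, MDA 2.48) and between-repeat Pearson
correlations (0.88, 0.85, 0.55, 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .calling import KaryotypeSpec
from .counts import WindowCounts
from .errors import CalibrationError, InsufficientDataError, InvalidParameterError
from .genomes import simulation_chrom_lengths, synthetic_band_table
from .grid import WindowGrid, aggregate_grid
from .normalize import normalize_counts
from .qc import mapd, profile_correlation

_LN2 = float(np.log(2.0))


@dataclass
class KitNoiseProfile:
    """Simulator parameterization standing in for one WGA chemistry."""

    kit: str
    bias_sd_log2: float
    autocorr: float = 0.5
    shared_fraction: float = 0.0
    gc_bias_coeffs: Tuple[float, ...] = (0.0, 0.0)
    dropout_rate: float = 0.0
    #: probability of a hyperamplification spike (a window further
    #: multiplied by 2**spike_log2); repeat-private, like dropout.
    spike_rate: float = 0.0
    spike_log2: float = 0.0
    target_mapd_100kb: float = 0.0
    target_repeat_correlation: float = 0.0

    def __post_init__(self):
        if self.bias_sd_log2 < 0 or not (0 <= self.autocorr < 1):
            raise InvalidParameterError("bias_sd_log2 >= 0 and 0 <= autocorr < 1 required")
        if not (0 <= self.shared_fraction <= 1) or not (0 <= self.dropout_rate <= 1):
            raise InvalidParameterError("shared_fraction and dropout_rate must be in [0,1]")
        if not (0 <= self.spike_rate <= 1):
            raise InvalidParameterError("spike_rate must be in [0,1]")


# bias_sd_log2 / shared_fraction values below were produced by
# calibrate_bias_sd / calibrate_shared_fraction on the default simulation
# genome (10% hg19, 20-kb windows, 30 reads/window) and frozen as the
# package's standard kit conditions.
KIT_PROFILES: Dict[str, KitNoiseProfile] = {
    "bulk": KitNoiseProfile("bulk", bias_sd_log2=0.1875, autocorr=0.5,
                            shared_fraction=1.0, gc_bias_coeffs=(0.0, 0.0),
                            target_mapd_100kb=0.20),
    "PicoPLEX": KitNoiseProfile("PicoPLEX", bias_sd_log2=0.3125, autocorr=0.5,
                                shared_fraction=0.9688, gc_bias_coeffs=(1.0, 0.0),
                                target_mapd_100kb=0.24,
                                target_repeat_correlation=0.85),
    "MALBAC": KitNoiseProfile("MALBAC", bias_sd_log2=0.4688, autocorr=0.5,
                              shared_fraction=0.9375, gc_bias_coeffs=(1.5, 0.0),
                              target_mapd_100kb=0.31,
                              target_repeat_correlation=0.88),
    "GenomePlex": KitNoiseProfile("GenomePlex", bias_sd_log2=0.6504, autocorr=0.5,
                                  shared_fraction=0.5000, gc_bias_coeffs=(0.3, 0.0),
                                  target_mapd_100kb=0.42,
                                  target_repeat_correlation=0.55),
    "MDA": KitNoiseProfile("MDA", bias_sd_log2=3.9155, autocorr=0.2,
                           shared_fraction=0.0, gc_bias_coeffs=(0.3, 0.0),
                           dropout_rate=0.10, spike_rate=0.10, spike_log2=4.0,
                           target_mapd_100kb=2.48,
                           target_repeat_correlation=0.01),
}


@dataclass
class SimulationConfig:
    karyotype: KaryotypeSpec
    kit_profile: KitNoiseProfile
    grid: WindowGrid
    mean_reads_per_window: float = 30.0
    seed: int = 0
    n_repeats: int = 1
    control_depth_factor: float = 1.0
    expectation_mode: bool = False
    #: SD (log2) of the genome-intrinsic long-wavelength coverage track
    #: (mappability/accessibility-like).  It is a fixed property of the
    #: genome, shared by every sample *and* the control, so it cancels
    #: out of control-normalized ratios but dominates the between-repeat
    #: correlation of depth-normalized counts.
    genomic_bias_sd_log2: float = 0.25
    genomic_autocorr: float = 0.997

    def __post_init__(self):
        if self.mean_reads_per_window <= 0:
            raise InvalidParameterError("mean_reads_per_window must be > 0")


@dataclass
class SimulationResult:
    samples: List[WindowCounts]
    control: WindowCounts

    @property
    def sample(self) -> WindowCounts:
        return self.samples[0]


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with unit marginal variance."""
    if n == 0:
        return np.empty(0)
    eps = rng.normal(0.0, np.sqrt(1.0 - phi ** 2), size=n)
    eps[0] = rng.normal()  # stationary start
    if phi == 0.0:
        return eps
    return lfilter([1.0], [1.0, -phi], eps)


def _ar1_per_chrom(grid: WindowGrid, phi: float, rng: np.random.Generator) -> np.ndarray:
    z = np.empty(grid.n_windows)
    for _, sl in grid.chrom_slices.items():
        z[sl] = _ar1(sl.stop - sl.start, phi, rng)
    return z


def copy_number_track(karyotype: KaryotypeSpec, grid: WindowGrid) -> np.ndarray:
    """Per-window copy number implied by a karyotype (events override sex baseline)."""
    cn = np.empty(grid.n_windows)
    for chrom, sl in grid.chrom_slices.items():
        cn[sl] = karyotype.copy_number(chrom)
    for chrom, start, end, value in karyotype.events:
        if chrom not in grid.chrom_slices:
            raise InvalidParameterError(f"karyotype event on unknown chromosome {chrom!r}")
        sl = grid.chrom_slices[chrom]
        if end > int(grid.end[sl][-1]) or start < 0:
            raise InvalidParameterError(f"karyotype event out of bounds on {chrom}")
        hit = (grid.start >= start) & (grid.start < end)
        hit[:sl.start] = False
        hit[sl.stop:] = False
        cn[hit] = value
    return cn


def genomic_wave(grid: WindowGrid, sd_log2: float = 0.25,
                 autocorr: float = 0.997) -> np.ndarray:
    """Deterministic long-wavelength coverage track of the synthetic genome.

    Mean-one multiplicative factor seeded by the grid identity, so every
    sample and control simulated on the same grid shares it exactly
    (like mappability: it divides out of sample/control ratios).
    """
    if sd_log2 <= 0:
        return np.ones(grid.n_windows)
    seed = int(grid.checksum(), 16) % (2 ** 31)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3A7E]))
    z = _ar1_per_chrom(grid, autocorr, rng)
    w = np.exp2(sd_log2 * z)
    return w / w.mean()


def _gc_response(grid: WindowGrid, coeffs: Sequence[float]) -> np.ndarray:
    d = grid.gc_fraction - 0.41
    log2g = np.zeros(grid.n_windows)
    for p, c in enumerate(coeffs, start=1):
        log2g += c * d ** p
    g = np.exp2(log2g)
    return g / g.mean()


def simulate_counts(cfg: SimulationConfig) -> SimulationResult:
    """Simulate sample (and repeat) counts plus a matched diploid control.

    Fully reproducible from ``cfg.seed``.  In ``expectation_mode`` the
    Poisson draw and dropout are skipped and expected counts (floats)
    are returned — useful for exactness checks.
    """
    grid = cfg.grid
    prof = cfg.kit_profile
    ss = np.random.SeedSequence([int(cfg.seed), 0xC0DE])
    ctrl_ss, shared_ss, *rep_ss = ss.spawn(2 + 2 * cfg.n_repeats)

    cn = copy_number_track(cfg.karyotype, grid)
    g = _gc_response(grid, prof.gc_bias_coeffs)
    wave = genomic_wave(grid, cfg.genomic_bias_sd_log2, cfg.genomic_autocorr)
    base_mu = cfg.mean_reads_per_window * (cn / 2.0) * g * wave

    sigma = prof.bias_sd_log2
    shared = _ar1_per_chrom(grid, prof.autocorr, np.random.default_rng(shared_ss))
    sq_sh = np.sqrt(prof.shared_fraction)
    sq_pr = np.sqrt(1.0 - prof.shared_fraction)
    samples: List[WindowCounts] = []
    for r in range(cfg.n_repeats):
        priv_rng = np.random.default_rng(rep_ss[2 * r])
        drop_rng = np.random.default_rng(rep_ss[2 * r + 1])
        private = _ar1_per_chrom(grid, prof.autocorr, priv_rng)
        log2_b = sigma * (sq_sh * shared + sq_pr * private)
        # mean-one bias: E[2^y] for y ~ N(0, s^2) is exp(s^2 ln2^2 / 2)
        b = np.exp2(log2_b - sigma ** 2 * _LN2 / 2.0)
        mu = base_mu * b
        if cfg.expectation_mode:
            counts = mu.copy()
        else:
            if prof.spike_rate > 0:
                spiked = drop_rng.random(grid.n_windows) < prof.spike_rate
                mu = mu * np.where(spiked, 2.0 ** prof.spike_log2, 1.0)
                mu = mu / (1.0 - prof.spike_rate
                           + prof.spike_rate * 2.0 ** prof.spike_log2)
            if prof.dropout_rate > 0:
                mu = mu * (drop_rng.random(grid.n_windows) >= prof.dropout_rate)
            counts = priv_rng.poisson(mu).astype(np.int64)
        samples.append(WindowCounts(
            sample_id=f"{cfg.karyotype.name or 'sim'}:{prof.kit}:rep{r}",
            counts=counts, grid_ref=grid.checksum(), kit=prof.kit,
            sample_type="single_cell"))

    ctrl_rng = np.random.default_rng(ctrl_ss)
    cn_ctrl = copy_number_track(KaryotypeSpec(sex="XX"), grid)
    mu_ctrl = (cfg.mean_reads_per_window * cfg.control_depth_factor
               * (cn_ctrl / 2.0) * wave)
    if cfg.expectation_mode:
        ctrl_counts = mu_ctrl.copy()
    else:
        ctrl_counts = ctrl_rng.poisson(mu_ctrl).astype(np.int64)
    control = WindowCounts(sample_id="control", counts=ctrl_counts,
                           grid_ref=grid.checksum(), kit="none",
                           sample_type="bulk")
    return SimulationResult(samples=samples, control=control)


def _simulated_mapd(profile: KitNoiseProfile, depth: float, grid: WindowGrid,
                    agg_grid: WindowGrid, factor: int, seeds: Sequence[int]) -> float:
    from .counts import aggregate_counts

    vals = []
    for s in seeds:
        res = simulate_counts(SimulationConfig(
            karyotype=KaryotypeSpec(sex="XX"), kit_profile=profile, grid=grid,
            mean_reads_per_window=depth, seed=int(s)))
        sa = aggregate_counts(res.sample, grid, factor, agg_grid=agg_grid)
        ca = aggregate_counts(res.control, grid, factor, agg_grid=agg_grid)
        prof = normalize_counts(sa, ca, agg_grid)
        vals.append(mapd(prof))
    return float(np.mean(vals))


def calibrate_bias_sd(target_mapd: float, depth: float, grid: WindowGrid,
                      window_size: int = 100_000, seed: int = 0,
                      kit_template: Optional[KitNoiseProfile] = None,
                      tol: float = 0.01, n_seeds: int = 5,
                      max_sigma: float = 16.0) -> float:
    """Find sigma so simulated MAPD at ``window_size`` matches the target.

    Monte-Carlo monotone bisection with common random numbers (the same
    seeds at every sigma, averaged over ``n_seeds``).  Raises
    :class:`CalibrationError` when the target sits below the Poisson
    sampling floor at the given depth.
    """
    if kit_template is None:
        kit_template = KitNoiseProfile("custom", bias_sd_log2=0.0)
    factor = max(1, int(window_size) // grid.window_size)
    agg_grid = aggregate_grid(grid, factor)
    seeds = np.random.SeedSequence([int(seed), 0xCA1]).generate_state(n_seeds) % (2 ** 31)

    def f(sigma: float) -> float:
        try:
            return _simulated_mapd(replace(kit_template, bias_sd_log2=sigma),
                                   depth, grid, agg_grid, factor, seeds)
        except InsufficientDataError:
            # bias so extreme that (nearly) every window is empty
            return float("nan")

    floor = f(0.0)
    if target_mapd < floor - tol:
        raise CalibrationError(
            f"target MAPD {target_mapd} is below the Poisson floor "
            f"{floor:.3f} at depth {depth} reads/window")
    if abs(floor - target_mapd) <= tol:
        return 0.0
    # Expand the bracket while MAPD still grows with sigma; beyond some
    # sigma the zero-masking survivorship makes MAPD fall again (or the
    # simulation degenerates), which bounds what is reachable.
    lo, f_lo = 0.0, floor
    hi = 0.25
    f_hi = f(hi)
    while f_hi < target_mapd:
        if np.isnan(f_hi) or f_hi < f_lo or hi >= max_sigma:
            # The peak may sit inside (lo, hi): refine before giving up.
            probes = lo + (hi - lo) * np.linspace(0.2, 0.8, 4)
            vals = np.array([f(p) for p in probes])
            if np.all(np.isnan(vals)) or np.nanmax(vals) < target_mapd:
                best = np.nanmax([f_lo, *vals[~np.isnan(vals)]] or [f_lo])
                raise CalibrationError(
                    f"target MAPD {target_mapd} unreachable: maximum "
                    f"simulated MAPD ~{best:.3f} before degeneracy")
            k = int(np.nanargmax(vals))
            hi, f_hi = float(probes[k]), float(vals[k])
            break
        lo, f_lo = hi, f_hi
        hi *= 1.5
        f_hi = f(hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - target_mapd) <= tol:
            return float(mid)
        if f_mid < target_mapd:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
        if hi - lo < 1e-4:
            break
    return float(0.5 * (lo + hi))


def repeat_correlation(repeats: Sequence[WindowCounts], grid: WindowGrid,
                       window_size: int = 100_000, span: float = 0.3) -> float:
    """Between-repeat Pearson r of GC-corrected, depth-normalized counts.

    This is the reproducibility readout: each repeat is GC-corrected and
    scaled to a uniform (flat diploid) reference rather than divided by
    the matched control, so reproducible amplification structure -- the
    kit's shared bias and the genome's intrinsic coverage track -- stays
    in view instead of cancelling.
    """
    from .counts import aggregate_counts
    from .normalize import gc_loess_correct, normalize_to_control

    factor = max(1, int(window_size) // grid.window_size)
    agg_grid = aggregate_grid(grid, factor)
    flat = np.ones(agg_grid.n_windows)
    profs = []
    for wc in repeats:
        agg = aggregate_counts(wc, grid, factor, agg_grid=agg_grid)
        corrected = gc_loess_correct(agg, agg_grid, span=span)
        profs.append(normalize_to_control(corrected, flat, agg_grid,
                                          sample_id=wc.sample_id))
    return profile_correlation(profs[0], profs[1])


def calibrate_shared_fraction(profile: KitNoiseProfile, target_r: float,
                              depth: float, grid: WindowGrid,
                              window_size: int = 100_000, seed: int = 0,
                              tol: float = 0.01, n_seeds: int = 3) -> float:
    """Find the repeat-shared bias fraction hitting a target correlation.

    Correlation is measured by :func:`repeat_correlation` (depth-
    normalized counts at ``window_size``, Fig-style reproducibility).
    """
    seeds = np.random.SeedSequence([int(seed), 0xC02]).generate_state(n_seeds) % (2 ** 31)

    def f(rho: float) -> float:
        vals = []
        for s in seeds:
            res = simulate_counts(SimulationConfig(
                karyotype=KaryotypeSpec(sex="XX"),
                kit_profile=replace(profile, shared_fraction=rho), grid=grid,
                mean_reads_per_window=depth, seed=int(s), n_repeats=2))
            vals.append(repeat_correlation(res.samples, grid, window_size))
        return float(np.mean(vals))

    lo, hi = 0.0, 1.0
    f_lo, f_hi = f(lo), f(hi)
    if target_r <= f_lo:
        return 0.0
    if target_r >= f_hi:
        return 1.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - target_r) <= tol:
            return float(mid)
        if f_mid < target_r:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    return float(0.5 * (lo + hi))


def multi_cell_profile(profile: KitNoiseProfile, n_cells: int = 4) -> KitNoiseProfile:
    """Kit profile for a multi-cell (3-5 cell) input.

    Amplification starts from ``n_cells`` independent templates, so the
    locus-level bias averages out roughly as 1/sqrt(n_cells); dropout
    requires every template to fail and shrinks much faster.  This is
    the input type on which confirmed-karyotype CNV detection is
    benchmarked (multi-cell samples are visibly less noisy than single
    cells, which is why they were used for that comparison).
    """
    return replace(profile,
                   bias_sd_log2=profile.bias_sd_log2 / np.sqrt(n_cells),
                   dropout_rate=profile.dropout_rate ** n_cells,
                   spike_rate=profile.spike_rate / n_cells)


# ---------------------------------------------------------------------------
# Cell-line karyotype fixtures

def cell_line_fixtures(scale: float = 0.1) -> List[Tuple[str, KaryotypeSpec]]:
    """The six validation cell-line karyotypes plus a normal bulk spec.

    Coordinates come from the bundled synthetic band table at the given
    genome scale.
    """
    lengths = simulation_chrom_lengths(scale)
    bands = synthetic_band_table(scale)
    del16 = bands.band_span("chr16", "p12.1", "p11.2")
    del4 = bands.band_span("chr4", "p16.3", "p16.2")
    dup12 = bands.band_span("chr12", "p13.33", "p12.1")
    out = [
        ("GM00857", KaryotypeSpec(sex="XO", name="GM00857")),
        ("GM05875", KaryotypeSpec(sex="XX", name="GM05875",
                                  events=[("chr16", del16[0], del16[1], 1)])),
        ("GM04592", KaryotypeSpec(sex="XX", name="GM04592",
                                  events=[("chr21", 0, lengths["chr21"], 3)])),
        ("GM01359", KaryotypeSpec(sex="XY", name="GM01359",
                                  events=[("chr18", 0, lengths["chr18"], 3)])),
        ("GM03330", KaryotypeSpec(sex="XY", name="GM03330",
                                  events=[("chr13", 0, lengths["chr13"], 3)])),
        ("GM01183", KaryotypeSpec(sex="XY", name="GM01183",
                                  events=[("chr4", del4[0], del4[1], 1),
                                          ("chr12", dup12[0], dup12[1], 3)])),
        ("Bulk", KaryotypeSpec(sex="XX", name="Bulk")),
    ]
    return out


def kit_benchmark_calls() -> Dict[str, Dict[str, Optional[str]]]:
    """Benchmark per-kit detection outcomes for the validation cell lines.

    Karyotype strings as reported for each amplification chemistry on
    the six confirmed lines (None where detection produced no usable
    result); used to exercise concordance scoring.
    """
    malbac = {
        "GM00857": "45,XO",
        "GM05875": "46,XX, del(16p12.1-p11.2)",
        "GM04592": "47,XX,+21",
        "GM01359": "47,XY,+18",
        "GM03330": "47,XY,+13",
        "GM01183": "46,XY, del(4p16.3-p16.2), dup(12p13.33-p12.1)",
        "Bulk": "46,XX",
    }
    genomeplex = dict(malbac)
    genomeplex["GM04592"] = "46,XX,+21, del(1p31.1-p22.3)"
    genomeplex["GM01359"] = "47,XY,+18, dup(6q15-q16.1)"
    mda: Dict[str, Optional[str]] = {k: None for k in malbac}
    mda["GM00857"] = "+21, -22"
    mda["GM04592"] = "-22"
    mda["Bulk"] = "46,XX"
    return {"MALBAC": malbac, "PicoPLEX": dict(malbac),
            "GenomePlex": genomeplex, "MDA": mda}


# ---------------------------------------------------------------------------
# Tiny alignment fixtures for the read-counting module

def make_fixture_reference(chrom_lengths: Dict[str, int], path, seed: int = 0,
                           n_blocks: Optional[Dict[str, Tuple[int, int]]] = None,
                           ) -> None:
    """Write a small random reference FASTA; optional N block per chromosome."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            seq = rng.choice(list("ACGT"), size=length)
            if n_blocks and chrom in n_blocks:
                lo, hi = n_blocks[chrom]
                seq[lo:hi] = "N"
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, length, 80):
                fh.write(s[i:i + 80] + "\n")


def make_fixture_bam(placements: Sequence[Tuple[str, int, int, int, str, bool]],
                     chrom_lengths: Dict[str, int], path) -> None:
    """Write a coordinate-sorted BAM from explicit read placements.

    Each placement is (chrom, pos, mapq, length, strand, duplicate_flag);
    counts after filtering are computable by hand.
    """
    import pysam

    refs = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in refs],
    }
    order = sorted(range(len(placements)),
                   key=lambda k: (refs.index(placements[k][0]), placements[k][1]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for serial, k in enumerate(order):
            chrom, pos, mapq, length, strand, dup = placements[k]
            a = pysam.AlignedSegment()
            a.query_name = f"r{k:04d}"
            a.query_sequence = "A" * length
            a.reference_id = refs.index(chrom)
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = f"{length}M"
            flag = 0
            if strand == "-":
                flag |= 16
            if dup:
                flag |= 1024
            a.flag = flag
            bam.write(a)
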