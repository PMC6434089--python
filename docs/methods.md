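# Methods

## Problem and pipeline

`sccnv` detects megabase-scale copy-number variants (CNVs) from
low-coverage (~0.25×) single-end whole-genome sequencing of
whole-genome-amplified (WGA) single- or multi-cell samples. The signal
is read *depth*: each chromosome is tiled with fixed 20-kbp windows,
filtered reads are counted per window, counts are corrected and
normalized, and a segmentation of the per-window log2 copy-number
ratio yields gain/loss calls reported in karyotype style
(`47,XX,+21`, `46,XX, del(16p12.1-p11.2)`, …).

Stages, in order:

1. **Windows** (`grid`). Fixed-size tiling, 0-based half-open
   coordinates. Trailing partial windows are kept but flagged unusable
   so that window indices are derivable from chromosome lengths alone.
   Windows containing any `N` in the reference are unusable by default
   (`n_max = 0`, configurable); GC fraction is computed over the full
   window length (simplest reproducible definition; N-containing
   windows are excluded anyway). Grids aggregate by integer factors
   (runs of *k* windows, never crossing a chromosome; length-weighted
   GC; usable only if all members usable) for multi-scale quality
   metrics.

2. **Counting** (`counts`). A read is kept iff it is a primary mapped
   alignment with MAPQ ≥ 10 spanning ≥ 35 reference bases, and is not
   a duplicate. Duplicates (single-end) are reads sharing (chromosome,
   leftmost position, strand); the highest-MAPQ one survives, ties
   broken by read name. Filtering precedes duplicate detection; order
   is fixed and documented because it decides which duplicate
   survives. Each kept read increments the window containing its
   leftmost aligned base (deterministic for length-variable reads).
   Unusable windows still accumulate counts; exclusion happens at
   normalization.

3. **Normalization** (`normalize`). GC bias is removed per sample by
   LOESS of count on window GC over usable, non-zero autosomal windows
   (span 0.3 by default; sex chromosomes excluded from the fit to
   avoid copy-number confounding). The correction is multiplicative —
   `count · median(fit)/fit(gc)` — preserving non-negativity; fitted
   values are clamped below at 1% of their median, and GC values
   outside the fitted range use the nearest fitted value. Sample and
   control are corrected independently, then the ratio
   `r_i = (s_i/S)/(k_i/K)` is formed over unmasked windows (masked:
   unusable, zero in sample, or zero in control) and recentred on the
   median unmasked window. Median recentring matters: total-count
   scaling is itself perturbed by large CNVs (a trisomy inflates `S`),
   whereas the median window of a mostly-diploid genome sits at ratio
   1; after recentring a clean trisomy shows `x = log2 r` of exactly
   log2(1.5) on the trisomic chromosome and 0 elsewhere. `x_i` is
   NaN-free on unmasked windows by construction.

4. **Quality gate** (`qc`). MAPD — the median of |x_{i+1} − x_i| over
   adjacent unmasked windows, never across a chromosome boundary — is
   the noise statistic. For i.i.d. Gaussian x with SD σ, MAPD =
   σ·√2·Φ⁻¹(3/4) ≈ 0.9539 σ, which anchors both the simulator
   calibration and the segmentation pruning scale. The gate evaluates
   MAPD in 100-kb windows (the scale at which the 0.4 cutoff is
   defined; pass ⇔ MAPD ≤ 0.4) and coverage uniformity (fraction of
   usable windows with count ≥ 20% of the mean; pass ⇔ ≥ 0.90).
   Adjacency skips masked windows by default (the next unmasked window
   counts as adjacent); dropping pairs that span a mask is available
   as an option. A failed gate aborts the pipeline with a dedicated
   exit status unless forced.

5. **Segmentation** (`segment`). Circular binary segmentation: per
   chromosome, the arc (i, j) maximizing the pooled-variance
   two-sample |t| between arc and complement is found exhaustively;
   the split is kept if significant by permutation, and the recursion
   continues on the pieces. Numerical notes:
   - |t| is strictly increasing in v = u²·(1/k + 1/(n−k)) with u the
     centered arc sum (t² = (n−2)·v/(SS_tot − v)), so the O(n²) scan
     maximizes v with two flops per arc; arcs ending at n are
     complements of `(0, i)` (the same split) and are not enumerated
     twice. Ties break to the smallest (i, j).
   - Significance uses the Besag–Clifford sequential Monte-Carlo
     p-value: shuffle within the piece under test, stop at the 10th
     exceedance or after min(n_permutations, 10/α) shuffles, estimate
     p as the exceedance fraction at the stop (the total SS is
     permutation-invariant, so comparing v equals comparing t).
     Defaults: α = 0.01, n_permutations = 10 000, minimum segment 3
     windows. Each (chromosome, piece) derives its own seed stream
     from the configuration seed, making output deterministic and
     α-monotone.
   - After recursion, adjacent segments merge while their mean
     difference is below `prune_sd` (default 1.5) standard errors of
     that difference, `noise_sd·√(1/n₁+1/n₂)`, with the per-window
     noise SD estimated robustly as MAPD/0.9539. The standard error —
     not the per-window SD — is the right scale: a per-window-SD
     threshold would be ≈ 0.58 at realistic 20-kb MAPD (~0.37) and
     would swallow every half-copy (log2 1.5 ≈ 0.585) event regardless
     of its length.

6. **Calling and reporting** (`calling`). A segment calls as a gain if
   its mean exceeds +0.37 or a loss below −0.51 (strict inequalities;
   the asymmetric cutoffs are mosaic-tolerant, ratio ≈ 1.29 / 0.70).
   Same-direction passing segments merge before the size filter when
   contiguous and also across a neutral gap of up to a quarter of the
   minimum event size (segmentation can cut one biological event with
   a short noise dip; opposite-direction segments never bridge);
   merged events must exceed 4 Mbp. Chromosome Y is excluded by
   default. Reporting: a chromosome whose same-direction calls jointly
   cover ≥ 80% of it renders as one whole-chromosome event (the 80%
   tolerance accommodates acrocentric arms and masked telomeric
   windows; judging combined rather than single-call coverage keeps an
   aneuploidy split by a dip from being reported as two duplications);
   whole-X loss against a female control renders as `XO` unless the
   sample is known male, in which case the dosage difference is
   expected and dropped. Partial events carry cytogenetic band labels
   when a band table is available, with lookup positions nudged inward
   by max(two windows, 5% of the event span) — breakpoint estimates
   are window-quantized and noisy, and a boundary off by a few windows
   must not flip the reported band — else Mb coordinates.
   The karyotype dialect is deliberately simplified (modal count, sex
   token, `+N/−N/del(...)/dup(...)`), not full ISCN. Concordance
   scores detected against confirmed events one-to-one: same
   direction, reciprocal overlap ≥ 0.5; whole-chromosome events match
   any same-direction call covering ≥ 80% of the chromosome.

## Synthetic data

No sequencing data are distributed with the underlying study, so the
simulator is a first-class module; it emulates the *published summary
statistics* of the four WGA chemistries, not their molecular detail.
Per window,

    μ_i = D · (CN_i/2) · g(gc_i) · w_i · b_i,    count_i ~ Poisson(μ_i)

- `D` — mean reads per 20-kb window; default 30, matching ~0.25×
  coverage with ~170-bp reads.
- `CN_i` — from a karyotype spec (sex baseline plus explicit events).
- `g(gc)` — smooth kit GC response, `2^{c₁(gc−0.41)+c₂(gc−0.41)²}`,
  mean-normalized; coefficients reproduce the qualitative rightward
  shift of read GC content for MALBAC/PicoPLEX only (no quantitative
  GC data exist to calibrate against).
- `w_i` — a deterministic genome-intrinsic long-wavelength coverage
  track (log2-SD 0.25, AR(1) 0.997 per window; a
  mappability/accessibility stand-in) shared by **every** sample and
  the control on the same grid. It divides out of control-normalized
  ratios — calling and MAPD never see it — but dominates the
  correlation between depth-normalized repeat profiles, which is how
  reproducibility is measured (repeat vs repeat, not vs control).
  Modelling the repeat correlation as free per-sample Mb-scale waves
  instead is wrong: segmentation isolates wave peaks and emits false
  calls, which the benchmarked kits demonstrably do not produce.
- `b_i` — amplification bias: log2 b is a mean-one AR(1) Gaussian
  process (restarted per chromosome, autocorrelation 0.5 by default so
  that window aggregation shrinks MAPD sub-√n, reproducing the concave
  MAPD-versus-window-size trend) with marginal SD σ split into a
  repeat-shared and repeat-private part. MDA additionally has
  hyperamplification spikes (a window's μ × 2⁴ with probability 0.1)
  and locus dropout (μ ≈ 0 with probability 0.1), both repeat-private.
- The control is a pure-Poisson diploid female reference (no
  amplification bias) sharing `w`. Giving the control its own
  amplified-bulk bias would make the bulk calibration circular
  (bulk-vs-control MAPD would be √2 × target); instead each kit's σ is
  calibrated **through the full normalization path**, so the published
  MAPD targets absorb control sampling noise.

**Calibration.** `calibrate_bias_sd` bisects σ against Monte-Carlo
MAPD (common random numbers, ≥5 seeds, tolerance 0.01) at the stated
window size, erroring below the Poisson floor and above the
reachable maximum; `calibrate_shared_fraction` does the same for the
repeat-shared fraction against the depth-normalized repeat
correlation. Defaults were produced by these routines at the standard
conditions (10% genome, 20-kb windows, 30 reads/window) and frozen:

| kit        | σ (log2) | shared | MAPD@100kb | repeat r |
|------------|---------:|-------:|-----------:|---------:|
| bulk       | 0.1875   | 1.0    | 0.20       | —        |
| PicoPLEX   | 0.3125   | 0.9688 | 0.24       | 0.85     |
| MALBAC     | 0.4688   | 0.9375 | 0.31       | 0.88     |
| GenomePlex | 0.6504   | 0.5000 | 0.42       | 0.55     |
| MDA        | 3.9155   | 0.0    | 2.48*      | ~0       |

*The MDA value has a model ceiling: with lognormal bias at 30
reads/window, zero-count masking truncates the observable log-ratio
range and simulated MAPD saturates near 2.45; the 2.48 target
calibrates at ≥ ~60 reads/window (`calibrate_bias_sd` reports the
ceiling otherwise). MDA grossly fails both QC rules in either case.

`multi_cell_profile` models 3–5-cell inputs by averaging bias over ~4
templates (σ/√4, dropout⁴, spikes/4) — the input type on which
confirmed-karyotype detection is benchmarked.

**What the simulator does not model:** allele-level artifacts (ADO,
chimeras, SNVs), sequencing error, fragment-size effects, real
mappability maps, and real cytogenetic band positions (the bundled
band table is synthetic-approximate; only internal consistency between
fixtures, rendering and parsing is claimed). Passing tests therefore
demonstrate correct *pipeline mechanics and statistics* under a
realistic noise phenomenology, not performance on real libraries.

## Problem sizes and test design

The default test genome scales hg19 chromosome lengths to 10% (same
20-kb windows, ~15 200 windows, chrY omitted — the control is female
and reporting excludes Y), so a full pipeline run takes ~2 s and the
entire suite runs in minutes; full-length chromosomes are available
through the same API. The 4-Mbp size filter is co-scaled (400 kb) in
scaled-genome tests so event-level logic is exercised. This
desk-scaling is not neutral for false positives: 4 Mbp of evidence is
200 windows at full scale but only 20 scaled, so noise excursions
survive the scaled filter far more often. The karyotype-recovery test
therefore runs at the benchmark's own conditions — multi-cell
amplification against a pooled (4× depth) control — where ≥19/20
seeded runs per cell line recover the exact karyotype string; tests
and the acceptance script use 2000 CBS permutations as their stated
problem size (the sequential rule makes larger defaults cost the
same).

Degenerate inputs are defined behaviour: degenerate GC spread makes GC
correction the identity (with a warning); an all-zero control or too
few usable windows raise typed errors; chromosomes shorter than twice
the minimum segment width return a single segment; boundary threshold
values never call (strict inequalities).
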