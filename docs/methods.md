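# Methods

## The quantification model

A dilution-series protein array quantifies each sample not from one spot
but from a response curve over serial dilutions. `rppaquant` assumes the
same antigen–antibody binding kinetics at every spot of an array, so all
spots share one sigmoid response (the *SuperCurve*) and samples differ
only by a horizontal offset on the log-concentration axis:

    Y_i = a + (b − a) / (1 + exp(c · (d − v_i))),    v_i = ln x_i + δ_{j(i)}

with `x_i` the spot's dilution factor (step k of a 1:2 series has
x = 2^−k), `Y_i` its background-corrected net volume, and `δ_j` the
offset of series j. `b > a` and `c > 0` are enforced through the
transforms `b = a + e^β`, `c = e^γ`, so fitted curves are always
increasing in concentration. The offsets are identified by
`mean(δ) = 0`.

**Readout.** The fitted curve of series j crosses its half-maximum
`(a+b)/2` at `ln x = d − δ_j`; the sample readout is the relative
concentration `e^{δ_j}`, rescaled so the array-median readout is 1. This
is the only reading of a "half-maximum readout" that ranks samples (the
response *at* the crossing is `(a+b)/2` for every series) and it is the
quantity whose ratios give fold changes directly.

**Optimization.** Alternating minimization: (i) bounded trust-region
least squares on `(a, β, γ, d)` with δ fixed; (ii) independent bounded
1-D refinements of each `δ_j` (accepted only when they lower the loss);
δ re-centered to mean 0 each outer iteration with `d` shifted in step,
which leaves every prediction unchanged. Convergence when the relative
loss change falls below 1e-8, at most 200 outer iterations; the loss is
non-increasing across outer iterations by construction.
Initialization: `a` = 5th and `b` = 95th response percentile, `c = 1`,
`d` = median ln x, `δ = 0`.

**Weighting.** Spot noise on these arrays is dominated by multiplicative
printing/binding variation (approximately constant CV), so the default
objective weights each squared residual by `1/max(y, 0.001·y_max)²` —
i.e. it minimizes relative residuals. Plain unweighted least squares
(`FitConfig(weighting="constant")`) is available but, with constant-CV
noise, lets the brightest spots dominate: the lower asymptote then drifts
by ~±10⁵ counts between replicates and readout-ratio scatter roughly
doubles.

**Identifiability bounds.** When every spot sits on the lower shoulder of
the sigmoid (common for antibodies far from saturation), `b` and `c` lie
on an exponential-regime ridge: the data constrain only `c` and
`(b−a)e^{−cd}`. The shared-parameter step therefore bounds the span
`b − a` to at most 50× the observed response range and `c` to
[0.05, 20] per log-unit. On the ridge the per-series offsets — the
quantity of interest — remain identified; arrays that include a bright
control series (as printed control lysates provide in practice) pin the
upper bend and remove the ridge altogether.

**Outliers.** After convergence, residuals on the weighting scale are
compared to 3 × (1.4826·MAD); flagged observations get weight 0 in a
single warm-started refit, and flags are frozen (no re-flagging loop), so
one dusty or smeared spot cannot drag the shared curve.

## Image processing

**Gridding.** Row/column projection profiles of the median-subtracted
image are correlated (FFT, sub-pixel parabolic peak) against a Gaussian
comb at the layout's nominal centers, over 9 pitch scales within ±20%;
shifts are limited to ±1 pitch to avoid locking onto a lattice alias. A
deterministic 2-D descent (steps 1 → 0.5 → 0.25 px) then maximizes the
mean intensity sampled in disks at the candidate centers. If the best
profile correlation is below 0.25 the grid is declared not found (e.g.
pure noise) rather than guessed.

**Segmentation.** Each spot is segmented in its own window (half-width =
0.5 pitch); pixels nearer a neighboring center are excluded, so a smeared
neighbor cannot be captured. Foreground = local background + 3·robust SD,
both estimated from the dimmest 60% of window pixels (the spot can cover
~40% of a half-pitch window, which would contaminate a plain median). The
qualifying connected component (≥ 9 px) nearest the nominal center wins;
ties break deterministically (larger area, then smaller centroid row,
then column). The component is extended by hysteresis down to background
+ 1.5·robust SD — a strong threshold necessarily cuts the dim rim of a
spot, and connected weak-threshold extension recovers it without
admitting detached noise. Holes are filled. A component touching the
window edge with no neighbor on that side triggers one 1.5× window
expansion, so an isolated spot shifted ~30% of the pitch is still
captured whole. No component → flagged `missing`, with a nominal-radius
disk as bookkeeping mask. Spots with > 5% saturated pixels are flagged
`saturated`.

**Background.** Per spot: median of an annulus from (equivalent radius
+ 2 px) to +6 px further, excluding every spot mask; the annulus grows in
2 px steps (to +14 px) if fewer than 20 eligible pixels remain, else the
estimate is flagged low-confidence. Net volume = raw − level·area,
floored at 0 with a `negative_net` flag. Adding a constant to the whole
image provably changes no net volume (mask, median and subtraction all
shift together).

**Dust.** Within a spot's mask, pixels above median + 5·MAD of the mask
pixels, in connected components of ≥ 3 px (a 1–2 px excursion at this
threshold is ordinary noise) and ≤ 25% of the spot area, are dust: they
are in-painted with the median of the clean mask pixels and the volume
recomputed (`dust_corrected`). If dusty pixels exceed 25% of the area the
spot is excluded instead. Detection statistics on simulated specks that
inflate spot volume ≥ 20%: recall ≥ 0.9, false-positive rate ≤ 0.05
(see `tests/test_acceptance.py`).

## The synthetic-array generator

The generator emulates what the scanner sees, with full ground truth:

| parameter | default | meaning |
|---|---|---|
| pitch | 350 µm | center-to-center spot spacing |
| pixel size | 10 µm/px | scanner resolution (pitch = 35 px) |
| spot radius | 35% of pitch | flat-top disk, erf rim (10–90% width 15% of radius); optional donut dip |
| 4PL defaults | a=500, b=1.5e7, c=0.9, d=0.5 | volumes span the curve's lower shoulder; peak pixels stay far above read noise and below the 65535 ceiling |
| multiplicative CV | 10% | log-normal per-spot printing/binding variation (mean 1) |
| read noise SD | 8 counts | per-pixel Gaussian |
| background | 150 + 100·gradient | constant + linear plane across the frame |
| spot jitter SD | 5 µm | Gaussian per-spot displacement, truncated at 3 SD |
| global shift | (0, 0) µm | whole-grid translation |

Spot volumes follow the 4PL at the spot's dilution × series
concentration; the rendered profile is scaled so its pixel sum equals the
(noise-multiplied) volume, which the truth records as the spot's net
volume. The truth boundary mask is the rendered support — pixels
receiving ≥ 0.5 counts of foreground, i.e. everything quantization keeps.
Images are quantized to uint16 with clipping at 65535 (clipped pixels
counted per spot). Dust specks are flat disks (radius 1–2.5 px) of
specified per-pixel intensity, or scaled to add a chosen fraction of the
host spot's volume. Everything is a pure function of (config, seed).

What the generator does **not** emulate: enzyme-amplification
nonlinearity, optical PSF/bleed, photon (shot) noise statistics,
scratches and smears (non-compact artifacts), spatially correlated
printing errors, or antibody cross-reactivity. Passing tests therefore
demonstrate correctness of the *computational* chain under a realistic
noise model, not robustness to every failure mode of real slides.

## Simulation studies (study conditions)

* **Gradient discrimination**: five series at 0/25/50/75/100% target
  fraction plus a non-specific floor of 0.08 relative-concentration
  units, 15 spots each, 10% CV, plus a positive-control series at 8×;
  per-spot readouts are obtained by inverting the fitted curve at each
  net volume, calibrated by subtracting the mean 0% readout; adjacent
  levels compared by two-sided Welch tests over 100 Monte-Carlo
  replicates; linearity (R²) fitted on the five per-level means, as
  titration plots are drawn (replicate scatter is reported separately as
  mean ± SD).
* **Segmentation under shift**: 40 series (600 spots), per-spot jitter up
  to 30% of the pitch (Gaussian SD 15%, truncated), global shift 40% of
  the pitch on both axes; Dice overlap against truth masks.
* **Dust**: 4 arrays × 50 specks, each adding 20–50% of its host spot's
  volume; recall counts a speck whose pixels appear in the host's dust
  record, false positives are clean spots with any record.
* **Time course**: conditions at 0/6/24/48 h with programmed folds
  1/1/2/2 (baseline concentration 0.25), three replicate arrays averaged
  — a time-course panel replicates arrays in practice; folds are ratios
  of per-series readouts to the baseline readout.
* **Reproducibility**: ten samples with log-uniform concentrations in
  [0.1, 1], two independently rendered arrays, Pearson R over per-series
  readouts.

Problem sizes (100 gradient replicates, 600-spot shift arrays, 200
specks, 3 replicate time-course arrays) are the package's standing study
conditions; they run in well under two minutes each on one CPU.

## Numerical choices and degenerate inputs

* R² of a zero-variance response is defined as 0.
* Fold-change tables are kept at full precision and rounded to 2
  decimals only at serialization.
* The per-spot curve inversion clamps responses a relative 1e-9 inside
  (a, b) so it always returns a finite concentration.
* Fewer than 3 series / 3 distinct dilutions / 12 usable observations →
  `InsufficientDataError`; identical responses → `FlatFitError`; no
  detectable lattice → `GridNotFoundError`. Degenerate background
  annuli are flagged, never fatal.
* All tie-breaks (component choice, correlation argmax) are fixed
  deterministic rules; identical inputs give identical outputs, and all
  randomness flows from explicit seeds.

## Known limitations

* The readout is relative within an array (median 1); cross-array
  comparisons require a shared reference (e.g. total-protein
  normalization or common control samples), as on real platforms.
* With every spot on the lower shoulder *and* no bright series, the
  absolute scale of `b`/`c` is reported at a bound (readout ratios remain
  valid); the fit report exposes the parameters so this is visible.
* Dust in-painting assumes contaminants are compact; smears spanning
  more than 25% of a spot exclude it rather than repair it.
* The segmentation boundary is threshold-based; for spots whose true
  morphology is strongly non-radial (comet tails), the simulator cannot
  yet generate matching truth.
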