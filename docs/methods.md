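# Methods

This note documents the models, numerical choices, and known limitations of
fibrilkit's three analysis stages and of the synthetic-data generators used
to validate them.

## Kinetics: Boltzmann-sigmoid fitting

**Model.** ThT fluorescence growth curves are described by the empirical
Boltzmann sigmoid

    y(t) = y1 + (y2 − y1) / (1 + exp(−2 (t − t_half) / (t_half − t_lag)))

with initial/final plateaus y1, y2 (a.u.), half-time t_half (min), and lag
time t_lag (min).  The parametrization is chosen so that t_lag is exactly
the intercept of the tangent at t_half with the y = y1 baseline: the slope
at t_half is (y2 − y1)·k_agg/4 with k_agg = 2/(t_half − t_lag), so the
tangent descends the half-amplitude (y2 − y1)/2 over precisely
(t_half − t_lag) minutes.  This identity holds in closed form for any
parameter values and is asserted (to 1e-6 relative tolerance, via numerical
differentiation) on fitted curves in the test suite.  The model is purely
empirical; mechanistic nucleation–elongation models (Finke–Watzky,
secondary-nucleation kinetics) are out of scope.

**Fitting.** Bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) on the
parametrization (y1, y2, t_lag, gap) with gap = t_half − t_lag > 0, which
enforces the ordering constraint by construction; t_lag and gap are bounded
in (0, t_max].  Convergence tolerances are 1e-8 on parameters and cost,
with at most 5000 evaluations.  Initialization is cheap and robust: plateau
means from the first/last three points, t_half from the first mid-range
crossing, and the gap from the 10%-to-50% crossing distance.  Standard
errors come from the Gauss–Newton covariance (JᵀJ)⁻¹·s²; the t_half error
includes the t_lag–gap covariance term.

**No-transition guard.** A trace whose final-minus-initial rise is below
10% of its total range (or with zero range) raises a no-transition error
rather than returning a meaningless fit; non-convergence is reported via a
`converged` flag, never silently.

**Flagging gate.** A fit whose relative parameter uncertainty exceeds 20%
(including the gap, which governs k_agg and is the first casualty of
over-steep, under-sampled curves) is flagged but not discarded — the same
screening convention used to exclude unreliable parameters from very fast
aggregation conditions.

**Replicates.** Replicates sharing a time grid are combined into a mean
trace with per-timepoint mean absolute deviation (the error-bar convention
for this assay).  Both the per-replicate fits and the fit of the mean trace
are reported; the mean-trace fit populates the main study table by default
(`StudyConfig.fit_target`).

**Comparisons.** Percent reductions are 100·(control − value)/control.
Anion rankings sort IL conditions at one shared concentration ascending by
t_lag, t_half, or k_agg and compare the anion order to the
electroselectivity series HSO4 < AC < Cl < NO3 < BF4 (the inverse of the
Hofmeister solubility series for monovalent anions), reporting forward,
reverse, or no match.  Mixed concentrations in one ranking call are a
grouping error.

## AFM morphometry

**Flattening.** The best-fit background plane is estimated robustly:
least-squares fit, then up to two refits excluding pixels more than 3
robust sds (1.4826·MAD) from the plane, so sparse tall fibrils do not tilt
the background.  An optional per-row median subtraction removes
line-to-line scan offsets.  The output minimum is shifted to 0; flattening
is idempotent to numerical tolerance.

**Segmentation.** Pixels above threshold are labeled into 8-connected
grains (`skimage.measure.label`); grains below a minimum area (default 10
pixels) are discarded as specks.  The default threshold is the background
median plus 3× the robust noise sd.  The *median* reference matters:
because flattening pins the map minimum (≈ −4.5σ of the noise on a
megapixel image) to zero, an absolute 3σ cut would sit below the
background.  Grain heights are likewise reported relative to the
background median.

**Height measurement.** Per-grain maximal heights are read from a 3×3
mean-filtered copy of the map (configurable; 1 disables).  A raw pixel
maximum over an N-pixel object sits ≈ √(2 ln N) noise sds above the true
surface (≈ +1 nm at σ = 0.3 nm for a typical fibril footprint); the small
mean filter suppresses this bias to well under one noise sd while leaving
flat-topped fibrils ≥ 3 px wide unchanged.  Noise-free oracle tests disable
the filter and recover generator heights exactly.

**z₉₀%.** The empirical CDF uses the i/n convention; the z_q statistic is
the lower empirical quantile — the smallest observed height h such that at
least q·n objects have maximal height ≤ h.  This is deterministic, exactly
matches a brute-force sort-and-index oracle, and is monotone in q.  Images
of one condition are pooled by concatenating their height lists (pooled and
per-image values are both available).  The reported uncertainty is half the
central 95% interval of a seeded bootstrap (default 500–1000 resamples);
it is a reproducible dispersion estimate, not a claim about how any
particular published uncertainty was obtained.

**Calibration.** Default pixel size is 5000/1024 ≈ 4.883 nm (a 5 µm scan
at 1024 × 1024), used when a file header carries no physical size.

**Limitations.** No fibril tracing, persistence-length, twist-periodicity,
or tip-deconvolution corrections; a grain that merges several crossing
fibrils is counted once with the maximal height of the union, which is also
how grain-based workflows treat such fields.

## FTIR amide-I deconvolution

**Preprocessing.** The spectrum is cropped to 1600–1700 cm⁻¹ (≥ 50 points
required), a straight baseline through the window endpoints is subtracted,
Savitzky–Golay smoothing is applied, and the result is scaled to unit
trapezoid area over the window.  Since only area *fractions* are reported,
the normalization convention is immaterial to the results.  The nominal
20-point smoothing window is realized as 21 points so the filter is
symmetric.  The filter order is 4: over a 21-point window on a 1 cm⁻¹ grid
a quadratic filter visibly flattens σ ≈ 5–8 cm⁻¹ sub-bands and
redistributes several percentage points of area between neighboring
classes, while the quartic filter passes them nearly unchanged (measured
directly in the round-trip tests: max class error 2.3 vs 8.2 points).

**Band detection.** Candidate centers are local minima of the
Savitzky–Golay second derivative, snapped into the class intervals
(β-sheet 1620–1635 & 1690–1700, random/α-helix 1640–1658, β-turn
1665–1685, side-chain 1600–1620 cm⁻¹); a minimum falling between intervals
is assigned to the class of the nearest interval edge.  Every class is
guaranteed at least one candidate by injecting the interval midpoint when
none is found; candidates closer than 2 cm⁻¹ are merged.

**Fitting.** A sum of Gaussians (lmfit) with centers confined to their
class intervals, widths bounded to σ ∈ [2, 15] cm⁻¹, and non-negative
amplitudes.  Components whose fitted height falls below 1% of the tallest
are pruned and the reduced model refitted once.  Component areas use the
analytic form height·σ·√(2π), which agrees with numerical integration to
0.1%.

**Quantification.** Class percentages are class-area sums over the total
fitted area, so the four classes (three structural + side-chain) sum to
100%.  Reporting the side-chain share separately explains why the three
structural classes alone can total 94–98%.

**Limitations.** Gaussian line shapes only (no Lorentzian/Voigt, no
Fourier self-deconvolution); band–class assignment by position is the
standard convention but is not unique for proteins with unusual side-chain
absorptions; heavily overlapping bands make the decomposition non-unique,
which is why published percentage tables cannot be reproduced
bit-for-bit from spectra alone.

## Synthetic data

Each generator is a deterministic function of its spec (which carries the
seed); identical specs regenerate bitwise-identical data.

- **Kinetics**: Boltzmann sigmoid on a 0–200 min grid at 2-min sampling
  (lag times 16–67 min and half-times 19–80 min are well resolved with both
  plateaus), plus additive Gaussian noise scaled to the sigmoid amplitude
  (default 2%, matching typical plate-reader replicate scatter), 3
  replicates.
- **Fibril fields**: flat-topped anti-aliased rods (cylinder projection —
  chosen over a Gaussian cross-section for exact max-height ground truth)
  on a 1024 px / 5 µm field; defaults of 120 fibrils, lengths 100–600 nm,
  widths 15–30 nm (apparent, i.e. tip-broadened, widths), heights 4–12 nm,
  pixel noise 0.3 nm.  With configurable probabilities a fibril becomes a
  laterally associated pair (partner rod alongside, heights adding in the
  overlap strip) or a dense cluster of overlapping rods.  Objects are
  placed disjointly (rejection sampling with a 3-px margin) so the
  generator's per-object truth table corresponds one-to-one to segmented
  grains; dense specs may place fewer objects than requested.
- **Spectra**: one Gaussian per structure class (defaults 1652, 1628, 1672,
  1612 cm⁻¹ with σ 7/7/7/5) with prescribed area fractions, optional linear
  baseline, and noise scaled to peak absorbance, on a 1 cm⁻¹ grid.
  Reference composition presets (e.g. the ~54/20/24 helix/sheet/turn
  insulin monomer profile) are available via
  `spectrum_spec_from_reference`.

**What the generators do not emulate** — and hence what passing round-trip
tests do not demonstrate about real data: AFM tip convolution and imaging
artifacts beyond additive pixel noise; fibril curvature, branching and
crossing; correlated (1/f, drift) noise in kinetics and spectra; D₂O/water
vapor bands and ATR penetration-depth effects in FTIR.  Round-trip recovery
shows the estimators are correct and well-conditioned under the stated
noise model, not that instrument systematics are handled.

## Study orchestration

A YAML manifest declares conditions (exactly one control) with per-modality
file paths; anion labels are validated against the EMIM vocabulary
(HSO4, AC, Cl, NO3, BF4).  `run_study` executes all stages per condition,
records per-condition failures without aborting the run, and writes report
tables with fixed numeric formatting plus JSON metadata (package version,
seed, config hash), making repeated runs byte-identical.  Rankings are
computed per concentration for every kinetic parameter.

**Problem sizes.** The pipeline and determinism tests, and the simulated
study shipped with `fibrilkit simulate`, default to full-size 1024-px
fields; the test suite exercises down-scaled fields (256–512 px, 15–40
objects, with rod lengths scaled proportionally) — morphometry statistics
are size-independent apart from object counts, and the down-scaled fields
keep the suite fast.  Monte-Carlo checks use 100 kinetics seeds and 50
spectra, the sizes at which the reported medians/maxima are stable.
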