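# Methods

This note documents the models and procedures implemented in `pellimetrics`,
the assumptions behind them, the parameters that matter, and the design
choices made where more than one reasonable implementation exists.

## The two-phase fiber model and Eq.-style crystallinity

A bacterial cellulose fiber is modelled as a linear alternation of
crystalline and amorphous domains. A cellulose-binding dye stains the
disordered domains more efficiently, so a fluorescence intensity profile
along the fiber is bright over amorphous stretches and dim over crystalline
ones. The per-fiber crystallinity statistic is

    crystallinity% = Σ dark / (Σ dark + Σ bright) × 100,

with bright lengths defined as the FWHMs of retained profile peaks and dark
lengths as the gaps between the half-maximum edges of adjacent retained
peaks. Two consequences of this definition are worth keeping in mind:

* the stretches before the first and after the last retained peak are
  discarded — the statistic is defined on inter-peak structure, so a profile
  with n bright domains contributes only n − 1 dark ones (negligible for
  long fibers, a ~2.5-point downward bias at n = 10 on a 50%-duty pattern);
* the statistic inherits every bias of the peak measurement, which is why
  the peak filters and the reconstruction mode matter (below).

### Peak filters

Peaks are detected as local maxima (scipy `find_peaks`), with prominence in
the standard topographic sense and FWHM measured at half of (height − local
base), half-maximum crossings linearly interpolated between samples. Three
filters are applied in a fixed order:

1. FWHM ≥ 100 nm — the optical resolution floor; anything narrower cannot
   be a resolved domain;
2. spacing ≥ 100 nm — of a violating pair, the higher-prominence peak is
   kept (greedy, highest prominence first);
3. prominence ≥ the per-fiber median of the remaining peaks; ties at the
   median are retained.

The median-prominence cut presumes a mixed peak population: genuine domain
peaks plus a comparable number of weak spurious peaks (background debris,
noise bumps). It then removes exactly the spurious sub-population. On a
profile containing *only* genuine peaks the same rule necessarily discards
about half of them — there is no way around the arithmetic of a median — so
the synthetic generator deliberately includes a realistic nuisance
background (see below). `find_peaks_filtered` is verified against an
independently coded exhaustive enumerator applying the same three rules.

## SRRF reconstruction

For every subpixel of an M×-magnified grid, the radiality score samples the
intensity gradient (bicubic interpolation of central-difference gradients)
at `axes_in_ring` points on a ring of radius `ring_radius_px` and measures
how strongly the gradient lines converge on the subpixel: each ring sample
contributes ±(1 − d/r)², where d ≤ r is the distance from the subpixel
center to the gradient line and the sign is positive when the gradient
points uphill toward the center. Negative totals are clipped to zero.
Acquisition defaults are ring radius 0.5 px, magnification 10, 8 axes.
The grid convention maps source coordinate x to magnified coordinate
x·M + (M−1)/2 (pixel centers at integers, 0-based).

Frames are combined by TRAC of order 2 — the mean over time of products of
consecutive radiality frames. Two deliberate choices:

* **Intensity weighting is off by default.** Multiplying radiality by the
  local brightness sharpens every extended structure toward its brightness
  maximum; for 200 nm labeled stretches this compresses the measured FWHM
  to ~130 nm and biases the crystallinity statistic upward by 8–15 points.
  The pure gradient-convergence score preserves the extent of extended
  structures and is invariant to constant intensity offsets. A flag restores
  weighting.
* **Linearization.** TRAC is an order-2 correlation, so its amplitude is
  quadratic in radiality; `linearize=True` takes the square root before
  profile analysis, restoring an intensity-linear scale on which apparent
  widths track the underlying brightness profile. The raw TRAC map remains
  the default output (a temporally constant stack then reproduces the
  mean-square radiality map exactly).

Drift correction registers every frame to frame 0 by subpixel
cross-correlation (classic normalization, not phase correlation, which is
unreliable on smooth low-texture fluorescence scenes).

## Synthetic fluorescence data: what it emulates, and what it does not

`gen_fiber_stack` emulates dense small-molecule dye staining: emitters are a
Poisson process along the fiber (default 2000/µm in amorphous segments),
crystalline segments are attenuated by a dye contrast ratio (default 2.5 —
the dye binds disordered cellulose *more* efficiently, not exclusively, and
a continuous fiber ridge is also what keeps the reconstruction from
collapsing isolated bright blobs to point responses), each emitter blinks
independently per frame (p = 0.35), and every frame receives Poisson shot
noise over a constant background of 10 counts. Two static nuisance
components reproduce the structure a real TIRF background has and the
median-prominence filter expects: an optional correlated speckle field
(out-of-focus unbound dye) and, by default, 40 dim non-blinking point
sources (non-specifically adsorbed dye aggregates, ~12 photons). Being
static, the debris survives temporal correlation and supplies the weak,
wide spurious peaks that the median cut is designed to remove; genuine
domain peaks score 5–20× higher prominence, so the two populations separate
cleanly.

Geometry defaults follow the imaging scale of a TIRF acquisition: 100 nm
pixels, PSF σ = 0.65 px (65 nm), domain lengths around 510–600 nm
(crystalline) and 167–192 nm (amorphous), i.e. ≈75% crystallinity. Test and
acceptance runs use 30-frame 24×120 px stacks at magnification 4 — the
package's choice of simulation size; the pipeline itself is
size-independent.

Not modelled: real fluorophore photophysics (no triplet states, bleaching
or correlated blinking), fiber curvature and crossings (paths are straight
and isolated), axial structure, detector read noise, and drift (the
generator produces drift-free stacks; drift correction is exercised on
separately constructed inputs). Passing tests therefore demonstrate that
the analysis recovers truth under the stated two-phase staining model with
a realistic nuisance background — not that it is robust to every optical
artefact of a real microscope.

## WAXS analysis

Detector frames (flat detector, normal incidence; defaults 75 µm pixels,
50 mm distance, Cu Kα) are reduced by per-pixel 2θ binning with equal-width
bins; masked or doubly-invalid pixels are excluded, and the slit of a
two-exposure "line eraser" pair is removed by per-pixel averaging of the
unmasked contributions.

The amorphous background on 2θ ∈ [10°, 45°] is a shape-preserving cubic
(PCHIP) through anchor points: within every contiguous stretch at least
1.5° away from the known cellulose Iβ reflections (14.5°, 16.8°, 20.6°,
22.7°, 34.6° — standard powder-diffraction positions), the minimum of a
lightly smoothed (~1°) copy of the signal is taken per ~2° sub-window, and
the anchor value is averaged over ±0.25° to suppress the negative bias of
picking noise minima. The crystallinity index uses trapezoidal quadrature
of signal and background on the same grid. A two-broad-pseudo-Voigt halo
model is the documented alternative. The exclusion half-width trades two
biases: too narrow lets reflection tails lift the anchors (crystallinity
underestimated), too wide spans the halo's curvature with a chord
(overestimated); 1.5° keeps both under ~2 points at the study conditions.

Peaks are pseudo-Voigt profiles fitted by nonlinear least squares (lmfit)
to the background-subtracted signal, centers bounded within ±1° of their
initialization. Per reflection, the lattice spacing is d = 2π/q with
q = 4π sin(θ)/λ, and the crystallite size is τ = Kλ/(β cos θ) with K = 0.94
and β the fitted FWHM in radians; no instrumental-broadening correction is
applied by default (a quadrature-subtraction flag exists). Angles are
degrees at interfaces and radians internally.

## Raman preprocessing and band detection

Order of operations: Savitzky–Golay smoothing (degree 7; the nominal
12-point window is even and is widened to 13 — a symmetric kernel needs odd
support), piecewise degree-8 polynomial background subtraction over
256-point windows (50% overlap, Hann-taper blending, five
lower-envelope-clipping iterations per window), then normalization to the
maximum within 1094 ± 10 cm⁻¹. Subtraction precedes normalization. A
processing log makes the chain auditable and reprocessing is refused.

The carbonyl test at 1740 cm⁻¹ scores the maximum baseline-subtracted
intensity in a ±20 cm⁻¹ window against the SD of residuals in flanking
windows after a joint quadratic detrend. Because the score is a maximum
over ~40 samples, its null expectation is ≈2.3 SD; the presence threshold
is therefore set at 4 SD by Monte-Carlo calibration, which holds the
false-positive rate on band-free spectra at ~1–2% while a band at 10× the
noise amplitude scores ≥10.

## Tensile analysis

Raw crosshead displacement/force records are cropped at the first sample
reaching 2.5 mN and re-zeroed there; strain is Δdisplacement over the
20 mm starting grip spacing (no extensometer; shoulder compliance ignored)
and stress is force over the initial cross-section (2 mm width × measured
thickness). Rupture is the first sample where stress falls by ≥50% of the
running maximum within 3 samples, ignoring drops while the running maximum
is still below 10% of the record's peak (otherwise the near-zero noise
floor before loading triggers false ruptures). The modulus is the
least-squares slope over strains in [0.6, 0.8]·ε_max, where ε_max is the
strain at maximum pre-rupture stress; the strength is that maximum stress,
with the stress at the last pre-rupture sample reported alongside (the two
coincide for abrupt rupture).

## Density

Side-view photographs are segmented by Otsu's global threshold (manual
override available); only the largest connected component counts, which
discards reflections and dust. With the container radius r as user input,
h = A/(2r), V = πr²h and ρ = W/V, reported in mg/cm³. The synthetic
photographs place the pellicle rectangle at a sub-pixel offset — a real
photograph never aligns to the pixel grid, and exact alignment would make
every edge pixel ambiguously half-covered.

## Statistics

One-way and two-way fixed-effects ANOVA are computed through ordinary least
squares (statsmodels); two-way designs use Type II sums of squares, which
coincide with the balanced decomposition on balanced data (unbalanced input
warns). A design in which every observation is identical returns F = 0,
p = 1 rather than 0/0. Pairwise post-hoc comparisons are protected: they
run only when the omnibus p < 0.05, use pooled-variance t statistics with
the ANOVA residual mean square, and are Bonferroni-adjusted
(p_adj = min(1, p·m) over all m level pairs) with the conventional
*, **, *** star levels. Pearson's r is the standard product–moment
coefficient. Monte-Carlo calibration at the study conditions (4 groups of
6, 1000 replicates) keeps the omnibus type-I error at the nominal 5% and
the protected family-wise error below it.

## Numerical conventions and degenerate inputs

Seeded `numpy.random.default_rng` everywhere; identical inputs and seed
give bit-identical outputs. Half-maximum crossings and FWHMs are linearly
interpolated. Quadrature is trapezoidal on native grids. Flat profiles
yield empty peak sets (not errors); fibers with fewer than two retained
peaks are excluded with a named error; all-zero frames in drift correction
pass through with a warning and zero shift; zero-variance input to Pearson
correlation, empty two-way cells (named), out-of-range fit windows and
non-positive physical quantities raise `ValueError`s.

## Known limitations

* The SRRF implementation covers TRAC order 2 only; no GPU path, no other
  temporal modes, no fiducial drift correction.
* Fiber traces are inputs; there is no automatic tracing, and crossing or
  overlapping fibers must be excluded by trace selection.
* The crystallinity statistic saturates for domains below the 100 nm
  resolution floor; domain-length estimates near that floor compress toward
  the reconstruction's point-response width.
* WAXS analysis assumes an isotropic (orientation-free) pattern; no
  allomorph decomposition, Rietveld refinement or texture analysis.
* The tensile model is linear-elastic-to-rupture; no viscoelasticity,
  toughness or cyclic loading.
* The cylinder density model ignores meniscus curvature and assumes one
  side view is representative.
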