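# Methods

This note documents the models behind `qpiscreen`, the defaults and why
they were chosen, and what the synthetic benchmark does and does not show
about real microscope data.

## The phase phantom

Cells are modelled as smooth thickness profiles `d(x, y)` on a flat
background, converted to optical path difference by the thin-specimen
relation `OPD = d · (n_c − n_m)` with `n_c = 1.380` and `n_m = 1.334`
(watery culture medium; the excess 0.046 is a typical cytoplasmic
refractive increment). Profiles are squared-cosine caps rather than binary
disks: a hard-edged phantom has unbounded phase gradients, which makes the
holographic and transport-of-intensity round trips ill-posed and would
test the phantom, not the solver.

Three classes encode the screen's phenotypes:

| class | geometry | peak thickness | peak OPD |
| --- | --- | --- | --- |
| control | ellipse 13 × 5 µm (aspect 2.6) | 1.8 µm | ≈ 83 nm |
| round | circle r = 7 µm | 4.0 µm | ≈ 184 nm |
| vesicle | ellipse 8 × 6 µm + 4 puncta (r = 1.5 µm, +2.5 µm) | 1.2 µm soma | ≈ 55 nm soma, ≈ 170 nm at puncta |

No absolute per-phenotype OPD magnitudes are dictated by theory; these are
free parameters of the generator set to adherent-cell scales and exposed in
configuration. Two deliberate structural choices matter downstream: the
rounded class concentrates the same order of dry mass into a smaller, taller
footprint, so it raises the average-OPD readout strongly; the vesicle class
is nearly average-OPD-neutral (its thin soma and bright puncta roughly
cancel over the threshold mask), so it is visible to per-cell granularity
features but nearly invisible to the global OPD readout. That asymmetry is
what lets the two analysis routes report different dose sensitivities, as a
per-cell analysis trained on vesicles responds at doses the global readout
ignores.

The low-contrast cell type (`h9c2`) is the same geometry with all
thicknesses scaled by 0.5 — half the OPD signal of the compact
high-contrast type (`hela`).

Placement is dart-throwing (Poisson-disc) with a minimum centre separation
defaulting to the sum of semi-minor axes; per-cell size/thickness jitter is
lognormal (σ = 0.08) and orientation uniform. Rendering with `non_overlap`
set rejects placements whose centres come closer than half the summed
semi-minor axes.

### Noise model

Two noise sources, both OPD-domain:

* **Pixel read noise**: additive Gaussian, default σ = 3 nm — the nm-scale
  temporal phase noise of holographic instruments.
* **Background-flattening residual**: a constant per-well OPD offset,
  default σ = 3 nm, constant across a well's four fields. Residual
  reference-wave curvature after polynomial flattening is dominated by
  well-scale geometry (meniscus, plate bottom), so it does not average out
  over fields within a well. This is the mechanism by which the
  low-contrast cell type yields a weaker screening window: an absolute nm
  floor consumes twice the relative fraction of a halved signal window.
  Shot noise at the intensity level is additionally available in the
  optical forward models (`photon_budget`).

The default pixel size is 0.62 µm so that a 3-pixel blur equals 1.86 µm,
matching the cell-counting convention below.

### Plate and kinetics

Endpoint plates draw each well's confluency uniformly from 25–60% and
express the treated phenotype in a Bernoulli fraction given by a
four-parameter logistic dose model evaluated at the well's concentration
(`bottom` at zero dose). Time-lapse runs image every 10 min for 24 h by
default (145 frames including t = 0). Cells destined to express transition
at a time drawn uniformly from `[onset, onset + ramp]`; several effects can
be layered (e.g. early low-EC50 vesicle formation plus late high-EC50
rounding), with earlier-listed effects claiming cells first. All
randomness descends from the single design seed through per-well/field/
frame seed sequences, so every output is bit-reproducible.

## Optical forward models

Propagation is the exact angular-spectrum kernel (unitary over the
propagating band, evanescent components truncated); at a few µm of defocus
and NA ≈ 0.25 the Fresnel approximation would already bias the ±5 µm
planes. Off-axis holograms are `I = |O + R|²` with `O = exp(iφ)`,
`φ = 2π·OPD/λ` at λ = 684 nm, and a tilted plane reference at a default
carrier of (0.25, 0.25) cycles/pixel — far enough from DC for clean
sideband isolation. Defocus stacks are `|P_z O|²` at z = −5/0/+5 µm,
λ = 740 nm.

Before any FFT the object **phase** is rolled to zero at the border with a
raised-cosine window (default 16 px). Tapering the amplitude instead — the
more common convention — injects intensity structure at the border that
the TIE's nonlocal inverse Laplacian smears into the interior; phase
apodization suppresses wrap-around with no intensity side effects.
Accuracy metrics exclude the tapered margin.

## Holographic reconstruction

Demodulation pipeline: multiply by `exp(−i2π k·x)` to shift the sideband
at the carrier `k` to baseband; low-pass with a raised-cosine circular
window of radius half the carrier-to-DC distance (the standard compromise
between resolution and DC leakage); inverse FFT; **conjugate** (the
sideband centred at +k is the conjugate cross term `O*R`, so the physical
phase sign requires conjugation); optional angular-spectrum refocus;
`arctan2` phase; 2D unwrapping (reliability-sorted, via
`skimage.restoration.unwrap_phase`); background flattening by a 2nd-order
polynomial fitted on pixels below an Otsu threshold, with the background
median pinned to 0 nm. Carriers closer than 0.06 cycles/pixel to DC are
rejected ("carrier too low"). Automatic carrier detection finds the
strongest non-DC Fourier peak in the positive-row-frequency half-plane
with 3×3 centroid sub-bin refinement; because the two sidebands are
conjugate twins, the half-plane choice is a sign convention.

Measured on 512² smooth objects the round trip is ≈ 0.006 rad RMSE
(≈ 0.7 nm) inside the margin, linear to 0.1% under OPD doubling, and
refocusing a 10-µm defocused recording restores in-focus accuracy.

## Transport-of-intensity solver

For a uniform-intensity (pure phase) specimen the TIE reduces to a Poisson
equation; the solver estimates `∂I/∂z` by the central difference of the
±Δz planes and inverts the Laplacian spectrally with Tikhonov
regularization, `÷ (4π²|q|² + ε)`, zero-frequency set to 0 (the recovered
phase is mean-free). The image is mirror-padded before the solve, imposing
even (Neumann-like) symmetry that suppresses periodic-boundary artifacts.

The regularization default is ε = 10⁻⁶ × max(4π²|q|²). The choice is
load-bearing: cell-sized structures (tens of µm) live at |q|² some four
orders of magnitude below the grid maximum, so a floor of 10⁻³ — a common
choice for suppressing low-frequency noise blow-up on noisy data —
attenuates the cell-scale signal several-fold and makes a noise-free round
trip fail at the 10% level. At 10⁻⁶ the noise-free round trip is ≈ 1%
while low frequencies remain bounded; for shot-noise-limited stacks ε
should be raised (it is exposed in configuration). The residual at ±5 µm
is dominated by the finite-difference bias of the axial derivative and
shrinks monotonically as Δz is halved.

The full intensity-divergence form of the TIE is not implemented: the
specimens of interest are transparent with near-unit transmission.

## Global metrics

* **Confluency**: fraction of pixels with OPD ≥ threshold; the threshold
  default is 15 nm, a few σ above the read noise. It is a required
  configuration entry, not physics.
* **Cell count**: Gaussian blur with σ = 3 px (1.86 µm; the blur parameter
  is interpreted as a Gaussian σ) followed by detection of local maxima
  with prominence ≥ 30 nm — height above the highest saddle toward a
  larger maximum, implemented as grayscale h-maxima, the same semantics as
  ImageJ-style "find maxima" noise tolerance. Maxima outside the cell mask
  are discarded. Counting is exact for cells whose centres are separated
  beyond their footprint diameter; merging below the blur scale is counted
  as one, as it should be.
* **Average OPD**: total masked OPD divided by mask area. With disjoint
  identical cells this is provably independent of how many cells are in
  the field (each cell contributes the same mask and the same OPD mass),
  which the benchmark confirms to < 0.5% over 10–60% coverage; it rises
  when the same mass is remapped into taller, rounder cells. Departures
  from confluency-independence in dense fields come from overlapping cell
  skirts, a real effect, not an estimator artifact.

## Per-cell analysis

Segmentation is OPD thresholding, connected components, and a watershed on
the inverted blurred OPD seeded at the counting maxima; components missed
by every seed survive as single objects. Objects outside [50, 8000] px or
touching the field border form the *segmentation error* class — a pure
area/border rule, since no principled per-object error model exists — and
are excluded from fractions: `fraction = n_class / (n_total − n_error)`.

Features per object: area, Crofton perimeter (less biased than chain-code
length on digitized disks, keeping a circle's form factor `4πA/P²` near 1),
form factor, eccentricity, mean/max/integrated OPD, OPD variance, and a
granularity spectrum — the fraction of OPD mass removed by grayscale
openings at radii 1–4 px, which responds selectively to vesicle puncta.

The classifier is gradient-boosted shallow trees (200 × depth-2) on
standardized features, the same family as the machine-guided learning used
by high-content screening tools, with a logistic-regression fallback for
reproducibility studies; per-modality retraining is supported via a
modality tag and the feature standardization absorbs overall signal-scale
differences between imaging modes. On the synthetic classes the held-out
accuracy saturates near 1.0 in both contrast regimes — the phantom classes
are well separated by construction, so this validates the plumbing
(segmentation → features → model → fractions), not classification
difficulty on real cells.

## Screening statistics

Wells average their four fields. `Z' = 1 − 3(s_pos + s_neg)/|m_pos −
m_neg|` uses sample SDs (n−1); coincident means are flagged undefined.
Time-lapse series condense to a raw trapezoidal AUC (no smoothing is
applied; baseline subtraction of the t = 0 value is flag-controlled, and
both modes are provided since either convention is defensible). The 4PL is
fitted in log10-dose space by bounded least squares with five starts
(hill ∈ [−10, 10], log-EC50 within the dose range ± 2 logs); the vehicle
response enters at two logs below the lowest dose; the (bottom, top, hill)
↔ (top, bottom, −hill) label symmetry is canonicalized to positive hill;
flat responses return a non-convergent fit with no EC50. Onset is the
first time with `m = 3` consecutive points beyond baseline mean ± 3 SD
(direction selectable; an absolute tolerance substitutes when the baseline
SD is zero) — the multiple-point run requirement trades one frame of
latency for robustness against single-frame excursions.

## Benchmark problem sizes

The reference experiments use 192² endpoint fields (16 wells × 4 fields
per arm), 128² time-lapse fields at 10-min sampling over 8–12 h, and 512²
fields for the optical round trips. These sizes keep a full benchmark run
around a minute on one CPU while leaving every per-field quantity (tens of
cells, hundreds of OPD-significant pixels per cell) in the regime where
the estimators behave as they would on full-sized images.

## What the benchmark does and does not show

The generator reproduces the *structure* of a label-free screen: plate
layout, replicate counts, confluency range, contrast regimes, dose and
kinetic ordering of two phenotypes, nm-scale noise. It does not reproduce
real cellular texture, cell–cell contact and overlap at high confluency,
debris, drift, illumination gradients, or instrument aberrations beyond a
constant flattening residual; classifier accuracies and Z' values on real
images will be lower. Reported Z' and EC50 values characterize this
simulation — they are not predictions of any instrument's numbers, and
published values from experimental screens depend on image data that is
not reproducible here. What carries over are the invariants: the
quantitative linearity of reconstruction, the confluency-independence and
shape-sensitivity of average OPD, the error-corrected fraction formula,
the closed-form Z', and the ordering phenomena (lower contrast → weaker
window; an early-phenotype-sensitive readout → lower apparent EC50).

## Known limitations

* No partial-coherence or objective-MTF modelling; the forward models are
  scalar and coherent (the TIE stack's LED illumination is treated as
  quasi-monochromatic).
* No aberration compensation beyond polynomial flattening; refocus
  distance is user-given (no autofocus search).
* No cell division, migration, or tracking across time-lapse frames;
  per-frame fields are static apart from phenotype transitions.
* Hologram reconstruction assumes a single dominant carrier; multiplexed
  or strongly aberrated holograms are out of scope.
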