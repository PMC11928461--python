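# Methods

This note documents the models, conventions and default parameters
behind each analysis stage, what the synthetic-data generators emulate
(and deliberately do not), and the numerical choices made where the
design was open.

## Imaging conventions

All images are 2-D intensity grids with a physical pixel size
(`pixel_size_um`, default 0.1 µm on a 256×256 field). Coordinates are
0-based (row, col); areas are always reported in µm² via
`pixel_size_um²`.

**Segmentation.** The membrane channel is Gaussian-blurred (σ = 1.5 px,
the standard detector-noise suppression for confocal GUV images) and
thresholded. Otsu's method is the default because it is deterministic
and parameter-free; a fixed threshold can be supplied instead. Otsu ties
are irrelevant here because thresholding is applied to the blurred
float image with scikit-image's 256-bin histogram. The mask is
shift-invariant under a uniform intensity offset (the histogram shifts
with the data) and translates with the image.

**Recruitment.** The recruitment readout is the integrated protein
intensity over the mask normalised to the mask area — identically the
mean masked intensity. It is linear in the coat brightness, which the
generator linearity test exploits.

**Relative lipid order φ.** The ratio of a blue/green emission window to
a red emission window of a solvatochromic membrane dye reports lipid
packing. "Ratio" is ambiguous between the ratio of masked sums and the
mean of per-pixel ratios; we use the **ratio of sums**, which is robust
to per-pixel division noise at low counts, and expose the per-pixel
ratio map (out-of-mask pixels zeroed) for display. Both conventions
coincide on noise-free uniform membranes. The live-cell variant
subtracts a per-channel scalar background (mean over a user-drawn
background region), clips negative pixels to zero, and flags — rather
than drops — regions whose background-subtracted red signal vanishes.

**Condensate detection.** Threshold + connected components with
**8-connectivity** (diagonal contact merges), area filter in µm². A
field is called condensed when the mean condensate area exceeds 0.4 µm²
*and* the count normalised to a 90 µm² reference region exceeds 20.
Normalising the count to a reference density makes the call invariant
to subdividing the field. The mean area of an empty field is reported
as 0 so the classifier is total.

**Granulosity index.** G = sd/mean of the image after a circular
Fourier high-pass (cutoff in cycles per image dimension; it must be
held constant across any series being compared, and is a required
parameter because no universal value exists). A literal circular
high-pass would remove the DC component, making the mean ≈ 0 and the
index ill-defined; we therefore **retain DC**, so the denominator is
the image mean, a constant image gives exactly G = 0, and G is
invariant to rescaling the image by any positive factor — the only
reading under which the index is finite and well behaved.

## Phase-boundary fitting

The condensed/dispersed calls over a two-concentration grid are
separated with a support-vector machine: linear kernel or 2nd-degree
polynomial kernel (γ = scale, coef0 = 1), features standardised,
regularization C = 1 by default (recorded in the output; separable toy
problems benefit from larger C). Points are sorted canonically before
fitting so the boundary is independent of input order.

## Kinetics

**FRAP.** Normalisation F(t) = (I(t) − I_bleach)/(I_pre − I_bleach)
with I_pre the pre-bleach mean and I_bleach the **first post-bleach
frame** (no back-extrapolation, matching the common plugin convention);
invariant to affine rescaling of the raw trace. The recovery model is a
single exponential M(1 − e^(−t/τ)) with M ∈ [0, 1], τ > 0, fitted on
post-bleach frames with t re-zeroed at the bleach. A single exponential
is the minimal model consistent with reporting % recovery at fixed
times (5 s, 15 s); diffusion-coupled models are out of scope.

**Dose–response.** 4-parameter logistic in log₁₀(concentration).
Saturation within the tested range is called when the fitted curve at
the top dose is within 5% of the plateau amplitude *and* the plateau's
95% confidence half-width is below 20% of its value. The rule is a
package definition that separates lipid-site binding (plateaus by
~10 µM) from collective condensation-driven binding (still rising at
~30 µM). Degenerate fits (constant response) are returned flagged, not
raised.

## IR spectral analysis

Grids are uniform ascending, ≤ 2 cm⁻¹ step, covering 1400–1794 cm⁻¹.
Two instrument modes reproduce the respective published workflows:

* **afmir** (nanospectroscopy): 3-point adjacent averaging →
  Savitzky–Golay smoothing (order 2, 13 points) → max-normalisation;
  second derivative by SG (order 2, 13 points) followed by a further
  13-point SG smooth.
* **ftir** (ATR): SG smoothing (order 2, 9 points) → normalisation;
  second derivative by SG (order 2, 11 points).

Band positions are the **second-derivative minima** (not absorbance
maxima), refined by 3-point parabolic interpolation; localization error
on noise-free Lorentzians is below half a grid step across the
1700–1760 cm⁻¹ C=O window, and the position is invariant to
multiplicative rescaling.

**Width calibration.** The band width is the separation of the
second-derivative zero crossings scaled to an FWHM equivalent. For an
analytic Lorentzian of FWHM Γ the *unsmoothed* second derivative
crosses zero at ±Γ/(2√3) (so Γ = √3 × separation), but the SG passes
broaden the lobes far beyond that. The calibration factor was therefore
computed once by passing an analytic 20 cm⁻¹ Lorentzian (2 cm⁻¹ grid)
through each mode's full pipeline and is frozen in
`spectra.WIDTH_CALIBRATION` (afmir 0.9339, ftir 1.1591). Because SG
broadening is not a pure rescaling, the factor is exact at the ~20 cm⁻¹
anchor width typical of the lipid carbonyl band and approximate away
from it.

**Amide-I fractions.** A linear baseline anchored at the 1600–1700 cm⁻¹
window endpoints is subtracted and the corrected absorbance is
integrated over fixed sub-band windows (intermolecular β-sheet
1610–1630, β-sheet 1630–1645, random coil 1645–1652, α-helix 1652–1662,
turns 1662–1690 cm⁻¹ — standard FTIR assignments; the exact windows are
config-overridable, and fractions are only comparable within one window
set). Fractions are sub-band areas divided by their sum, so they total
exactly 1. Integration runs on a 0.1 cm⁻¹ resampled grid so the
boundaries partition cleanly. Band overlap biases windowed integration
slightly toward neighbouring classes (a 30% β mixture reads ~27%); the
resolution test shows a 3-point true difference is reported to within
those few tenths, comfortably below the 5-point scale at which
aggregation is called.

## Membrane mechanics

Over the 100–1000 Pa assay range the vesicle elongation (strain, ΔL/L₀)
is linear in the applied pressure drop; the OLS slope is the compliance.
The **relative elastic modulus** is defined as
E_rel = slope(reference)/slope(sample) — the minimal definition under
which a linear stress–strain plot yields a dimensionless modulus,
stiffer membranes score higher, and the identity
E_rel(a,b)·E_rel(b,a) = 1 holds. Naked GUVs are the reference (= 1) by
convention. The forth/back record reports slope and intercept
differences with combined standard errors and pools the two directions
when both differences fall within 2 SE; the full ANCOVA is a standard
test left to external tools, for which the record exposes the needed
statistics.

## Diffusional sizing

Plug-flow approximation: the residence time at observation position i
is t_i = L_i·(width·height)/Q, with diffusion modelled along the width
only (height-averaged concentration) — Poiseuille (Taylor–Aris)
dispersion is neglected, which is the main known limitation of the
forward model. The diffusion equation with no-flux walls and a top-hat
initial stream over `sample_stream_fraction` of the width is solved by
a cosine eigenfunction expansion (modes truncated once their decay
factor falls below 1e-18, capped at 4000; t = 0 returns the exact
top-hat because the truncated series would Gibbs-oscillate). Every
profile conserves the initial mass to 1e-3 relative, and the series
agrees with an implicit (Crank–Nicolson) finite-difference oracle to
1e-4 max-norm.

Fitting minimises the summed squared profile mismatch across the four
positions over a 200-point log-spaced R_H grid in 0.1–50 nm, with a
free linear amplitude per profile (absorbing exposure/background
nuisance), then refines by golden-section search between the best grid
neighbours to 0.01 nm. The objective is unimodal on noise-free inputs.

Default chip geometry and conditions (exact chip dimensions for any
given device are required config): width 300 µm, height 25 µm, stream
fraction 0.25, observation path lengths 5.3/19.9/57.3/81.8 mm, flow
60 µL/h (within the 20–150 µL/h operating range), T = 298.15 K,
η = 8.9e-4 Pa·s. At these settings the 18.65 nm vesicle preset spreads
by ~30 µm at the last window — well inside the sensitive regime.

## Synthetic data

All generators are seeded (`numpy` PCG64; identical seed + parameters ⇒
bit-identical output) and return a ground-truth record sufficient to
predict the ideal output of their matched analysis stage. Noise is
**additive Gaussian** clipped at zero — not Poisson — because every
downstream stage is ratio- or fit-based and insensitive to the noise
family at the tested SNRs; `noise_sd` is expressed in each modality's
own intensity units (default 2.0 counts on a background of 10 for
images; trace/spectrum/strain generators take explicit overrides).

Specific choices:

* **GUV rings** render with an apparent membrane width of 0.8 µm — the
  diffraction-broadened thickness a high-NA confocal shows for a
  bilayer — so that blur-then-threshold segmentation reproduces the
  true ring area to within its documented tolerance. Membrane and coat
  amplitudes default to 100 counts (SNR 50 at default noise; the dye's
  absolute brightness is unpublished, so this is a package choice).
* **Dye ratio images** set on-membrane windows to exactly
  (φ·A_red, A_red), so the expected per-pixel ratio equals the
  configured φ.
* **Condensate disks** pick each radius so the rasterised pixel count
  matches the drawn area to within one pixel (the n-th nearest-pixel
  construction), and placement keeps 3 px clearance so 8-connected
  components never merge.
* **Spectra** are sums of Lorentzian (lipid) and Gaussian (amide)
  bands. The liquid-phase C=O preset sits at 1730 cm⁻¹ with 20 cm⁻¹
  width; the gel preset is placed 8 cm⁻¹ above the liquid position
  because the transition is characterised by its shift, not an absolute
  gel wavenumber. Amide presets realise a configurable true
  intermolecular-β fraction with the remaining classes in fixed
  proportion.
* **Deformation series** follow strain = P/(k_ref·E_rel) with
  k_ref = 5000 Pa, giving realistic strains of 0.02–0.2 for a naked
  vesicle over 100–1000 Pa. The stiffness presets
  {naked 1.0, FL-coated 2.5, FL+ALG2 3.5, FL+CALC 1.3} are invented
  magnitudes chosen to satisfy the qualitative >2-fold and >3-fold
  bounds of the assay they emulate, and are documented as such in the
  ground truth.
* **FRAP traces** sample at 11 Hz with ~1 s of pre-bleach frames.

What the generators do **not** emulate: optical point-spread functions,
camera gain/offset statistics, 3-D geometry, membrane undulations,
photobleaching during acquisition, realistic lipid spectral libraries,
or polydisperse size mixtures. Passing the recovery tests therefore
demonstrates the correctness of the analysis algebra and fitting
machinery under the stated noise model, not robustness to every optical
artefact of real data.

## Problem sizes

Default test and reference computations use 256×256 images (64×64 for
the granulosity oracle, which compares against an explicit DFT-matrix
evaluation), 198-point spectra, 10-point pressure series, 200-frame
FRAP traces, a 200-point radius grid with 256-point profiles for
sizing, and 100 replicates for the seeded EC50 recovery study — sizes
at which every stage runs in seconds on one core while keeping
estimator error well below the tested tolerances.
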