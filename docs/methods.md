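# Methods

This note documents the models, conventions and numerical choices behind
`dropletlab`, and what its synthetic-data validation does and does not
establish about real microscopy data.

## Scope and data model

The package analyzes in-vitro liquid–liquid phase separation (LLPS)
experiments in which two proteins — a pentameric scaffold labeled with a
green dye and a disordered partner labeled with a red dye — form liquid
droplets under macromolecular crowding. Images are two-channel fluorescence
fields (`ImageStack`, `(C, Y, X)` float with pixel size in µm; optional
Z-stacks `(C, Z, Y, X)`), analyzed strictly per Z-slice: droplets are
treated as 2D circles on each plane, never as 3D volumes.

## Synthetic scenes

`synthgen` paints each droplet with an analytic radial law
`background + amplitude_c · g_c(r)` per channel, where `g_c` is 1 in the
core, `shell_factor_c` in an outer top-hat annulus occupying the last
`shell_width_fraction` of the radius, and falls linearly to zero over
`edge_softness` pixels centred on the radius. The top-hat shell is the
simplest parameterization with a testable shell-to-core contrast; the
linear edge ramp keeps the ground truth piecewise-linear so profiles can be
checked analytically. Z-stacks use spherical cross-sections (in-plane
radius shrinks with distance from the droplet's centre plane).

Noise is additive Gaussian by default, with a Poisson (shot-noise) mode;
camera bit depth, gain and read-noise statistics are deliberately not
modelled. There is no point-spread function and no chromatic aberration:
the uniform bead fixture therefore tests the *analyzer's* neutrality (a
perfectly flat two-channel ratio must come out flat), not the optics.
Consequences for interpretation: passing round trips demonstrate that the
analysis chain is unbiased on data that satisfy its geometric assumptions
(circular droplets, radially symmetric composition, uniform background);
they do not establish robustness to PSF blur, aberration, tilted
illumination or aspherical droplets.

Default study conditions baked into tests and examples: droplet radii
12–20 px at 0.1 µm/px (1–2 µm droplets), shell width 15% of the radius with
1.3× enrichment, 30 sampling rays, two-channel amplitude ratios set by the
concentration scenarios below. All randomness flows from one explicit
integer seed recorded in the scene spec; equal seeds reproduce images
bit-for-bit.

## Segmentation

Both channels of a slice are independently min–max scaled to [0, 1]
(constant channels map to zeros and carry a warning flag). Detection then
iterates on channel 1 (the scaffold channel, which defines droplets):

1. seed at the brightest unassigned pixel; stop when that peak falls below
   the stopping threshold (default 0.75 of the normalized slice maximum);
2. flood-fill the connected region above 50% of the seed peak — the
   standard full-width-at-half-maximum boundary rule;
3. split candidate regions by watershed on the Euclidean distance
   transform (peak markers at least `0.7·max(EDT)` apart), so touching
   droplets resolve;
4. validate circularity `4πA/P²` ≥ 0.8 (configurable), with the Crofton
   perimeter estimator (4 directions), which is the least biased of the
   available estimators for smooth convex masks — a rasterized disk scores
   ≈ 1.0, a 2:1 ellipse ≈ 0.84, thin lines ≈ 0.

Examined pixels are marked assigned whether or not the candidate
validates, which guarantees termination and the partition property (no
pixel in two regions). Droplet radius is the equal-area-circle radius;
the centre is the channel-1 intensity-weighted centroid. Channel 2 is
always measured on channel-1 masks.

## Radial profiling and the shell statistic

For each droplet the surrounding crop (1.2× radius plus margin) is
re-normalized per channel to [0, 1] (the "secondary normalization"). The
normalization window is the crop, not the mask alone: the crop includes the
rim falling to background, so the channel minimum sits at background and
the maximum at the channel's brightest structure. This choice makes the
ratio algebra exact — for a droplet with shell factors (1.3, 1.0) the
normalized shell/core ratio contrast is precisely 1.3 — whereas
normalizing over mask pixels only would compress the contrast by the
mask's interior minimum.

Intensity is sampled by bilinear interpolation along `n_radii = 30` equally
spaced rays out to 1.2× the radius (≈ 1 px distance steps). Ray averaging
(rather than annular binning) retains per-ray traces, so the s.d. envelope
across rays is available. The ratio trace divides ray-averaged channel
means (averaging per-ray ratios first is available as an option; on
noiseless symmetric droplets the two agree). Distances where the
denominator channel falls below ε = 0.05 of the normalized scale are
masked — this is the divide-by-zero guard at the droplet edge.

The shell-enrichment statistic is the mean ratio over the outer annulus
(`radius·(1 − 0.15)` to `radius`) divided by the mean ratio over the core
(0 to `0.5·radius`). It is ≈ 1 on uniform droplets and beads, ≈ `f1/f2` on
shell factors `(f1, f2)`, and reciprocal under swapping the channels. The
1–2% shortfall observed on synthetic droplets (1.29 recovered for a true
1.3) comes from interpolation smoothing across the core/shell step and is
well inside the 5% validation tolerance.

## FRAP

Recovery traces are normalized so the pre-bleach mean is 1; the model is
the hyperbola `I(t) = (I0 + I∞·t/t½)/(1 + t/t½)` fitted by
Levenberg–Marquardt within bounds, with a deterministic initializer
(I0 = first sample, I∞ = last, t½ = time of closest approach to the
midpoint). Mobile fraction is `(I∞ − I0)/(1 − I0)`, clipped to [0, 1] with
the raw value retained. Flat traces return Mf = 0 with a low-confidence
flag instead of failing; traces ending before one half-time are flagged
likewise. Global acquisition photobleaching is corrected by dividing by
`exp(−k·t)`, with `k` fitted to an unbleached reference as a single
exponential (non-decaying references give k = 0 with a warning).

`D_app = 0.224·r²/t½` with r the bleached-spot radius (default 0.5 µm, a
1 µm diameter ROI). The finite-difference simulator (explicit FTCS on a
disk with reflecting boundary, time step 0.2·h²/D against the 0.25·h²/D
stability bound, full bleach of a concentric disk, an immobile fraction
held fixed) reproduces this relation within ~16% when the bleach spot is
small relative to the droplet — consistent with the hyperbolic fit being an
approximation to true diffusive recovery; the 20% consistency tolerance
reflects that model mismatch, not numerical error.

Note: for t½ = 14.3 s and r = 0.5 µm the formula gives
D_app = 3.92 × 10⁻³ µm²/s. Reference tabulations pairing this half-time
with 2.9 × 10⁻³ evidently used a different effective radius or averaging
order; the package reports the formula exactly as written.

Viscosity scaling: since D ∝ 1/η, a hypothetical η fold-change multiplies
t½ by the same factor, and the recovered fraction within a window t is
`Mf·x/(1 + x)` with `x = t/(t½·fold)`. For the uncrowded reference fit
(Mf 0.79, t½ 14.3 s) a 100-fold viscosity increase still predicts 23%
recovery within a 10-minute window — the quantitative basis for attributing
stronger immobilization to network cross-linking rather than viscosity.
The 10-minute window is this package's fixed convention for that
prediction.

## Quantitation

Calibration curves are ordinary least-squares lines through mean
intensities of uniform dye fields at known concentration, gated at
R² ≥ 0.95: a failed gate signals saturation/quenching and refuses the
curve rather than silently extrapolating a nonlinearity. Conversion to
total protein concentration divides by the labeled fraction (e.g. 0.10)
and by the quantum-yield correction factor (defaults 0.73 green, 1.43
red). Curves carry their crowder condition and refuse mismatched lookups
unless overridden, since crowders shift dye quantum yields.

Image photometry: background is the per-channel median outside all
(dilated) masks and is subtracted; droplet means exclude a 2-px rim
(eroded mask) to avoid partial-volume bias at the edge ramp. Whether
published droplet means included the rim is unknowable from the outside;
the exclusion margin is a documented choice here, and on synthetic flat
droplets it makes the round trip exact.

Partition coefficients are dense/light mean intensity after background
subtraction; light-phase concentrations come from linear interpolation on
plate-reader standard curves divided by the labeled fraction; time-lapse
composition traces divide out per-channel bleach exponentials, normalize
channel 1 to its first frame, and report the channel-2/channel-1 ratio.

## Viscometry

The glycerol/water oracle implements the Cheng exponential-blending
mixture formula (water and glycerol viscosity branches plus a
composition/temperature-dependent blending exponent), accurate to ~1%
against tabulated values at 20 °C (1.005 mPa·s water, 1.41 Pa·s glycerol).
Rotor standard curves are lines in log–log space (Förster–Hoffmann
power law `I = a·η^x`), requiring ≥ 3 standards spanning ≥ 1 decade and
monotone intensities. Estimates outside the calibrated range are returned
with an extrapolation flag rather than refused — relevant because
condensate viscosities (≈ 2 Pa·s) exceed the pure-glycerol range at room
temperature, so validation uses a synthetic power-law ladder spanning
10⁻³–10 Pa·s. Default glycerol ladder: mass fractions 0–0.9 in steps of
0.1 at 25 °C.

## Phase diagrams

A well is scored phase-separated at A340 ≥ 0.1 (inclusive, configurable).
Replicate wells are combined by median — robust to a single aberrant
replicate, the natural choice for triplicates. The boundary is the set of
Pareto-minimal positive (conc A, conc B) pairs per crowder level; no
binodal is fitted or interpolated, because per-well scoring is the raw
observable. The synthetic grid generator places a sigmoidal turbidity rise
at a known saturation concentration, and boundary recovery is validated to
within one grid step.

## Problem sizes and determinism

Validation runs use scenes of 101²–160² px with 1–4 droplets, FRAP traces
of 240–480 samples, a 200-replicate noise study (σ = 0.02), and a
diffusion grid of ~100² nodes — sizes at which every statistic is stable to
well inside its test tolerance while the full suite completes in well
under a minute. Statistical tests (noise unbiasedness within 2·SE) run
with fixed seeds as deterministic regressions; the unbiasedness check uses
an interior bleach depth (I0 = 0.21), since an estimator bounded at I0 ≥ 0
is necessarily biased when the truth sits on the boundary.

## Known limitations

- No PSF, aberration or illumination-field modelling; real-data accuracy
  at droplet edges will be worse than the synthetic round trips suggest.
- Segmentation assumes bright, roughly circular droplets on a darker
  background; it will not separate heavily overlapping droplets whose
  joint mask has a single distance-transform peak.
- The hyperbolic FRAP model has no reaction/binding term; systems with
  exchange-dominated recovery need a different model.
- The default rotor curve assumes a single power law across the calibrated
  range; strongly non-Förster–Hoffmann dyes should use the monotone-spline
  form (`fit_rotor_curve(..., form="spline")`), which reproduces the
  standards exactly but cannot extrapolate meaningfully beyond them.
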