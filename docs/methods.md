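# Methods

This note documents the physical model, the numerical choices and the
limits of validity of the `eict` toolkit, in the spirit of the model
documentation that simulation packages ship alongside their API reference.

## Optical model

The chain is a point-projection geometry: source → sample mask (69 cm) →
sample (+3 cm) → detector mask (84 cm) → detector (86 cm). Lengths transform
between planes by the ratio of source distances; the sample-mask→sample
magnification m_s = (69+3)/69 ≈ 1.043 and the sample→detector magnification
M = 86/72 ≈ 1.194 follow from the configured distances. The instrument this
configuration describes quotes m_s = 1.06; since that value is inconsistent
with its printed distances, the toolkit derives m_s from the distances and
exposes `m_s_override` for users who want to pin the quoted number — the
discrepancy is surfaced, not silently reconciled.

The spectrum is collapsed onto an effective monochromatic energy
(default 18 keV, λ[Å] = 12.398/E[keV]); polychromatic effects
(beam hardening, energy-dependent δ/β) are out of scope. The source focal
spot is modelled as a horizontal Gaussian (FWHM 70 μm at the source,
geometrically projected). Vertical blur is ignored: the slit geometry makes
the physics one-dimensional per axial row, and the toolkit simulates a
single row (one axial slice).

### Illumination curve

Each sample-mask aperture produces a top-hat beamlet; at the detector-mask
plane it has width w·(84/69) and is convolved with the projected source
penumbra (σ = FWHM/2.355 × (84−69)/69). The detected rate versus mask offset
is the overlap of that profile with the detector-mask windows, summed over
neighbouring periods. The overlap has a closed form in
G(t) = t·Φ(t) + φ(t) (the antiderivative of the normal CDF); the test suite
checks it against a brute-force double quadrature at random offsets
(<0.1%). The model is exactly periodic in the detector-mask period referred
to the sample-mask plane. Circular apertures are treated as slits of equal
width for the curve shape; their reduced open area is a separate flux factor
(π(d/2)²/(p·h) with h the effective vertical pixel height, default 40 μm).

Aperture transmission is binary (septa transmission defaults to 0); a
nonzero sample-mask septa transmission adds a constant background, a nonzero
detector-mask septa transmission lifts the curve floor.

### Working point

`choose_working_point` root-finds C(x) = f·C_max on a cubic-spline
interpolant of the sampled curve, restricted to the requested flank
(default: positive slope, i.e. offsets below the peak; fraction f = 0.5).
The slope C′(x_m) is taken from a differentiated Gaussian fit to the whole
curve — EI curves are near-Gaussian once source blur rounds the
mask-overlap trapezoid — with a spline-derivative fallback
(`slope_method="spline"`) for strongly non-Gaussian curves such as the
zero-blur triangle. A target fraction of exactly 1 is rejected: the peak has
zero slope and is not a usable working point.

## Forward model

Detection follows the geometric EI signal model: per beamlet,
I = exposure · exp(−2k∫β dz) · C(x_m − z_od·g), with g the transverse
gradient of the projected δ. Projections are computed by rotating the maps
(bilinear, matching the radon/iradon convention of scikit-image) and summing
columns; gradients by central differences on the voxel-pitch projection.
Positions outside the phantom support are vacuum.

The default detection mode averages the full integrand over the beamlet
footprint on the sample — the aperture top-hat (w·m_s) convolved with the
projected source penumbra, sampled at 9 quadrature points. This averaging is
what makes resolution aperture-driven; a `center` mode evaluates the
integrand at the beamlet centre only (the rigid-shift linearization, useful
for analytic checks). C(·) is shared between simulation and retrieval by
default; mismatched curves can be injected for robustness studies. Arguments
outside the measured curve support are clamped and counted.

The curve argument follows the signal model literally: the refraction shift
z_od·g is applied in the same coordinate as the sample-mask offset. Forward
simulation and retrieval use the identical convention, so the calibration
C′/C cancels consistently.

Poisson noise is seeded per frame from (master seed, angle, offset), a
counter-style scheme that makes the realisation independent of trajectory
ordering. Dark frames carry a configurable offset level (default 0).

## Sampling schemes

N_dith = ⌈p/w⌉ sub-period steps fully sample one period (4/8/16 for the
20/10/5 μm bands at p = 79 μm). Because p/w is not an integer for any of
these bands, steps of exactly w·m_s cannot tile the projected period; the
toolkit defines the dither step as **p·m_s/N_dith** (19.75/9.875/4.9375 μm
at the mask; ×m_s at the sample plane) so that interleaved samples land on
an exactly uniform grid. This idealization differs from the nominal
aperture-width shift by <1.3% and keeps every downstream grid uniform.

Dithered scans draw a per-angle random jitter, quantized to whole dither
steps over one period, and store the draw table; assembly reverses it
exactly, which is the point — sub-step jitter would need interpolation and
is out of scope. Cycloidal type 1 advances one dither step per angular
increment at N_base×N_dith angles; type 2 advances further (e.g. 28 μm×m_s)
at fewer angles. Both fold the translation back and forth over 10 projected
periods by default (configurable) so the field of view is not consumed;
the usable lateral extent of a cycloidal sinogram shrinks by the span.

Scan duration is Σ exposure for fly scans; step-and-shoot adds
overhead_per_step × n_steps with the overhead a free parameter — published
step-and-shoot totals fold in motor overheads that are instrument-specific,
so the toolkit does not pretend to predict them.

## Assembly

Flat/dark correction computes (I−dark)/(flat−dark) per exposure-normalised
frame, with linear interpolation between flats when positions are given
(validated on a constructed 2% linear drift). Dithered interleaving places
each beamlet sample at its exact grid cell (all offsets are integer dither
steps by construction); jittered edge cells that end up unsampled are filled
with the vacuum value 1.0 and counted. Negative normalized intensities
(possible under noise) are clipped to 0 and counted.

Cycloidal regridding exploits the grid structure: type-1 samples lie exactly
on the lateral grid, so each lateral column is interpolated along the angle
axis with a cubic spline on a ±360°-tiled (hence wrapping) angle coordinate —
a shear-aligned separable scheme. Type-2 offsets are incommensurate with the
grid, so those scans use Clough–Tocher (cubic) scattered interpolation in
(angle, lateral) space with the same angular tiling and nearest-sample
fallback at the hull edge. Duplicate samples at back-and-forth turnarounds
are averaged and counted. The target grid defaults to the dithered
equivalent (N_base angles × dither-step pitch), including for type 2, where
the pitch oversamples the data — a documented choice rather than a claim
about information content.

## Retrieval and reconstruction

The single-image filter divides each row's spectrum by
1 + i·2πν·z_od·(C′/C)·γ, with ν the frequency conjugate to the lateral
coordinate. The sign of the iν term follows from the forward shift
C(x_m − z_od·g) and numpy's FFT convention (F(∂x f) = +i2πν F(f)); the
magnitude, 1/√(1+(2πν z_od (C′/C) γ)²) ≤ 1, is a pure low-pass either way.
γ = δ/(2kβ) carries units of metres in this convention. Rows are padded
symmetrically to twice their width before the FFT and cropped after.
With γ = 0 the filter is the identity and the output is −log(I/I0)/(2k).
Non-positive filtered intensities abort with a pixel report rather than
producing silent NaNs. On data generated by the linearized forward model the
filter is an exact inverse (verified to ~1e−12 relative RMSE); on the full
nonlinear simulation of a matched single-material cylinder the interior β is
recovered to well under 5% relative RMSE.

FBP delegates to `skimage.transform.iradon` (Ram-Lak ramp filter, linear
back-projection interpolation, 360° data averaged over conjugate views by
the standard 1/(2N) weighting) after zero-padding the sinogram laterally so
the rotation axis sits at the back projector's centre index. Slices are in β
units (line integrals divided by the pixel size = sinogram pitch); μ = 2kβ
is available as a helper.

Modulation analysis averages the reconstructed slice along the bar
direction inside each group's bounding box and reads the profile at the bar
and gap centres known from the phantom metadata:
(mean peak − mean trough)/(mean peak + mean trough), clipped at 0. For bars
embedded in a substrate the ideal value is the material contrast (0.33 for
the default densities), not 1; comparisons across aperture bands are
therefore made per frequency, not against an absolute scale.

## Synthetic data

The phantom factory emulates two study objects. The bar phantom mimics a
resolution chip: groups of equal bars and gaps (50% duty cycle) from 5 μm
upward, embedded in a cylinder; bars are a denser version of the substrate
material so γ is constant exactly and retrieval mismatch does not confound
resolution measurements. Rasterization uses pixel-centre sampling at 4×
supersampling with box down-averaging. The soft-tissue phantom is a seeded
sum of Gaussian blobs on a cylindrical background with δ := 2kγβ, which
satisfies the homogeneity assumption to machine precision. Default optical
constants (δ = 8e−7, β = 1.6e−9 for the substrate) are configuration
choices, selected to keep projection transmission within (0.1, 0.9) for
~1 mm objects at 18 keV — they are plausible for soft condensed matter but
are not tabulated material data.

What the synthetic data does *not* contain: mask fabrication defects,
detector cross-talk and scintillator blur, polychromatic hardening, motor
positioning errors, sample drift. Passing tests therefore demonstrate the
correctness and internal consistency of the sampling/retrieval chain, not
robustness of a real instrument to those effects.

## Problem sizes and benchmarks

The test suite runs at desk scale, chosen so the full suite completes in a
few minutes on one CPU: the resolution experiment uses a ~900² phantom at
1.25 μm voxels with bands 5/10/20 μm, 240 angles over 360° and 5 bars per
group; the retrieval round trip uses a 256² phantom at 400 angles; cycloidal
comparisons use 120 base angles with a 3-period back-and-forth span. At
these sizes the aperture-ordering property (modulation non-increasing with
aperture width at every bar frequency) and the <2% cyc1 fidelity hold with
margin.

The denoising benchmark runs on a pure absorber with the identity (γ = 0)
retrieval: ramp-filtered Poisson noise is broadband, the regime where a
local learned kernel is effective (the default 7–9 pixel ridge-regression
kernel gains ~4× SNR). After phase retrieval with a realistic γ the noise
is strongly low-pass-correlated and a small convolution kernel removes much
less of it — a real property of EI data, documented here so users do not
mistake it for a harness defect. Heavier denoisers (U-Net-class) plug into
the same fit/apply contract; training at instrument scale is out of scope.

## Known limitations

- Geometric optics only: no free-space propagation fringes, no coherence
  effects; valid in the regime where the EI signal model itself holds.
- One axial row: vertical structure, cone-beam divergence and row cross-talk
  are not modelled (parallel-beam approximation at M ≈ 1.2).
- The illumination curve is simulated per-beamlet with an ideally aligned
  detector window; period mismatch across a wide field (79·86/69 = 98.46 μm
  vs the 98 μm detector mask) is not accumulated.
- Circular-aperture bands affect flux, not curve shape.
- Sub-step (non-quantized) jitter is unsupported by design.
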