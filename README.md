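# eict — edge-illumination phase-contrast micro-CT toolkit

`eict` simulates and reconstructs **edge-illumination (EI) x-ray
phase-contrast micro-CT** with *aperture-driven, adjustable in-slice
resolution*. It is aimed at instrument developers and imaging scientists who
want to study EI sampling schemes, mask designs and retrieval settings
without beam time: everything from the refractive-index phantom to the
reconstructed slice is computed on a laptop.

In EI, a *sample mask* (period p, aperture width w) splits the beam into
narrow beamlets and a *detector mask* places absorbing edges in front of the
pixel columns. Refraction in the sample shifts each beamlet across its edge,
so intensity encodes the local phase gradient. The detected signal per
beamlet is

```
I(x, y) = I0 · exp(−2k ∫ β dz) · C( x_m − z_od · ∂/∂x ∫ δ dz )
```

where n = 1 − δ + iβ is the complex refractive index, k the wave number,
z_od the sample–detector distance, and C(·) the *illumination curve* —
detected intensity versus lateral mask offset, measured without a sample.
Imaging is done at a working point x_m where C is ≈50% of its maximum
(steepest slope). For a quasi-homogeneous object with
γ = δ/(2kβ) = const, a single Fourier filter retrieves the projected
absorption from one intensity image:

```
∫ β dz = −(1/2k) · log( F⁻¹[ F(I/I0) / (1 + i·2πν·z_od·(C′(x_m)/C(x_m))·γ) ] )
```

after which standard filtered back projection (Ram-Lak) gives axial slices
of β. Because each measurement averages the sample only over the beamlet
footprint (~w·m_s), the in-slice resolution follows the **aperture width**,
not the source or detector blur — swapping a 20 μm mask band for a 5 μm band
sharpens the image at constant magnification and field of view.

The toolkit covers the full chain:

- **system model** — geometry, multi-band masks, illumination-curve
  simulation (closed-form beamlet/mask overlap), working-point selection,
  open-area flux accounting;
- **phantom factory** — bar-pattern resolution chips and single-material
  soft-tissue blob phantoms (γ constant by construction);
- **forward simulator** — beamlet-sampled attenuation + refraction with
  optional Poisson noise, seeded per frame;
- **acquisition** — dithered step-and-shoot schedules (with reversible
  random jitter), cycloidal type-1/type-2 fly scans, scan-time accounting;
- **sinogram assembly** — flat/dark correction, dither interleaving with
  exact jitter reversal, cubic regridding of cycloidal samples;
- **retrieval & reconstruction** — the single-image filter above, FBP,
  bar-modulation analysis;
- **denoising harness** — odd/even projection splits and a pluggable
  denoiser contract (default: closed-form convolutional ridge regression).

## Worked example

```bash
python examples/01_illumination_curve.py
```

```
        band      C_max   x_m (um)   C/Cmax    C' (1/um)
  20um_slits     6041.1     -11.16    0.500        387.4
  10um_slits     7498.9      -8.86    0.500        595.7
   5um_slits     7955.0      -8.37    0.500        672.1
```

Each row is one band of the multi-band sample mask: `C_max` is the peak
detected rate per beamlet (narrow beamlets fit the 17 μm detector-mask
window better, so their *transmitted fraction* is higher even though their
absolute flux is lower), `x_m` the automatically selected 50% working point
on the positive-slope flank, and `C'` the slope there — the refraction
sensitivity used by the retrieval filter.

`python examples/02_aperture_resolution.py` then scans a bar phantom end to
end with the 20 μm and 10 μm bands and prints the per-frequency modulation,
showing it rise toward the ideal bar/substrate contrast (0.33) as the
apertures narrow; `03` reproduces the fly-scan time budget (48 min for the
type-1 scan that replaces a 2.5 h dithered scan) and `04` demonstrates the
self-supervised denoising path (~4× SNR gain with no clean targets).

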