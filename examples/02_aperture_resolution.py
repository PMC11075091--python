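"""Aperture-driven resolution: scan a bar phantom with two mask bands.

The same bar-pattern phantom is scanned end to end (forward simulation,
sinogram assembly, phase retrieval, filtered back projection) with 20 um and
10 um slit apertures at identical magnification. The bar modulation
(peak-trough contrast, ideal value 0.33 for these materials) improves with
the narrower apertures at every spatial frequency — resolution is set by the
aperture width, not the source or detector.

Runs in roughly a minute on one CPU.
"""

import numpy as np

from eict import (
    AcquisitionSettings,
    RetrievalSettings,
    bar_pattern_phantom,
    choose_working_point,
    dithered_trajectory,
    fbp_reconstruct,
    flat_dark_correct,
    interleave_dithered,
    load_config,
    modulation_analysis,
    phase_retrieve,
    simulate_illumination_curve,
    simulate_scan,
)

cfg = load_config()
g, det = cfg.geometry, cfg.detector
phantom = bar_pattern_phantom([10e-6, 20e-6, 30e-6], voxel_size=2.5e-6)
gamma = float(np.nanmean(phantom.gamma_map()))
settings = AcquisitionSettings(i0_rate=1e4)

results = {}
for name in ("20um_slits", "10um_slits"):
    band = cfg.band(name)
    curve = simulate_illumination_curve(g, band, det, i0_rate=1e4)
    wp = choose_working_point(curve, cfg.working_point_fraction, cfg.flank)
    traj = dithered_trajectory(200, band, g)
    fs = simulate_scan(g, band, phantom, traj, wp, curve, settings)
    sino = interleave_dithered(flat_dark_correct(fs), traj, band, g)
    tb = phase_retrieve(sino, RetrievalSettings.from_system(g, wp, gamma))
    rec = fbp_reconstruct(tb)
    results[name] = modulation_analysis(rec, phantom.meta["bar_groups"])

print(f"{'bar width':>10} {'lp/mm':>7} {'20um band':>10} {'10um band':>10}")
for m20, m10 in zip(results["20um_slits"], results["10um_slits"]):
    print(
        f"{m20['width_um']:>8.0f} um {m20['frequency_lp_mm']:7.2f} "
        f"{m20['modulation']:10.3f} {m10['modulation']:10.3f}"
    )
print(
    "\nModulation rises toward the ideal 0.33 as the aperture narrows;"
    "\nbars below the aperture width stay washed out."
)
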