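"""Image formation: projections, refraction gradients, frame detection."""

import numpy as np
import pytest

from eict import (
    AcquisitionSettings,
    OpticalMap,
    beamlet_positions,
    detect_frame,
    dithered_trajectory,
    projected_attenuation,
    refraction_gradient,
    simulate_scan,
)

VOX = 4e-6
N = 200


def slab_map(beta=2e-9, delta=0.0, rows=(80, 120)):
    """Uniform horizontal slab spanning the full width."""
    b = np.zeros((N, N))
    d = np.zeros((N, N))
    b[rows[0] : rows[1], :] = beta
    d[rows[0] : rows[1], :] = delta
    return OpticalMap(delta=d, beta=b, voxel_size=VOX)


class TestProjectedAttenuation:
    def test_vacuum_is_zero(self):
        omap = OpticalMap(delta=np.zeros((N, N)), beta=np.zeros((N, N)), voxel_size=VOX)
        pos = np.linspace(-300e-6, 300e-6, 31)
        assert np.all(projected_attenuation(omap, 33.0, pos) == 0.0)

    def test_uniform_slab_normal_incidence(self):
        beta = 2e-9
        omap = slab_map(beta=beta, rows=(80, 120))
        t = 40 * VOX
        pos = np.linspace(-200e-6, 200e-6, 21)
        proj = projected_attenuation(omap, 0.0, pos)
        assert np.allclose(proj, beta * t, rtol=1e-9)

    def test_rotated_square_against_closed_form(self):
        # axis-aligned square of side L at view angle 30 deg: the projection
        # is a trapezoid with plateau beta*L/cos(theta) and mass beta*L^2
        beta = 3e-9
        L_px = 60
        L = L_px * VOX
        b = np.zeros((N, N))
        b[70 : 70 + L_px, 70 : 70 + L_px] = beta
        omap = OpticalMap(delta=np.zeros((N, N)), beta=b, voxel_size=VOX)
        xs = (np.arange(N) - (N - 1) / 2) * VOX
        proj = projected_attenuation(omap, 30.0, xs)
        mass = np.trapezoid(proj, xs)
        assert mass == pytest.approx(beta * L * L, rel=5e-3)
        theta = np.deg2rad(30.0)
        # plateau sampled well inside its support (centre of the projection)
        centre = xs[np.argmax(proj)]
        plateau = proj[np.abs(xs - centre) < 0.1 * L]
        assert np.allclose(plateau, beta * L / np.cos(theta), rtol=5e-3)

    def test_outside_support_treated_as_vacuum(self):
        omap = slab_map()
        val = projected_attenuation(omap, 0.0, np.array([10.0]))  # 10 m off-axis
        assert val[0] == 0.0


class TestRefractionGradient:
    def test_uniform_slab_interior_zero(self):
        omap = slab_map(beta=0.0, delta=1e-6, rows=(80, 120))
        pos = np.linspace(-150e-6, 150e-6, 11)
        g = refraction_gradient(omap, 0.0, pos)
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_wedge_constant_gradient(self):
        # delta linear in x over a slab of thickness t: gradient = slope * t
        slope = 1.0  # per metre of x, dimensionless delta
        rows = (60, 140)
        t = (rows[1] - rows[0]) * VOX
        xs = (np.arange(N) - (N - 1) / 2) * VOX
        d = np.zeros((N, N))
        d[rows[0] : rows[1], :] = 2e-6 + slope * 1e-3 * xs[None, :] * 1.0
        d = np.clip(d, 0, None)
        omap = OpticalMap(delta=d, beta=np.zeros((N, N)), voxel_size=VOX)
        pos = np.linspace(-100e-6, 100e-6, 9)
        g = refraction_gradient(omap, 0.0, pos)
        assert np.allclose(g, slope * 1e-3 * t, rtol=1e-6)

    def test_cylinder_antisymmetric_zero_at_centre(self):
        from eict import cylinder_phantom

        omap = cylinder_phantom(radius=200e-6, shape=N, voxel_size=VOX)
        pos = np.linspace(-150e-6, 150e-6, 31)
        g = refraction_gradient(omap, 0.0, pos)
        assert abs(g[15]) < 1e-3 * np.abs(g).max()
        assert np.allclose(g, -g[::-1], atol=1e-2 * np.abs(g).max())


class TestDetectFrame:
    def test_flat_field_no_sample(self, geom, band20, curve_wp, settings_clean):
        curve, wp = curve_wp("20um_slits")
        fr = detect_frame(
            geom, band20, None, 0.0, 0.0, wp, curve, settings_clean,
            exposure=2.0, n_beamlets=8,
        )
        assert fr.kind == "flat"
        assert np.allclose(fr.intensities, 2.0 * wp.c_xm)

    def test_pure_absorber_scales_flat_by_beer_lambert(
        self, geom, band20, curve_wp, settings_clean
    ):
        curve, wp = curve_wp("20um_slits")
        beta, rows = 2e-9, (80, 120)
        omap = slab_map(beta=beta, rows=rows)
        fr = detect_frame(geom, band20, omap, 0.0, 0.0, wp, curve, settings_clean)
        t = (rows[1] - rows[0]) * VOX
        expected = wp.c_xm * np.exp(-2 * omap.k * beta * t)
        assert np.allclose(fr.intensities, expected, rtol=1e-9)
        # round trip: -log(I/flat) = 2k * projected attenuation
        assert np.allclose(
            -np.log(fr.intensities / wp.c_xm), 2 * omap.k * beta * t, rtol=1e-9
        )

    def test_wedge_shifts_working_point_along_curve(
        self, geom, band20, curve_wp, settings_clean
    ):
        curve, wp = curve_wp("20um_slits")
        slope_per_m = 2.0e-3
        rows = (60, 140)
        t = (rows[1] - rows[0]) * VOX
        xs = (np.arange(N) - (N - 1) / 2) * VOX
        d = np.zeros((N, N))
        d[rows[0] : rows[1], :] = 1e-5 + slope_per_m * xs[None, :]
        omap = OpticalMap(delta=np.clip(d, 0, None), beta=np.zeros((N, N)), voxel_size=VOX)
        fr = detect_frame(geom, band20, omap, 0.0, 0.0, wp, curve, settings_clean)
        g = slope_per_m * t
        expected = curve(wp.x_m - geom.z_od * g)
        inner = slice(1, -1)  # edge beamlets clip the wedge boundary
        assert np.allclose(fr.intensities[inner], expected, rtol=1e-6)

    def test_period_shift_reproduces_frame_on_invariant_phantom(
        self, geom, band20, curve_wp, settings_clean
    ):
        curve, wp = curve_wp("20um_slits")
        omap = slab_map(beta=2e-9, delta=1e-6)
        period = band20.period * geom.m_s
        f0 = detect_frame(geom, band20, omap, 0.0, 0.0, wp, curve, settings_clean)
        f1 = detect_frame(geom, band20, omap, 0.0, period, wp, curve, settings_clean)
        # interior beamlets see an identical sample strip one period over
        assert np.allclose(f0.intensities[1:-1], f1.intensities[2:], rtol=1e-12)

    def test_exposure_linearity(self, geom, band20, curve_wp, settings_clean):
        curve, wp = curve_wp("20um_slits")
        omap = slab_map(beta=2e-9)
        f1 = detect_frame(geom, band20, omap, 10.0, 0.0, wp, curve, settings_clean, exposure=1.0)
        f2 = detect_frame(geom, band20, omap, 10.0, 0.0, wp, curve, settings_clean, exposure=2.0)
        assert np.allclose(f2.intensities, 2 * f1.intensities, rtol=1e-12)


class TestSimulateScan:
    def test_single_entry_plus_flats_darks(self, geom, band20, curve_wp, settings_clean):
        curve, wp = curve_wp("20um_slits")
        omap = slab_map()
        traj = dithered_trajectory(1, band20, geom)
        traj.angles_deg = traj.angles_deg[:1]
        traj.offsets = traj.offsets[:1]
        traj.exposures = traj.exposures[:1]
        fs = simulate_scan(
            geom, band20, omap, traj, wp, curve, settings_clean, n_flats=2, n_darks=1
        )
        assert len(fs.of_kind("sample")) == 1
        assert len(fs.of_kind("flat")) == 2
        assert len(fs.of_kind("dark")) == 1

    def test_noise_free_rerun_bit_identical(self, geom, band20, curve_wp, settings_clean):
        curve, wp = curve_wp("20um_slits")
        omap = slab_map()
        traj = dithered_trajectory(3, band20, geom, jitter_seed=1)
        a = simulate_scan(geom, band20, omap, traj, wp, curve, settings_clean)
        b = simulate_scan(geom, band20, omap, traj, wp, curve, settings_clean)
        assert np.array_equal(a.stack(), b.stack())

    def test_poisson_seeding_determinism(self, geom, band20, curve_wp):
        curve, wp = curve_wp("20um_slits")
        omap = slab_map(beta=0.0)
        traj = dithered_trajectory(2, band20, geom)
        settings = AcquisitionSettings(i0_rate=1e4, noise="poisson", seed=42)
        fs = simulate_scan(geom, band20, omap, traj, wp, curve, settings, n_flats=3)
        fs2 = simulate_scan(geom, band20, omap, traj, wp, curve, settings, n_flats=3)
        assert np.array_equal(fs.stack(), fs2.stack())
        settings3 = AcquisitionSettings(i0_rate=1e4, noise="poisson", seed=43)
        fs3 = simulate_scan(geom, band20, omap, traj, wp, curve, settings3, n_flats=3)
        assert not np.array_equal(fs.stack("flat"), fs3.stack("flat"))

    def test_poisson_relative_std_one_percent(self, geom, band20, curve_wp):
        curve, wp = curve_wp("20um_slits")
        traj = dithered_trajectory(1, band20, geom)
        settings = AcquisitionSettings(i0_rate=1e4, noise="poisson", seed=7)
        exposure = 1.0e4 / wp.c_xm
        frames = [
            detect_frame(
                geom, band20, None, 0.0, 0.0, wp, curve, settings,
                exposure=exposure, n_beamlets=12, noise_tag=i,
            )
            for i in range(120)
        ]
        counts = np.stack([f.intensities for f in frames])
        rel_std = (counts / counts.mean()).std()
        assert counts.size >= 1e3
        assert rel_std == pytest.approx(0.01, rel=0.10)

    def test_empty_trajectory_rejected(self, geom, band20, curve_wp, settings_clean):
        from eict import Trajectory

        curve, wp = curve_wp("20um_slits")
        omap = slab_map()
        traj = Trajectory(
            angles_deg=np.array([]), offsets=np.array([]), exposures=np.array([]),
            scheme="dithered",
        )
        with pytest.raises(ValueError):
            simulate_scan(geom, band20, omap, traj, wp, curve, settings_clean)
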