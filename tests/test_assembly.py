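"""Sinogram assembly: normalization, interleaving, cycloidal regridding."""

import numpy as np
import pytest

from eict import (
    Frame,
    Sinogram,
    beamlet_positions,
    cycloidal_type1_trajectory,
    cycloidal_type2_trajectory,
    dithered_trajectory,
    flat_dark_correct,
    interleave_dithered,
    regrid_cycloidal,
    simulate_scan,
    soft_tissue_phantom,
)


def make_frame(values, angle, offset):
    return Frame(
        intensities=np.asarray(values, float),
        angle_deg=float(angle),
        lateral_offset=float(offset),
        exposure=1.0,
    )


def synth_frames(traj, n_beamlets, band, geom, func):
    """Frames whose beamlet values sample func(angle_deg, x_sample_frame)."""
    pitch = band.period * geom.m_s
    xb = (np.arange(n_beamlets) - (n_beamlets - 1) / 2.0) * pitch
    out = []
    for a, o in zip(traj.angles_deg, traj.offsets):
        out.append(make_frame(func(a, xb - o), a, o))
    return out


class TestFlatDarkCorrect:
    def test_frame_equal_flat_gives_one(self):
        flat = make_frame([10, 20, 30], 0, 0)
        dark = make_frame([1, 2, 3], 0, 0)
        sample = make_frame([10, 20, 30], 0, 0)
        out = flat_dark_correct([sample], [flat], [dark])
        assert np.allclose(out[0].intensities, 1.0)

    def test_frame_equal_dark_gives_zero(self):
        flat = make_frame([10, 20, 30], 0, 0)
        dark = make_frame([1, 2, 3], 0, 0)
        sample = make_frame([1, 2, 3], 0, 0)
        out = flat_dark_correct([sample], [flat], [dark])
        assert np.allclose(out[0].intensities, 0.0)

    def test_drifting_flats_restored_by_interpolation(self):
        # 2% linear illumination drift across the scan, flats at both ends
        n = 50
        base = np.full(8, 100.0)
        dark = make_frame(np.zeros(8), 0, 0)
        samples = [make_frame(base * (1 + 0.02 * i / (n - 1)), i, 0) for i in range(n)]
        flats = [
            make_frame(base, 0, 0),
            make_frame(base * 1.02, 0, 0),
        ]
        out = flat_dark_correct(samples, flats, [dark], flat_positions=[0, n - 1])
        vals = np.stack([f.intensities for f in out])
        assert np.allclose(vals, 1.0, atol=0.002)

    def test_flat_not_above_dark_rejected(self):
        flat = make_frame([10, 1, 30], 0, 0)
        dark = make_frame([1, 2, 3], 0, 0)
        with pytest.raises(ValueError, match="pixel"):
            flat_dark_correct([make_frame([5, 5, 5], 0, 0)], [flat], [dark])

    def test_exposure_normalized(self):
        flat = Frame(intensities=np.array([200.0]), angle_deg=0, lateral_offset=0, exposure=2.0, kind="flat")
        dark = Frame(intensities=np.array([0.0]), angle_deg=0, lateral_offset=0, exposure=1.0, kind="dark")
        sample = Frame(intensities=np.array([50.0]), angle_deg=0, lateral_offset=0, exposure=0.5)
        out = flat_dark_correct([sample], [flat], [dark])
        assert out[0].intensities[0] == pytest.approx(1.0)


class TestInterleave:
    def test_uniform_phantom_gives_constant_sinogram(self, geom, band20):
        traj = dithered_trajectory(4, band20, geom)
        frames = synth_frames(traj, 6, band20, geom, lambda a, x: np.full_like(x, 0.7))
        sino = interleave_dithered(frames, traj, band20, geom)
        assert np.allclose(sino.values, 0.7)
        assert sino.values.shape == (4, 24)
        d = np.diff(sino.lateral)
        assert np.allclose(d, traj.step)

    def test_jitter_reversal_restores_unjittered_sinogram(
        self, geom, band20, curve_wp, settings_clean
    ):
        curve, wp = curve_wp("20um_slits")
        # phantom kept clear of the jitter margin (one period at each edge)
        ph = soft_tissue_phantom(seed=2, shape=160, voxel_size=4e-6, radius_fraction=0.25)
        t_plain = dithered_trajectory(8, band20, geom)
        t_jit = dithered_trajectory(8, band20, geom, jitter_seed=99)
        assert t_jit.jitter_steps.max() > 0
        fs_p = simulate_scan(geom, band20, ph, t_plain, wp, curve, settings_clean)
        fs_j = simulate_scan(geom, band20, ph, t_jit, wp, curve, settings_clean)
        s_p = interleave_dithered(flat_dark_correct(fs_p), t_plain, band20, geom)
        s_j = interleave_dithered(flat_dark_correct(fs_j), t_jit, band20, geom)
        assert np.allclose(s_p.values, s_j.values, rtol=1e-12)

    def test_missing_frame_reported(self, geom, band20):
        traj = dithered_trajectory(2, band20, geom)
        frames = synth_frames(traj, 4, band20, geom, lambda a, x: np.ones_like(x))
        with pytest.raises(ValueError, match="missing"):
            interleave_dithered(frames[:-1], traj.__class__(
                angles_deg=traj.angles_deg[:-1],
                offsets=traj.offsets[:-1],
                exposures=traj.exposures[:-1],
                scheme="dithered",
                n_dith=traj.n_dith,
                step=traj.step,
            ), band20, geom)

    def test_off_centre_rod_traces_sinusoid(self, geom, band10, curve_wp, settings_clean):
        import numpy as np

        curve, wp = curve_wp("10um_slits")
        n, vox = 192, 4e-6
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        x0, y0 = 120e-6, 80e-6
        r = np.hypot((xx - c) * vox - x0, (yy - c) * vox - y0)
        beta = np.where(r < 15e-6, 2e-9, 0.0)
        from eict import OpticalMap

        ph = OpticalMap(delta=beta * 500.0, beta=beta, voxel_size=vox)
        traj = dithered_trajectory(24, band10, geom)
        fs = simulate_scan(geom, band10, ph, traj, wp, curve, settings_clean)
        sino = interleave_dithered(flat_dark_correct(fs), traj, band10, geom)
        att = np.clip(-np.log(np.clip(sino.values, 1e-9, None)), 0.0, None)
        # centroid of the absorption trace per angle (refraction lobes clipped)
        w = att / att.sum(axis=1, keepdims=True)
        trace = w @ sino.lateral
        th = np.deg2rad(sino.angles_deg)
        # rows increase downward, so the trace is x0*cos - y0*sin
        expected = x0 * np.cos(th) - y0 * np.sin(th)
        assert np.max(np.abs(trace - expected)) < 1.5 * sino.pitch

    def test_sinogram_mass_conserved_over_angles(
        self, geom, band20, curve_wp, settings_clean
    ):
        curve, wp = curve_wp("20um_slits")
        ph = soft_tissue_phantom(seed=4, shape=160, voxel_size=4e-6, radius_fraction=0.28)
        traj = dithered_trajectory(12, band20, geom)
        fs = simulate_scan(geom, band20, ph, traj, wp, curve, settings_clean)
        sino = interleave_dithered(flat_dark_correct(fs), traj, band20, geom)
        mass = (-np.log(np.clip(sino.values, 1e-9, None))).sum(axis=1)
        assert mass.std() / mass.mean() < 0.01


class TestRegrid:
    def test_constant_function_exact(self, geom, band20):
        traj = cycloidal_type1_trajectory(10, band20, geom, span_periods=2)
        frames = synth_frames(traj, 8, band20, geom, lambda a, x: np.full_like(x, 0.55))
        sino = regrid_cycloidal(frames, traj, band20, geom)
        assert np.allclose(sino.values, 0.55, atol=1e-12)

    def test_linear_in_offset_exact(self, geom, band20):
        traj = cycloidal_type1_trajectory(10, band20, geom, span_periods=2)
        frames = synth_frames(
            traj, 8, band20, geom, lambda a, x: 1.0 + 200.0 * x
        )
        sino = regrid_cycloidal(frames, traj, band20, geom)
        expected = 1.0 + 200.0 * sino.lateral[None, :]
        assert np.allclose(sino.values, expected, atol=1e-10)

    def test_smooth_periodic_in_angle_accurate(self, geom, band20):
        traj = cycloidal_type1_trajectory(60, band20, geom, span_periods=2)
        f = lambda a, x: 1.0 + 0.3 * np.sin(np.deg2rad(a)) + 100.0 * x
        frames = synth_frames(traj, 8, band20, geom, f)
        sino = regrid_cycloidal(frames, traj, band20, geom)
        expected = (
            1.0
            + 0.3 * np.sin(np.deg2rad(sino.angles_deg))[:, None]
            + 100.0 * sino.lateral[None, :]
        )
        assert np.max(np.abs(sino.values - expected)) < 1e-4

    def test_cyc1_matches_dithered_within_2pct(
        self, geom, band20, curve_wp, settings_clean
    ):
        curve, wp = curve_wp("20um_slits")
        ph = soft_tissue_phantom(seed=6, shape=256, voxel_size=4e-6, radius_fraction=0.33)
        n_base = 90
        t_d = dithered_trajectory(n_base, band20, geom)
        fs_d = simulate_scan(geom, band20, ph, t_d, wp, curve, settings_clean)
        s_d = interleave_dithered(flat_dark_correct(fs_d), t_d, band20, geom)
        t_c = cycloidal_type1_trajectory(n_base, band20, geom, span_periods=3)
        fs_c = simulate_scan(geom, band20, ph, t_c, wp, curve, settings_clean)
        s_c = regrid_cycloidal(flat_dark_correct(fs_c), t_c, band20, geom)
        sel = np.isin(np.round(s_d.lateral * 1e9), np.round(s_c.lateral * 1e9))
        rmse = np.sqrt(np.mean((s_d.values[:, sel] - s_c.values) ** 2))
        assert rmse / np.sqrt(np.mean(s_d.values[:, sel] ** 2)) < 0.02

    def test_cyc2_reduces_high_frequency_content(
        self, geom, band20, curve_wp, settings_clean
    ):
        curve, wp = curve_wp("20um_slits")
        ph = soft_tissue_phantom(seed=8, shape=256, voxel_size=4e-6, radius_fraction=0.33)
        n_fine = 240
        t1 = cycloidal_type1_trajectory(n_fine // 4, band20, geom, span_periods=3)
        fs1 = simulate_scan(geom, band20, ph, t1, wp, curve, settings_clean)
        s1 = regrid_cycloidal(flat_dark_correct(fs1), t1, band20, geom)
        t2 = cycloidal_type2_trajectory(
            n_fine // 4, 28e-6 * geom.m_s, band20, geom, span_periods=3
        )
        fs2 = simulate_scan(geom, band20, ph, t2, wp, curve, settings_clean)
        s2 = regrid_cycloidal(
            flat_dark_correct(fs2), t2, band20, geom, target_angles=s1.angles_deg
        )
        sel = np.isin(np.round(s1.lateral * 1e9), np.round(s2.lateral * 1e9))
        spec1 = np.abs(np.fft.rfft(s1.values[:, sel] - 1.0, axis=1)) ** 2
        spec2 = np.abs(np.fft.rfft(s2.values - 1.0, axis=1)) ** 2
        hi = spec1.shape[1] // 2
        assert spec2[:, hi:].mean() < spec1[:, hi:].mean()

    def test_wrong_scheme_rejected(self, geom, band20):
        traj = dithered_trajectory(2, band20, geom)
        frames = synth_frames(traj, 4, band20, geom, lambda a, x: np.ones_like(x))
        with pytest.raises(ValueError):
            regrid_cycloidal(frames, traj, band20, geom)

    def test_span_exceeding_coverage_rejected(self, geom, band20):
        traj = cycloidal_type1_trajectory(4, band20, geom, span_periods=10)
        frames = synth_frames(traj, 4, band20, geom, lambda a, x: np.ones_like(x))
        with pytest.raises(ValueError, match="span"):
            regrid_cycloidal(frames, traj, band20, geom)


class TestSinogramType:
    def test_axes_must_be_uniform(self):
        with pytest.raises(ValueError):
            Sinogram(
                values=np.ones((3, 4)),
                angles_deg=np.array([0.0, 10.0, 15.0]),
                lateral=np.arange(4) * 1e-6,
            )

    def test_negative_values_rejected_unless_signed(self):
        with pytest.raises(ValueError):
            Sinogram(
                values=-np.ones((2, 2)),
                angles_deg=np.array([0.0, 180.0]),
                lateral=np.arange(2) * 1e-6,
            )
        s = Sinogram(
            values=-np.ones((2, 2)),
            angles_deg=np.array([0.0, 180.0]),
            lateral=np.arange(2) * 1e-6,
            signed=True,
        )
        assert s.values.min() == -1
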