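"""From raw frames to rectangular sinograms.

Steps: flat/dark correction, then either dithered interleaving (with exact
reversal of the per-angle random jitter) or cycloidal regridding onto the
dithered-equivalent rectangular grid.

Lateral coordinates are expressed at the sample plane; the sinogram pitch is
one dither step (p·m_s/N_dith). Angles are half-open [0°, 360°) and treated
as periodic during interpolation. Pixel-centre convention, 0-based indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, griddata

from .acquisition import Trajectory
from .forward import Frame, FrameSet, beamlet_positions
from .geometry import MaskBand, SystemGeometry

logger = logging.getLogger(__name__)

__all__ = ["Sinogram", "flat_dark_correct", "interleave_dithered", "regrid_cycloidal"]


@dataclass
class Sinogram:
    """Rectangular (angle × lateral) grid of normalized intensities I/I0."""

    values: np.ndarray  # (n_angles, n_lateral)
    angles_deg: np.ndarray  # uniform, [0, 360)
    lateral: np.ndarray  # m, sample plane, uniform pitch
    scheme: str = ""
    band_name: str = ""
    signed: bool = False  # True for retrieved line integrals (may dip below 0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)
        if self.values.shape != (self.angles_deg.size, self.lateral.size):
            raise ValueError("values grid must be (n_angles, n_lateral)")
        for ax, name in ((self.angles_deg, "angle"), (self.lateral, "lateral")):
            d = np.diff(ax)
            if ax.size > 1 and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6)):
                raise ValueError(f"{name} axis must be strictly monotone and uniform")
        if not self.signed and np.any(self.values < 0):
            raise ValueError("sinogram values must be >= 0")

    @property
    def pitch(self) -> float:
        return float(self.lateral[1] - self.lateral[0]) if self.lateral.size > 1 else 0.0

    def crop_lateral(self, x_min: float, x_max: float) -> "Sinogram":
        sel = (self.lateral >= x_min - 1e-12) & (self.lateral <= x_max + 1e-12)
        return Sinogram(
            values=self.values[:, sel],
            angles_deg=self.angles_deg,
            lateral=self.lateral[sel],
            scheme=self.scheme,
            band_name=self.band_name,
            signed=self.signed,
            meta=dict(self.meta),
        )


def flat_dark_correct(
    frames: FrameSet | list[Frame],
    flats: list[Frame] | None = None,
    darks: list[Frame] | None = None,
    flat_positions: list[int] | None = None,
) -> list[Frame]:
    """Normalize sample frames to (I − dark)/(flat − dark).

    If several flats are given together with ``flat_positions`` (the index in
    the sample sequence at which each flat was taken), the flat used for a
    sample frame is linearly interpolated between the bracketing flats, which
    corrects slow illumination drifts. Otherwise the mean flat is used.

    Intensities are divided by exposure first, so frames of different
    exposure normalize consistently.
    """
    if isinstance(frames, FrameSet):
        samples = frames.of_kind("sample")
        flats = flats if flats is not None else frames.of_kind("flat")
        darks = darks if darks is not None else frames.of_kind("dark")
    else:
        samples = list(frames)
    if not flats:
        raise ValueError("at least one flat frame is required")
    if not darks:
        raise ValueError("at least one dark frame is required")

    dark = np.mean([d.intensities / d.exposure for d in darks], axis=0)
    flat_stack = np.stack([f.intensities / f.exposure for f in flats])
    bad = np.nonzero(flat_stack.min(axis=0) - dark <= 0)[0]
    if bad.size:
        raise ValueError(
            f"flat <= dark at pixel(s) {bad.tolist()[:20]}; cannot normalize"
        )

    n = len(samples)
    if flat_positions is not None and len(flats) > 1:
        pos = np.asarray(flat_positions, dtype=float)
        if pos.size != flat_stack.shape[0]:
            raise ValueError("flat_positions must match the number of flats")
        interp_flats = np.empty((n, flat_stack.shape[1]))
        for px in range(flat_stack.shape[1]):
            interp_flats[:, px] = np.interp(np.arange(n), pos, flat_stack[:, px])
    else:
        interp_flats = np.broadcast_to(flat_stack.mean(axis=0), (n, flat_stack.shape[1]))

    out = []
    for i, fr in enumerate(samples):
        norm = (fr.intensities / fr.exposure - dark) / (interp_flats[i] - dark)
        out.append(
            Frame(
                intensities=np.clip(norm, 0.0, None),
                angle_deg=fr.angle_deg,
                lateral_offset=fr.lateral_offset,
                exposure=1.0,
                kind="sample",
                band_name=fr.band_name,
            )
        )
    return out


def _grid_geometry(n_beamlets: int, band: MaskBand, geom: SystemGeometry, traj: Trajectory):
    pitch = band.period * geom.m_s
    xb = (np.arange(n_beamlets) - (n_beamlets - 1) / 2.0) * pitch
    return xb, traj.step


def interleave_dithered(
    frames: list[Frame], traj: Trajectory, band: MaskBand, geom: SystemGeometry
) -> Sinogram:
    """Combine dithered frames into a fully sampled sinogram, reversing jitter.

    The value measured by beamlet b in the frame acquired at lateral offset s
    probes the sample at x = x_b − s; since all offsets (including jitter)
    are integer multiples of the dither step, every sample lands exactly on
    the uniform grid. Cells that a jittered scan leaves unsampled at the
    lateral edges are filled with the vacuum value 1.0 and counted in
    ``meta["n_filled"]``.
    """
    if traj.scheme != "dithered":
        raise ValueError("trajectory is not dithered")
    if len(frames) != len(traj):
        raise ValueError("frame count does not match trajectory length")
    nd = traj.n_dith
    step = traj.step
    angles = traj.unique_angles
    missing = []
    for a in angles:
        if np.count_nonzero(traj.angles_deg == a) != nd:
            missing.append(float(a))
    if missing:
        raise ValueError(f"missing dither frames at angle(s) {missing[:10]}")

    n_beamlets = frames[0].intensities.size
    xb, _ = _grid_geometry(n_beamlets, band, geom, traj)
    x0 = xb[0] - (nd - 1) * step  # canonical (jitterless) leftmost sample
    n_lat = n_beamlets * nd
    lateral = x0 + np.arange(n_lat) * step

    values = np.full((angles.size, n_lat), np.nan)
    angle_index = {a: i for i, a in enumerate(angles)}
    for fr, s in zip(frames, traj.offsets):
        ia = angle_index[fr.angle_deg]
        idx = np.rint((xb - s - x0) / step).astype(int)
        ok = (idx >= 0) & (idx < n_lat)
        values[ia, idx[ok]] = fr.intensities[ok]

    n_filled = int(np.isnan(values).sum())
    if n_filled:
        logger.info("filled %d unsampled edge cells with vacuum value 1.0", n_filled)
        values = np.nan_to_num(values, nan=1.0)
    n_clip = int(np.count_nonzero(values < 0))
    values = np.clip(values, 0.0, None)
    return Sinogram(
        values=values,
        angles_deg=angles,
        lateral=lateral,
        scheme="dithered",
        band_name=band.name,
        meta={"n_filled": n_filled, "n_clipped": n_clip},
    )


def regrid_cycloidal(
    frames: list[Frame],
    traj: Trajectory,
    band: MaskBand,
    geom: SystemGeometry,
    target_angles: np.ndarray | None = None,
) -> Sinogram:
    """Interpolate cycloidal samples onto the dithered-equivalent grid.

    Type-1 samples land exactly on the uniform lateral grid (the shift per
    frame is one dither step), so the regridding reduces to a cubic spline
    along the periodically tiled angle axis, independently per lateral
    column — the shear-aligned separable scheme. Type-2 shifts are generally
    incommensurate with the grid; those scans are regridded with cubic
    (Clough–Tocher) scattered interpolation in (angle, lateral) space, again
    with the angle axis tiled by ±360° so the interpolation wraps.

    The usable lateral extent shrinks by the back-and-forth span: only
    positions probed at *every* angle are kept.
    """
    if traj.scheme not in ("cyc1", "cyc2"):
        raise ValueError("trajectory is not cycloidal")
    if len(frames) != len(traj):
        raise ValueError("frame count does not match trajectory length")
    nd = traj.n_dith
    step = traj.step
    n_beamlets = frames[0].intensities.size
    xb, _ = _grid_geometry(n_beamlets, band, geom, traj)

    if target_angles is None:
        n_base = max(len(traj) // nd, 2)
        target_angles = np.arange(n_base) * (360.0 / n_base)
    target_angles = np.asarray(target_angles, dtype=float)

    # lateral grid: positions sampled at every offset in [0, span]
    x_lo, x_hi = xb[0], xb[-1] - traj.span
    if x_hi <= x_lo:
        raise ValueError(
            "back-and-forth span exceeds the beamlet coverage; "
            "use more beamlets or a smaller span"
        )
    i0 = int(np.ceil((x_lo - xb[0]) / step - 1e-9))
    i1 = int(np.floor((x_hi - xb[0]) / step + 1e-9))
    lateral = xb[0] + np.arange(i0, i1 + 1) * step
    n_lat = lateral.size

    offsets = traj.offsets
    on_grid = np.allclose(offsets / step, np.rint(offsets / step), atol=1e-6)

    vals = np.stack([f.intensities for f in frames])  # (n_frames, n_beamlets)
    ang = traj.angles_deg

    if on_grid:
        values = np.full((target_angles.size, n_lat), np.nan)
        # per lateral column: collect the (angle, value) samples that hit it
        col_of = {}
        for i in range(len(traj)):
            idx = np.rint((xb - offsets[i] - lateral[0]) / step).astype(int)
            ok = (idx >= 0) & (idx < n_lat)
            for b in np.nonzero(ok)[0]:
                col_of.setdefault(idx[b], []).append((ang[i], vals[i, b]))
        n_dup = 0
        for m, samples in col_of.items():
            arr = np.asarray(samples)
            order = np.argsort(arr[:, 0])
            th, v = arr[order, 0], arr[order, 1]
            uth, inv = np.unique(th, return_inverse=True)
            if uth.size != th.size:
                n_dup += th.size - uth.size
                v = np.bincount(inv, weights=v) / np.bincount(inv)
                th = uth
            # periodic tiling so the spline wraps at 0/360
            th_t = np.concatenate([th - 360.0, th, th + 360.0])
            v_t = np.concatenate([v, v, v])
            values[:, m] = CubicSpline(th_t, v_t)(target_angles)
        n_nan = int(np.isnan(values).sum())
        if n_nan:
            logger.info("%d grid cells had no column samples; vacuum-filled", n_nan)
            values = np.nan_to_num(values, nan=1.0)
        meta = {"n_duplicates_averaged": n_dup, "method": "per-column cubic spline"}
    else:
        pts_a = np.concatenate([ang - 360.0, ang, ang + 360.0])
        a_all = np.repeat(pts_a, n_beamlets)
        x_one = (xb[None, :] - offsets[:, None]).ravel()
        x_all = np.tile(x_one, 3)
        v_all = np.tile(vals.ravel(), 3)
        tg_a, tg_x = np.meshgrid(target_angles, lateral, indexing="ij")
        values = griddata(
            np.column_stack([a_all / 360.0 * np.ptp(x_all), x_all]),
            v_all,
            (tg_a / 360.0 * np.ptp(x_all), tg_x),
            method="cubic",
        )
        n_nan = int(np.isnan(values).sum())
        if n_nan:
            near = griddata(
                np.column_stack([a_all / 360.0 * np.ptp(x_all), x_all]),
                v_all,
                (tg_a / 360.0 * np.ptp(x_all), tg_x),
                method="nearest",
            )
            values[np.isnan(values)] = near[np.isnan(values)]
            logger.info("%d cells filled by nearest-sample fallback", n_nan)
        meta = {"method": "scattered cubic (Clough-Tocher)", "n_nearest_filled": n_nan}

    n_clip = int(np.count_nonzero(values < 0))
    values = np.clip(values, 0.0, None)
    meta["n_clipped"] = n_clip
    return Sinogram(
        values=values,
        angles_deg=target_angles,
        lateral=lateral,
        scheme=traj.scheme,
        band_name=band.name,
        meta=meta,
    )
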