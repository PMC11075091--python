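"""Edge-illumination image formation.

The detected intensity behind one beamlet is

    I = I0 · exp(−2k ∫β dz) · C(x_m − z_od · ∂x ∫δ dz),

i.e. attenuation (Beer–Lambert on β) times the illumination curve evaluated
at the working point shifted by the refraction-induced beamlet displacement
(z_od times the transverse gradient of the projected δ). The model is
geometric ray optics with a single refraction event at the sample plane;
diffraction and fringe effects are not part of it.

Because the beamlet has a finite footprint on the sample (the aperture
width times the mask→sample magnification, slightly widened by the
projected source penumbra), the default detection averages the integrand
over that footprint. This is what makes resolution *aperture-driven*: a
frame carries information only from strips of width ~w·m_s centred on the
beamlet positions. A ``center`` sampling mode evaluates the integrand at
the beamlet centre only (a rigid-shift idealization, useful for linearized
round-trip checks).

The phantom is one axial slice; one simulated frame is a 1D array with one
value per beamlet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .geometry import MaskBand, SystemGeometry
from .illumination import IlluminationCurve, WorkingPoint
from .phantoms import OpticalMap
from .units import fwhm_to_sigma

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionSettings",
    "Frame",
    "FrameSet",
    "beamlet_positions",
    "projected_attenuation",
    "refraction_gradient",
    "detect_frame",
    "simulate_scan",
]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Photon budget and noise model for a simulated scan.

    i0_rate : per-beamlet flux upstream of the sample, counts/s. Must match
        the rate the illumination curve was simulated with, since the curve
        carries the absolute scale.
    noise : "none" for deterministic expectation values, "poisson" for shot
        noise (seeded per frame from (seed, angle, offset), so the noise
        realisation does not depend on trajectory ordering).
    dark_level : detector offset in counts/s, added to every frame.
    beamlet_sampling : "average" integrates over the beamlet footprint
        (default), "center" point-samples at the beamlet centre.
    """

    i0_rate: float = 1.0
    noise: Literal["none", "poisson"] = "none"
    seed: int = 0
    dark_level: float = 0.0
    beamlet_sampling: Literal["average", "center"] = "average"
    n_sub: int = 9

    def __post_init__(self) -> None:
        if self.i0_rate <= 0:
            raise ValueError("i0_rate must be positive")
        if self.n_sub < 1:
            raise ValueError("n_sub must be >= 1")


@dataclass
class Frame:
    """One detected frame: counts per illuminated beamlet column."""

    intensities: np.ndarray
    angle_deg: float
    lateral_offset: float  # m, sample plane
    exposure: float  # s
    kind: str = "sample"  # sample | flat | dark
    band_name: str = ""
    n_clamped: int = 0  # beamlets whose curve argument left the sampled support

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class FrameSet:
    """Stack of frames from one scan, sample frames first in schedule order."""

    frames: list[Frame] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def of_kind(self, kind: str) -> list[Frame]:
        return [f for f in self.frames if f.kind == kind]

    def stack(self, kind: str | None = None) -> np.ndarray:
        sel = self.frames if kind is None else self.of_kind(kind)
        return np.stack([f.intensities for f in sel])


def beamlet_positions(
    field_width: float, band: MaskBand, geom: SystemGeometry
) -> np.ndarray:
    """Lab-frame beamlet centres (m, sample plane) covering ``field_width``.

    One beamlet per mask period (line-skipping layout: the blocked columns in
    between are not simulated), symmetric about the rotation axis.
    """
    pitch = band.period * geom.m_s
    n = int(np.floor(field_width / pitch))
    n = max(n, 1)
    return (np.arange(n) - (n - 1) / 2.0) * pitch


def _rotated_projection(values: np.ndarray, angle_deg: float, voxel: float):
    """Parallel projection of a map onto the lateral axis at one view angle.

    Rotating the map by −angle and summing over rows matches the convention
    of skimage.transform.radon/iradon, so reconstructions land in phantom
    orientation.
    """
    if angle_deg % 360.0 != 0.0:
        rot = ndimage.rotate(
            values, -angle_deg, reshape=False, order=1, mode="constant", cval=0.0
        )
    else:
        rot = values
    proj = rot.sum(axis=0) * voxel
    n = proj.size
    xs = (np.arange(n) - (n - 1) / 2.0) * voxel
    return xs, proj


def projected_attenuation(
    omap: OpticalMap, angle_deg: float, positions: np.ndarray
) -> np.ndarray:
    """Line integrals ∫β dz (m) through the rotated slice at lateral positions.

    Positions outside the padded support are treated as vacuum (0).
    """
    xs, proj = _rotated_projection(omap.beta, angle_deg, omap.voxel_size)
    positions = np.asarray(positions, dtype=float)
    if positions.size and (
        positions.min() < xs[0] - omap.voxel_size
        or positions.max() > xs[-1] + omap.voxel_size
    ):
        logger.info("positions outside map support treated as vacuum")
    return np.interp(positions, xs, proj, left=0.0, right=0.0)


def refraction_gradient(
    omap: OpticalMap, angle_deg: float, positions: np.ndarray
) -> np.ndarray:
    """Transverse derivative ∂x ∫δ dz (dimensionless) at lateral positions."""
    xs, proj = _rotated_projection(omap.delta, angle_deg, omap.voxel_size)
    grad = np.gradient(proj, omap.voxel_size)
    return np.interp(np.asarray(positions, dtype=float), xs, grad, left=0.0, right=0.0)


def _beamlet_quadrature(
    band: MaskBand, geom: SystemGeometry, settings: AcquisitionSettings
):
    """Sub-beamlet sample offsets and weights across the footprint.

    The footprint profile is the aperture top-hat (width w·m_s at the sample
    plane) convolved with the projected source penumbra; it is sampled at
    n_sub points and the weights normalised to 1.
    """
    if settings.beamlet_sampling == "center" or settings.n_sub == 1:
        return np.array([0.0]), np.array([1.0])
    w_s = band.aperture * geom.m_s
    sigma = (
        fwhm_to_sigma(geom.source_fwhm)
        * geom.d_samplemask_sample
        / geom.d_source_samplemask
    )
    half = w_s / 2.0 + 2.5 * sigma
    u = np.linspace(-half, half, settings.n_sub)
    if sigma == 0.0:
        prof = ((u >= -w_s / 2) & (u <= w_s / 2)).astype(float)
    else:
        from scipy.special import ndtr

        prof = ndtr((u + w_s / 2) / sigma) - ndtr((u - w_s / 2) / sigma)
    prof /= prof.sum()
    return u, prof


def _frame_rng(
    settings: AcquisitionSettings, angle_deg: float, offset: float, tag: int = 0
):
    # counter-based substream: keyed on the physical frame coordinates so the
    # realisation is invariant under trajectory reordering
    key = (
        settings.seed,
        int(round(abs(angle_deg) * 1e6)),
        int(round(abs(offset) * 1e9)),
        tag,
    )
    return np.random.default_rng(key)


def detect_frame(
    geom: SystemGeometry,
    band: MaskBand,
    omap: OpticalMap | None,
    angle_deg: float,
    lateral_offset: float,
    working_point: WorkingPoint,
    curve: IlluminationCurve,
    settings: AcquisitionSettings,
    exposure: float = 1.0,
    n_beamlets: int | None = None,
    field_width: float | None = None,
    noise_tag: int = 0,
    _profiles=None,
) -> Frame:
    """Simulate one frame at a given view angle and lateral sample offset.

    With ``omap=None`` a flat field is produced (counts = exposure·C(x_m)
    per beamlet, plus dark level). ``_profiles`` allows a caller that loops
    over offsets at a fixed angle to reuse the projected β/δ profiles.
    """
    if field_width is None:
        field_width = omap.field_width() if omap is not None else 0.0
    xb = beamlet_positions(max(field_width, band.period * geom.m_s), band, geom)
    if n_beamlets is not None:
        xb = (np.arange(n_beamlets) - (n_beamlets - 1) / 2.0) * band.period * geom.m_s

    if omap is None:
        counts = np.full(xb.size, exposure * (working_point.c_xm + settings.dark_level))
        kind = "flat"
        n_clamped = 0
    else:
        if _profiles is None:
            xs_b, tb = _rotated_projection(omap.beta, angle_deg, omap.voxel_size)
            xs_d, td = _rotated_projection(omap.delta, angle_deg, omap.voxel_size)
            grad = np.gradient(td, omap.voxel_size)
        else:
            xs_b, tb, grad = _profiles
        u, wts = _beamlet_quadrature(band, geom, settings)
        # sample-frame coordinates probed by each sub-beamlet
        pos = xb[:, None] - lateral_offset + u[None, :]
        t_beta = np.interp(pos, xs_b, tb, left=0.0, right=0.0)
        g = np.interp(pos, xs_b, grad, left=0.0, right=0.0)
        arg = working_point.x_m - geom.z_od * g
        lo, hi = curve.offsets[0], curve.offsets[-1]
        n_clamped = int(np.count_nonzero((arg < lo) | (arg > hi)))
        if n_clamped:
            logger.warning(
                "%d sub-beamlet curve arguments clamped to the sampled support",
                n_clamped,
            )
        integrand = np.exp(-2.0 * omap.k * t_beta) * np.asarray(curve(arg))
        counts = exposure * (integrand @ wts + settings.dark_level)
        kind = "sample"

    if settings.noise == "poisson":
        rng = _frame_rng(settings, angle_deg, lateral_offset, noise_tag)
        counts = rng.poisson(counts).astype(float)
    return Frame(
        intensities=counts,
        angle_deg=angle_deg,
        lateral_offset=lateral_offset,
        exposure=exposure,
        kind=kind,
        band_name=band.name,
        n_clamped=n_clamped,
    )


def _dark_frame(
    n_beamlets: int, settings: AcquisitionSettings, exposure: float, band: MaskBand
) -> Frame:
    counts = np.full(n_beamlets, settings.dark_level * exposure)
    if settings.noise == "poisson" and settings.dark_level > 0:
        rng = _frame_rng(settings, -1.0, -1.0)
        counts = rng.poisson(counts).astype(float)
    return Frame(
        intensities=counts,
        angle_deg=0.0,
        lateral_offset=0.0,
        exposure=exposure,
        kind="dark",
        band_name=band.name,
    )


def simulate_scan(
    geom: SystemGeometry,
    band: MaskBand,
    omap: OpticalMap,
    trajectory,
    working_point: WorkingPoint,
    curve: IlluminationCurve,
    settings: AcquisitionSettings,
    n_flats: int = 1,
    n_darks: int = 1,
) -> FrameSet:
    """Run a full scan along a trajectory, plus flat and dark frames.

    Frames at the same view angle share one projection computation, so the
    cost scales with the number of distinct angles, not frames.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    field_width = omap.field_width()
    xb = beamlet_positions(max(field_width, band.period * geom.m_s), band, geom)
    frames: list[Frame] = []
    order = np.lexsort((trajectory.offsets, trajectory.angles_deg))
    profiles_cache: dict[float, tuple] = {}
    frame_by_index: dict[int, Frame] = {}
    for idx in order:
        ang = float(trajectory.angles_deg[idx])
        if ang not in profiles_cache:
            xs_b, tb = _rotated_projection(omap.beta, ang, omap.voxel_size)
            _, td = _rotated_projection(omap.delta, ang, omap.voxel_size)
            profiles_cache = {ang: (xs_b, tb, np.gradient(td, omap.voxel_size))}
        frame_by_index[idx] = detect_frame(
            geom,
            band,
            omap,
            ang,
            float(trajectory.offsets[idx]),
            working_point,
            curve,
            settings,
            exposure=float(trajectory.exposures[idx]),
            n_beamlets=xb.size,
            _profiles=profiles_cache[ang],
        )
    frames = [frame_by_index[i] for i in range(len(trajectory))]
    exp0 = float(trajectory.exposures[0])
    for i in range(n_flats):
        frames.append(
            detect_frame(
                geom,
                band,
                None,
                0.0,
                0.0,
                working_point,
                curve,
                settings,
                exposure=exp0,
                n_beamlets=xb.size,
                noise_tag=1 + i,
            )
        )
    for _ in range(n_darks):
        frames.append(_dark_frame(xb.size, settings, exp0, band))
    return FrameSet(frames=frames)
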