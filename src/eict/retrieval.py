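"""Single-image phase retrieval, FBP reconstruction, modulation analysis.

Retrieval inverts the linearized edge-illumination signal model for a
single-material (homogeneous) object. Writing A = exp(−2k∫β dz) and using
the homogeneity ratio γ = δ/(2kβ) = const, the normalized intensity is

    I/I0 = A · C(x_m − z_od ∂x ∫δ dz) / C(x_m)
         ≈ A + γ z_od (C'(x_m)/C(x_m)) ∂x A,

so a single Fourier-domain filter recovers A row by row:

    ∫β dz = −(1/2k) · log( F⁻¹[ F(I/I0) / (1 + i·2πν·z_od·(C'/C)·γ) ] ),

with ν the spatial frequency conjugate to the lateral coordinate. The
filter magnitude 1/|1 + i·2πν·z_od·(C'/C)·γ| is ≤ 1 at every frequency: it
is a pure low-pass, the edge-illumination analogue of the Paganin filter.
The sign of the iν term follows from the forward model's shift direction
C(x_m − z_od·g) together with the FFT sign convention used here
(F(∂x f) = +i2πν F(f)).

Reconstruction is standard parallel-beam filtered back projection with a
Ram-Lak (ramp) filter and linear-interpolation back projection; 360° data
average conjugate views through the standard 1/(2N) angular weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon

from .assembly import Sinogram
from .geometry import SystemGeometry
from .illumination import WorkingPoint

logger = logging.getLogger(__name__)

__all__ = [
    "RetrievalSettings",
    "ReconSlice",
    "retrieval_transfer",
    "phase_retrieve",
    "fbp_reconstruct",
    "fbp_reconstruct_raw",
    "modulation_analysis",
    "beta_to_mu",
]


@dataclass(frozen=True)
class RetrievalSettings:
    """Parameters of the single-image retrieval filter.

    gamma : homogeneity ratio δ/(2kβ) of the object, in metres.
    z_od : sample-to-detector distance, m.
    c_xm, c_prime : illumination-curve value and slope at the working point.
    k : wave number, 1/m.
    """

    gamma: float
    z_od: float
    c_xm: float
    c_prime: float
    k: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.c_xm <= 0:
            raise ValueError("C(x_m) must be positive")
        if self.z_od <= 0 or self.k <= 0:
            raise ValueError("z_od and k must be positive")

    @classmethod
    def from_system(
        cls, geom: SystemGeometry, wp: WorkingPoint, gamma: float
    ) -> "RetrievalSettings":
        return cls(
            gamma=gamma, z_od=geom.z_od, c_xm=wp.c_xm, c_prime=wp.c_prime, k=geom.k
        )

    @property
    def slope_ratio(self) -> float:
        """C'(x_m)/C(x_m), 1/m."""
        return self.c_prime / self.c_xm


@dataclass
class ReconSlice:
    """Reconstructed axial slice of β (dimensionless), square pixel grid.

    The rotation axis sits at pixel index ``n//2`` along both axes (the
    iradon convention); ``coords`` maps pixel indices to physical metres.
    """

    values: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("reconstructed slice must be square")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinates of pixel centres, in metres."""
        idx = np.arange(self.n) - self.n // 2
        return idx * self.pixel_size, idx * self.pixel_size


def retrieval_transfer(nu: np.ndarray, settings: RetrievalSettings) -> np.ndarray:
    """Complex transfer function 1/(1 + i·2πν·z_od·(C'/C)·γ) at frequencies ν."""
    nu = np.asarray(nu, dtype=float)
    return 1.0 / (
        1.0 + 1j * 2.0 * np.pi * nu * settings.z_od * settings.slope_ratio * settings.gamma
    )


def phase_retrieve(sino: Sinogram, settings: RetrievalSettings) -> Sinogram:
    """Retrieve projected absorption ∫β dz (m) from a normalized sinogram.

    Applied row-wise (1D along the lateral axis — edge-illumination phase
    sensitivity is one-dimensional). Rows are symmetrically padded to twice
    their width before the FFT and cropped after, which suppresses wrap-around
    from the non-periodic field of view. With γ = 0 the filter is the
    identity and the result is the pure attenuation signal −log(I/I0)/(2k).
    """
    vals = sino.values
    n = vals.shape[1]
    padded = np.pad(vals, ((0, 0), (n // 2, n - n // 2)), mode="symmetric")
    m = padded.shape[1]
    nu = np.fft.fftfreq(m, d=sino.pitch)
    h = retrieval_transfer(nu, settings)
    filt = np.fft.ifft(np.fft.fft(padded, axis=1) * h[None, :], axis=1)
    resid = np.abs(filt.imag).max()
    if resid > 1e-8 * max(np.abs(filt.real).max(), 1.0):
        logger.warning("imaginary residue %.3g after retrieval filter", resid)
    filt = filt.real[:, n // 2 : n // 2 + n]
    if np.any(filt <= 0):
        bad = np.argwhere(filt <= 0)
        raise ValueError(
            f"non-positive intensity after filtering at {bad.shape[0]} pixel(s), "
            f"first at (angle, lateral) index {tuple(bad[0])}; "
            "check normalization and the γ value"
        )
    t_beta = -np.log(filt) / (2.0 * settings.k)
    return Sinogram(
        values=t_beta,
        angles_deg=sino.angles_deg,
        lateral=sino.lateral,
        scheme=sino.scheme,
        band_name=sino.band_name,
        signed=True,
        meta={**sino.meta, "retrieved": True, "gamma_m": settings.gamma},
    )


def fbp_reconstruct_raw(
    values: np.ndarray, angles_deg: np.ndarray, lateral: np.ndarray, **meta
) -> ReconSlice:
    """FBP of a ∫β dz grid given explicit (possibly non-uniform) angles.

    The grid is zero-padded laterally so the rotation axis (lateral
    coordinate 0) sits at the centre index expected by the back projector;
    the output slice is in β units (line integrals divided by the pixel
    size) with pixel size equal to the lateral pitch.
    """
    values = np.asarray(values, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    lateral = np.asarray(lateral, dtype=float)
    if angles_deg.size < 2:
        raise ValueError("need at least 2 angles for reconstruction")
    pitch = float(lateral[1] - lateral[0])
    ic_f = -lateral[0] / pitch
    ic = int(np.rint(ic_f))
    if abs(ic_f - ic) > 0.01:
        logger.warning(
            "rotation axis offset %.3f px from the lateral grid; using nearest",
            ic_f - ic,
        )
    n = lateral.size
    half = max(ic, n - 1 - ic)
    n_out = 2 * half + 1
    left = half - ic
    padded = np.zeros((angles_deg.size, n_out))
    padded[:, left : left + n] = values
    recon = iradon(
        padded.T / pitch,
        theta=angles_deg,
        filter_name="ramp",
        interpolation="linear",
        circle=False,
        output_size=n_out,
    )
    return ReconSlice(
        values=recon,
        pixel_size=pitch,
        meta={"n_angles": angles_deg.size, **meta},
    )


def fbp_reconstruct(sino: Sinogram) -> ReconSlice:
    """Filtered back projection (Ram-Lak filter) of a ∫β dz sinogram."""
    return fbp_reconstruct_raw(
        sino.values,
        sino.angles_deg,
        sino.lateral,
        scheme=sino.scheme,
        band=sino.band_name,
    )


def beta_to_mu(beta: np.ndarray | float, k: float) -> np.ndarray | float:
    """Linear attenuation coefficient μ = 2kβ (1/m)."""
    return 2.0 * k * beta


def modulation_analysis(
    recon: ReconSlice, bar_groups: list[dict]
) -> list[dict]:
    """Bar-pattern modulation per group from a reconstructed slice.

    For each group the slice is averaged along the bar direction (y) inside
    the group's bounding box, giving one profile across the bars. Using the
    known bar phase and pitch from the phantom metadata, the profile is read
    at the bar centres (peaks) and gap centres (troughs):

        modulation = (mean(peaks) − mean(troughs)) / (mean(peaks) + mean(troughs)),

    clipped at 0. Perfect binary bars give 1; an unresolved group gives ~0.
    """
    ys, xs = recon.coords()
    out = []
    for g in bar_groups:
        x0, x1 = g["x0_um"] * 1e-6, g["x1_um"] * 1e-6
        y0, y1 = g["y0_um"] * 1e-6, g["y1_um"] * 1e-6
        if x0 < xs[0] or x1 > xs[-1] or y0 < ys[0] or y1 > ys[-1]:
            raise ValueError(f"bar group box {g} lies outside the reconstructed slice")
        rows = (ys >= y0) & (ys <= y1)
        profile = recon.values[rows, :].mean(axis=0)
        pitch = g["pitch_um"] * 1e-6
        c0 = g["first_bar_centre_um"] * 1e-6
        nb = int(g["n_bars"])
        peaks = np.interp(c0 + np.arange(nb) * pitch, xs, profile)
        troughs = np.interp(c0 + pitch / 2.0 + np.arange(nb) * pitch, xs, profile)
        denom = peaks.mean() + troughs.mean()
        mod = (peaks.mean() - troughs.mean()) / denom if denom != 0 else 0.0
        out.append(
            {
                "width_um": g["width_um"],
                "frequency_lp_mm": 1e3 / (2.0 * g["width_um"]),
                "modulation": float(np.clip(mod, 0.0, 1.0)),
            }
        )
    return out
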