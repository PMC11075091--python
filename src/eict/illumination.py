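"""Illumination curve of an edge-illumination system.

The illumination curve C(x) is the detected intensity versus lateral
sample-mask offset x, measured with no sample in the beam. It encodes how a
refraction-induced beamlet shift converts into an intensity change: imaging
is performed at a fixed working point x_m on a flank of the curve, and the
local value C(x_m) and slope C'(x_m) calibrate the phase sensitivity.

The model is geometric: each sample-mask aperture produces a top-hat beamlet
which is blurred by the projected source focal spot (Gaussian) and overlaps
the transmitting apertures of the detector mask. The overlap integral has a
closed form in terms of G(t) = t·Φ(t) + φ(t), the antiderivative of the
normal CDF; a brute-force quadrature of the same integral is used as an
independent oracle in the test suite.

Offsets are expressed at the sample-mask plane in metres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, curve_fit

from .geometry import DetectorSpec, MaskBand, SystemGeometry
from .units import fwhm_to_sigma

__all__ = [
    "IlluminationCurve",
    "WorkingPoint",
    "simulate_illumination_curve",
    "transmitted_fraction",
    "choose_working_point",
]


def _gauss_cdf_antideriv(t: np.ndarray) -> np.ndarray:
    """G(t) = t·Φ(t) + φ(t); G' = Φ. For σ→0, σ·G(x/σ) → max(x, 0)."""
    from scipy.special import ndtr

    return t * ndtr(t) + np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi)


def _tophat_gauss_overlap(
    centre: np.ndarray, width: float, sigma: float, lo: float, hi: float
) -> np.ndarray:
    """Flux of a unit-flux top-hat beamlet (width ``width``, centred at
    ``centre``, blurred by a Gaussian of std ``sigma``) falling inside the
    window [lo, hi]."""
    c = np.asarray(centre, dtype=float)
    a, b = c - width / 2.0, c + width / 2.0  # unblurred beamlet support
    if sigma == 0.0:
        return np.clip(np.minimum(hi, b) - np.maximum(lo, a), 0.0, None) / width
    g = _gauss_cdf_antideriv
    val = (
        g((hi - a) / sigma)
        - g((lo - a) / sigma)
        - g((hi - b) / sigma)
        + g((lo - b) / sigma)
    )
    return sigma * val / width


def transmitted_fraction(
    geom: SystemGeometry,
    band: MaskBand,
    det: DetectorSpec,
    offsets: np.ndarray,
    det_septa_transmission: float = 0.0,
    n_neighbours: int = 3,
) -> np.ndarray:
    """Fraction of one beamlet's flux reaching the detector vs mask offset.

    ``offsets`` are lateral sample-mask displacements (m). The overlap is
    evaluated at the detector-mask plane: the beamlet is the aperture top-hat
    projected to that plane and convolved with the projected source blur; the
    detector mask contributes a row of transmitting windows spaced by its
    period. Circular apertures are treated with their diameter as the
    horizontal width (the in-plane physics is one-dimensional; their reduced
    flux is a separate scale factor, see :func:`eict.geometry.flux_per_period`).
    """
    offsets = np.asarray(offsets, dtype=float)
    r_sm = geom.d_source_samplemask
    r_dm = geom.d_source_detmask
    mag = r_dm / r_sm
    beam_width = band.aperture * mag
    # penumbra of the source focal spot at the detector-mask plane
    sigma = fwhm_to_sigma(geom.source_fwhm) * (r_dm - r_sm) / r_sm
    centres = offsets * mag  # beamlet centre displacement at that plane

    frac = np.zeros_like(centres)
    half = det.detmask_aperture / 2.0
    for n in range(-n_neighbours, n_neighbours + 1):
        mid = n * det.detmask_period
        frac += _tophat_gauss_overlap(centres, beam_width, sigma, mid - half, mid + half)
    if det_septa_transmission > 0.0:
        frac = frac + det_septa_transmission * (1.0 - frac)
    return frac


@dataclass
class IlluminationCurve:
    """Sampled illumination curve plus fitted-model conveniences.

    offsets : sample-mask offsets in metres (strictly increasing)
    intensities : detected counts per second per beamlet (≥ 0)
    """

    offsets: np.ndarray
    intensities: np.ndarray
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.offsets.size < 4:
            raise ValueError("illumination curve needs at least 4 samples")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def c_max(self) -> float:
        return float(self.intensities.max())

    def spline(self) -> CubicSpline:
        if self._spline is None:
            self._spline = CubicSpline(self.offsets, self.intensities)
        return self._spline

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        """Evaluate C at offsets x (m); clamped to the sampled support."""
        x = np.clip(x, self.offsets[0], self.offsets[-1])
        return self.spline()(x)

    def gaussian_fit(self) -> tuple[float, float, float]:
        """Fit A·exp(−(x−μ)²/2s²) to the samples; returns (A, μ, s).

        EI illumination curves are approximately Gaussian once source blur
        smooths the mask-overlap trapezoid, which makes this a robust
        parametric handle for slope estimation.
        """
        x, y = self.offsets, self.intensities
        a0 = float(y.max())
        mu0 = float(x[np.argmax(y)])
        s0 = max(float(np.sqrt(np.sum(y * (x - mu0) ** 2) / np.sum(y))), 1e-9)

        def model(x, a, mu, s):
            return a * np.exp(-0.5 * ((x - mu) / s) ** 2)

        import warnings

        with warnings.catch_warnings():
            # only the point estimate is used; the covariance of a fit to a
            # noise-free sampled curve is legitimately ill-conditioned
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, x, y, p0=(a0, mu0, s0), maxfev=20000)
        a, mu, s = popt
        return float(a), float(mu), float(abs(s))

    def to_csv(self, path) -> None:
        """Write as two-column CSV (offset_um, intensity)."""
        data = np.column_stack([self.offsets * 1e6, self.intensities])
        np.savetxt(path, data, delimiter=",", header="offset_um,intensity", comments="")

    @classmethod
    def from_csv(cls, path) -> "IlluminationCurve":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(offsets=data[:, 0] * 1e-6, intensities=data[:, 1])


@dataclass(frozen=True)
class WorkingPoint:
    """Operating point on the illumination curve used during imaging."""

    x_m: float  # sample-mask offset, m
    c_xm: float  # detected counts/s at x_m
    c_prime: float  # slope dC/dx at x_m, counts/s per m
    c_max: float
    target_fraction: float
    flank: str  # "positive" or "negative" slope


def simulate_illumination_curve(
    geom: SystemGeometry,
    band: MaskBand,
    det: DetectorSpec,
    offsets: np.ndarray | None = None,
    i0_rate: float = 1.0,
    det_septa_transmission: float = 0.0,
    n_samples: int = 201,
) -> IlluminationCurve:
    """Step the sample mask laterally and record the detected intensity.

    ``i0_rate`` is the per-beamlet flux upstream of the sample in counts/s;
    the returned intensities are in the same units, so the curve carries the
    absolute photon budget used by the forward simulator.

    The model is exactly periodic with the detector-mask period referred to
    the sample-mask plane; the default offsets span one such period centred
    on the aligned position.
    """
    if offsets is None:
        period_sm = det.detmask_period * geom.d_source_samplemask / geom.d_source_detmask
        offsets = np.linspace(-period_sm / 2.0, period_sm / 2.0, n_samples)
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise ValueError("offsets must not be empty")
    frac = transmitted_fraction(
        geom, band, det, offsets, det_septa_transmission=det_septa_transmission
    )
    # residual leakage through the sample-mask septa: a uniform background
    # over (p − w)/p of the period, vignetted by the detector-mask open fraction
    if band.septa_transmission > 0.0:
        leak = (
            band.septa_transmission
            * (band.period - band.aperture)
            / band.aperture
            * det.detmask_aperture
            / det.detmask_period
        )
    else:
        leak = 0.0
    return IlluminationCurve(offsets=offsets, intensities=i0_rate * (frac + leak))


def choose_working_point(
    curve: IlluminationCurve,
    target_fraction: float = 0.5,
    flank: str = "positive",
    slope_method: str = "gauss_fit",
) -> WorkingPoint:
    """Locate the offset x_m where C(x_m)/C_max equals ``target_fraction``.

    The offset is found by root-finding on a cubic-spline interpolant of the
    sampled curve, restricted to the requested flank ("positive" slope =
    offsets below the peak, "negative" = above). The slope C'(x_m) is read
    from the differentiated Gaussian fit by default; ``slope_method="spline"``
    uses the spline derivative (a finite-difference-like fallback for curves
    that are far from Gaussian).
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must lie strictly inside (0, 1)")
    if flank not in ("positive", "negative"):
        raise ValueError("flank must be 'positive' or 'negative'")
    x, y = curve.offsets, curve.intensities
    c_max = curve.c_max
    if c_max <= 0 or np.ptp(y) < 1e-12 * max(c_max, 1.0):
        raise ValueError("curve is flat; no slope working point exists")
    i_peak = int(np.argmax(y))
    if flank == "positive":
        xs, ys = x[: i_peak + 1], y[: i_peak + 1]
    else:
        xs, ys = x[i_peak:], y[i_peak:]
    if xs.size < 2:
        raise ValueError(f"curve has no samples on the {flank} flank")
    target = target_fraction * c_max
    if target < ys.min() or target > ys.max():
        raise ValueError(
            f"target fraction {target_fraction} is outside the sampled range "
            f"of the {flank} flank"
        )
    spline = curve.spline()
    # bracket the crossing between adjacent samples, then refine
    diff = ys - target
    idx = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if idx.size == 0:
        # target equals an endpoint exactly
        x_m = float(xs[np.argmin(np.abs(diff))])
    else:
        # for the positive flank take the crossing nearest the peak
        j = idx[-1] if flank == "positive" else idx[0]
        x_m = float(brentq(lambda t: spline(t) - target, xs[j], xs[j + 1]))

    if slope_method == "gauss_fit":
        a, mu, s = curve.gaussian_fit()
        c_prime = float(a * np.exp(-0.5 * ((x_m - mu) / s) ** 2) * (mu - x_m) / s**2)
    elif slope_method == "spline":
        c_prime = float(spline(x_m, 1))
    else:
        raise ValueError("slope_method must be 'gauss_fit' or 'spline'")
    if abs(c_prime) < 1e-9 * c_max / max(np.ptp(x), 1e-12):
        raise ValueError("slope at the selected point is ~0; not a slope working point")
    return WorkingPoint(
        x_m=x_m,
        c_xm=float(spline(x_m)),
        c_prime=c_prime,
        c_max=c_max,
        target_fraction=target_fraction,
        flank=flank,
    )
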