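"""Optical chain of an edge-illumination (EI) micro-CT system.

The chain is source → sample mask → sample → detector mask → detector, all
on one optical axis. The sample mask structures the cone beam into narrow
beamlets; the detector mask creates absorbing edges in front of the pixel
columns. Because everything is projected from a (nearly) point source,
lengths transform between planes by the ratio of their distances from the
source, which is all the geometry this module needs.

All stored lengths are metres (see :mod:`eict.units`).
"""

from __future__ import annotations

import enum
import math
from typing import Literal

from pydantic import BaseModel, model_validator

from .units import wave_number


class Plane(str, enum.Enum):
    """Named planes of the optical chain, ordered by distance from the source."""

    SOURCE = "source"
    SAMPLE_MASK = "sample-mask"
    SAMPLE = "sample"
    DETECTOR_MASK = "detector-mask"
    DETECTOR = "detector"


class ConfigurationError(ValueError):
    """Raised for physically inconsistent system parameters."""


class SystemGeometry(BaseModel, frozen=True):
    """Distances of the EI chain and the effective (monochromatic) energy.

    Parameters
    ----------
    d_source_samplemask, d_samplemask_sample, d_source_detmask, d_source_detector :
        Distances in metres. Must satisfy
        ``0 < d_source_samplemask < d_source_detmask < d_source_detector``.
    effective_energy :
        Effective monochromatic energy in keV (the polychromatic spectrum is
        collapsed onto its mean energy).
    m_s_override :
        Optional override for the sample-mask→sample magnification. The
        instrument this models quotes m_s = 1.06 while its printed distances
        give (69+3)/69 ≈ 1.043; the toolkit derives m_s from distances by
        default and lets the user pin the quoted value explicitly instead of
        silently reconciling the two.
    """

    d_source_samplemask: float
    d_samplemask_sample: float
    d_source_detmask: float
    d_source_detector: float
    effective_energy: float = 18.0
    source_fwhm: float = 70e-6
    m_s_override: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "SystemGeometry":
        if not (0.0 < self.d_source_samplemask < self.d_source_detmask < self.d_source_detector):
            raise ConfigurationError(
                "need 0 < d(source→sample mask) < d(source→detector mask) "
                "< d(source→detector)"
            )
        if self.d_samplemask_sample < 0:
            raise ConfigurationError("sample-mask→sample distance must be >= 0")
        if self.z_od <= 0:
            raise ConfigurationError("sample must sit upstream of the detector")
        if self.effective_energy <= 0:
            raise ConfigurationError("effective energy must be positive")
        if self.source_fwhm < 0:
            raise ConfigurationError("source FWHM must be >= 0")
        return self

    # -- derived quantities -------------------------------------------------

    @property
    def d_source_sample(self) -> float:
        return self.d_source_samplemask + self.d_samplemask_sample

    @property
    def z_od(self) -> float:
        """Sample-to-detector distance (propagation distance for refraction)."""
        return self.d_source_detector - self.d_source_sample

    @property
    def m_s(self) -> float:
        """Sample-mask→sample-plane magnification."""
        if self.m_s_override is not None:
            return self.m_s_override
        return self.d_source_sample / self.d_source_samplemask

    @property
    def magnification(self) -> float:
        """Sample→detector-plane magnification M."""
        return self.d_source_detector / self.d_source_sample

    @property
    def k(self) -> float:
        """Wave number 2π/λ in 1/m at the effective energy."""
        return wave_number(self.effective_energy)

    def plane_distance(self, plane: Plane | str) -> float:
        plane = Plane(plane)
        return {
            Plane.SOURCE: 0.0,
            Plane.SAMPLE_MASK: self.d_source_samplemask,
            Plane.SAMPLE: self.d_source_sample,
            Plane.DETECTOR_MASK: self.d_source_detmask,
            Plane.DETECTOR: self.d_source_detector,
        }[plane]


class MaskBand(BaseModel, frozen=True):
    """One band of the multi-band sample mask.

    ``aperture`` is the slit width (or circle diameter) w and ``period`` the
    centre-to-centre aperture spacing p, both in metres at the mask plane.
    ``septa_transmission`` is the residual transmission of the absorbing
    septa (0 = perfectly opaque gold).
    """

    shape: Literal["slit", "circle"] = "slit"
    aperture: float
    period: float
    band_height: float = 1e-2
    septa_transmission: float = 0.0
    name: str = ""

    @model_validator(mode="after")
    def _check(self) -> "MaskBand":
        if not (0.0 < self.aperture < self.period):
            raise ConfigurationError("need 0 < aperture < period")
        if not (0.0 <= self.septa_transmission <= 1.0):
            raise ConfigurationError("septa transmission must be in [0, 1]")
        return self


class DetectorSpec(BaseModel, frozen=True):
    """Detector pixel grid plus the detector mask bonded in front of it."""

    pixel_pitch: float = 50e-6
    n_cols: int = 2400
    n_rows: int = 2400
    detmask_aperture: float = 17e-6
    detmask_period: float = 98e-6
    line_skipping: bool = True

    @model_validator(mode="after")
    def _check(self) -> "DetectorSpec":
        if self.detmask_aperture >= self.detmask_period:
            raise ConfigurationError("detector-mask aperture must be < period")
        if self.line_skipping:
            # line-skipping: one beamlet per two pixel columns at the detector
            if not math.isclose(
                self.detmask_period, 2 * self.pixel_pitch, rel_tol=0.05
            ):
                raise ConfigurationError(
                    "line-skipping detector mask period should be ~2 pixel pitches"
                )
        return self


# -- operations -------------------------------------------------------------


def geometric_magnification(geom: SystemGeometry) -> float:
    """Sample→detector magnification M = d(source→detector)/d(source→sample)."""
    return geom.magnification


def project_length(
    geom: SystemGeometry,
    length: float,
    from_plane: Plane | str,
    to_plane: Plane | str,
) -> float:
    """Scale a length between two planes of the chain.

    A feature of size L in a plane at distance r1 from the point source casts
    a shadow of size L·r2/r1 in a plane at distance r2.
    """
    r1 = geom.plane_distance(from_plane)
    r2 = geom.plane_distance(to_plane)
    if r1 == 0.0:
        raise ConfigurationError("cannot project from the source plane (r = 0)")
    return length * r2 / r1


def flux_per_period(
    band: MaskBand, effective_pixel_height: float = 40e-6
) -> float:
    """Open-area fraction of one mask period over one effective pixel height.

    Slit apertures span the full band height, so the fraction is simply w/p.
    Circular apertures only open πd²/4 within the p×h cell; relative to a
    slit of the same nominal width this costs a substantial flux factor
    (>4× for 10 μm circles vs 10 μm slits at h = 40 μm).
    """
    if effective_pixel_height <= 0:
        raise ConfigurationError("effective pixel height must be positive")
    if band.shape == "slit":
        return band.aperture / band.period
    if band.aperture > effective_pixel_height:
        import warnings

        warnings.warn(
            "circle diameter exceeds effective pixel height; clipping not modelled",
            stacklevel=2,
        )
    area = math.pi * (band.aperture / 2.0) ** 2
    return area / (band.period * effective_pixel_height)
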