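"""Schema-validated system configuration.

The configuration file (JSON; YAML parses to the same structure if a caller
prefers it) has four sections — ``geometry``, ``source``, ``sample_mask``
(a list of bands) and ``detector`` — plus an ``acquisition`` section with
operating choices. Lengths carry explicit unit suffixes ("86 cm", "79 um")
and are converted to metres on load. The packaged default describes the
multi-band laboratory system this toolkit models: a 69/3/84/86 cm chain at
18 keV effective energy, a 79 μm-period sample mask with 20/10/5 μm slit
bands plus a 10 μm circular band, and a line-skipping detector mask with
17 μm apertures at 98 μm period in front of 50 μm pixels.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from pydantic import BaseModel, field_validator

from .geometry import DetectorSpec, MaskBand, SystemGeometry
from .units import parse_length

__all__ = ["SystemConfig", "load_config", "default_config_path"]


class _GeometryCfg(BaseModel):
    d_source_samplemask: str | float
    d_samplemask_sample: str | float
    d_source_detmask: str | float
    d_source_detector: str | float
    effective_energy_kev: float = 18.0
    m_s_override: float | None = None


class _SourceCfg(BaseModel):
    fwhm_horizontal: str | float = "70 um"


class _BandCfg(BaseModel):
    name: str
    shape: str = "slit"
    aperture: str | float
    period: str | float
    band_height: str | float = "1 cm"
    septa_transmission: float = 0.0


class _SampleMaskCfg(BaseModel):
    bands: list[_BandCfg]

    @field_validator("bands")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("sample_mask needs at least one band")
        return v


class _DetectorCfg(BaseModel):
    pixel_pitch: str | float = "50 um"
    n_cols: int = 2400
    n_rows: int = 2400
    detmask_aperture: str | float = "17 um"
    detmask_period: str | float = "98 um"
    line_skipping: bool = True


class _AcquisitionCfg(BaseModel):
    working_point_fraction: float = 0.5
    flank: str = "positive"
    effective_pixel_height: str | float = "40 um"


class _RawConfig(BaseModel):
    geometry: _GeometryCfg
    source: _SourceCfg = _SourceCfg()
    sample_mask: _SampleMaskCfg
    detector: _DetectorCfg = _DetectorCfg()
    acquisition: _AcquisitionCfg = _AcquisitionCfg()


class SystemConfig(BaseModel, arbitrary_types_allowed=True):
    """Validated configuration resolved to SI units and domain objects."""

    geometry: SystemGeometry
    bands: dict[str, MaskBand]
    detector: DetectorSpec
    working_point_fraction: float
    flank: str
    effective_pixel_height: float

    def band(self, name: str) -> MaskBand:
        try:
            return self.bands[name]
        except KeyError:
            raise KeyError(
                f"unknown band {name!r}; available: {sorted(self.bands)}"
            ) from None


def default_config_path() -> Path:
    return Path(resources.files("eict").joinpath("data/default_config.json"))


def load_config(path: str | Path | None = None) -> SystemConfig:
    """Load and validate a system configuration (packaged default if None)."""
    if path is None:
        path = default_config_path()
    raw = _RawConfig.model_validate(json.loads(Path(path).read_text()))
    geom = SystemGeometry(
        d_source_samplemask=parse_length(raw.geometry.d_source_samplemask),
        d_samplemask_sample=parse_length(raw.geometry.d_samplemask_sample),
        d_source_detmask=parse_length(raw.geometry.d_source_detmask),
        d_source_detector=parse_length(raw.geometry.d_source_detector),
        effective_energy=raw.geometry.effective_energy_kev,
        source_fwhm=parse_length(raw.source.fwhm_horizontal),
        m_s_override=raw.geometry.m_s_override,
    )
    bands = {
        b.name: MaskBand(
            shape=b.shape,
            aperture=parse_length(b.aperture),
            period=parse_length(b.period),
            band_height=parse_length(b.band_height),
            septa_transmission=b.septa_transmission,
            name=b.name,
        )
        for b in raw.sample_mask.bands
    }
    det = DetectorSpec(
        pixel_pitch=parse_length(raw.detector.pixel_pitch),
        n_cols=raw.detector.n_cols,
        n_rows=raw.detector.n_rows,
        detmask_aperture=parse_length(raw.detector.detmask_aperture),
        detmask_period=parse_length(raw.detector.detmask_period),
        line_skipping=raw.detector.line_skipping,
    )
    return SystemConfig(
        geometry=geom,
        bands=bands,
        detector=det,
        working_point_fraction=raw.acquisition.working_point_fraction,
        flank=raw.acquisition.flank,
        effective_pixel_height=parse_length(raw.acquisition.effective_pixel_height),
    )
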