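"""Unit handling and physical constants.

All lengths are stored internally in metres; configuration files and most
public APIs accept quantity strings with explicit unit suffixes ("86 cm",
"79 um", "17 µm"). Energies are in keV.
"""

from __future__ import annotations

import math
import re

#: hc in keV·Å, so that λ[Å] = HC_KEV_ANGSTROM / E[keV].
HC_KEV_ANGSTROM = 12.398

_LENGTH_UNITS = {
    "m": 1.0,
    "cm": 1e-2,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ]+)\s*$")


def parse_length(value: float | str, default_unit: str | None = None) -> float:
    """Return a length in metres.

    Strings must carry a unit suffix ("3 cm", "79 um"). Bare numbers are
    interpreted in ``default_unit`` if given, otherwise rejected: silent
    unit guessing is how optical benches get mis-set.
    """
    if isinstance(value, str):
        m = _QUANTITY_RE.match(value)
        if not m:
            raise ValueError(f"cannot parse length {value!r}")
        number, unit = float(m.group(1)), m.group(2)
        if unit not in _LENGTH_UNITS:
            raise ValueError(f"unknown length unit {unit!r} in {value!r}")
        return number * _LENGTH_UNITS[unit]
    if default_unit is None:
        raise ValueError(
            f"bare number {value!r} needs an explicit unit suffix (e.g. '79 um')"
        )
    return float(value) * _LENGTH_UNITS[default_unit]


def wavelength_m(energy_kev: float) -> float:
    """Photon wavelength λ in metres for the given energy in keV."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    return HC_KEV_ANGSTROM / energy_kev * 1e-10


def wave_number(energy_kev: float) -> float:
    """Wave number k = 2π/λ in 1/m."""
    return 2.0 * math.pi / wavelength_m(energy_kev)


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian FWHM to its standard deviation."""
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
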