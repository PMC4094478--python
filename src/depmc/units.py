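"""Physical constants and unit-suffixed quantity parsing.

All internal computation is SI; configuration files and CLI arguments carry
explicit unit suffixes (``6.2 um``, ``1 MHz``, ``30 mS/m`` ...) which are
normalized here.
"""

from __future__ import annotations

import re

#: vacuum permittivity (F/m), CODATA 2018
EPS0 = 8.8541878128e-12
#: Boltzmann constant (J/K), exact SI
KB = 1.380649e-23


class UnitError(ValueError):
    """A quantity string is missing a unit or carries an unknown one."""


# unit -> (dimension, factor to SI)
_UNITS: dict[str, tuple[str, float]] = {
    "m": ("length", 1.0),
    "cm": ("length", 1e-2),
    "mm": ("length", 1e-3),
    "um": ("length", 1e-6),
    "µm": ("length", 1e-6),
    "μm": ("length", 1e-6),
    "nm": ("length", 1e-9),
    "s": ("time", 1.0),
    "ms": ("time", 1e-3),
    "min": ("time", 60.0),
    "Hz": ("frequency", 1.0),
    "kHz": ("frequency", 1e3),
    "MHz": ("frequency", 1e6),
    "GHz": ("frequency", 1e9),
    "V": ("voltage", 1.0),
    "mV": ("voltage", 1e-3),
    "kV": ("voltage", 1e3),
    "S/m": ("conductivity", 1.0),
    "mS/m": ("conductivity", 1e-3),
    "uS/m": ("conductivity", 1e-6),
    "Pa*s": ("viscosity", 1.0),
    "Pa.s": ("viscosity", 1.0),
    "mPa*s": ("viscosity", 1e-3),
    "mPa.s": ("viscosity", 1e-3),
    "K": ("temperature", 1.0),
    "cells/ml": ("concentration", 1.0),
    "1/ml": ("concentration", 1.0),
    "": ("dimensionless", 1.0),
}

_QUANTITY_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(\S*)\s*$"
)


def parse_quantity(value, dimension: str) -> float:
    """Parse ``value`` into an SI float of the requested ``dimension``.

    Numbers (int/float) are accepted only for dimensionless quantities;
    everything else must be a string with a unit suffix.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if dimension == "dimensionless":
            return float(value)
        raise UnitError(
            f"quantity {value!r} needs an explicit unit (expected {dimension})"
        )
    if not isinstance(value, str):
        raise UnitError(f"cannot parse quantity from {value!r}")
    m = _QUANTITY_RE.match(value)
    if m is None:
        raise UnitError(f"malformed quantity {value!r}")
    number, unit = m.groups()
    if unit not in _UNITS:
        raise UnitError(f"unknown unit {unit!r} in {value!r}")
    dim, factor = _UNITS[unit]
    if dim != dimension:
        raise UnitError(
            f"unit {unit!r} has dimension {dim}, expected {dimension} in {value!r}"
        )
    return float(number) * factor


def format_quantity(si_value: float, unit: str) -> str:
    """Format an SI value back into a suffixed string (inverse of parsing)."""
    if unit not in _UNITS:
        raise UnitError(f"unknown unit {unit!r}")
    _, factor = _UNITS[unit]
    return f"{si_value / factor!r} {unit}".strip()
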