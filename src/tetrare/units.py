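"""Unit handling for kinetics inputs.

Internal units are mol/L for concentrations and hours for times. Parsers
accept the suffixes practitioners actually write in configs (mM, h, d, yr).
One year is fixed at 8766 h (365.25 days) for every conversion.
"""

from __future__ import annotations

YEAR_HOURS = 8766.0  # 365.25 d
DAY_HOURS = 24.0

_TIME_FACTORS = {
    "h": 1.0,
    "hr": 1.0,
    "hour": 1.0,
    "hours": 1.0,
    "d": DAY_HOURS,
    "day": DAY_HOURS,
    "days": DAY_HOURS,
    "yr": YEAR_HOURS,
    "y": YEAR_HOURS,
    "year": YEAR_HOURS,
    "years": YEAR_HOURS,
}

_CONC_FACTORS = {
    "m": 1.0,
    "mol/l": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "mmol/l": 1e-3,
}


def _split(text: str) -> tuple[float, str]:
    s = str(text).strip()
    i = len(s)
    while i > 0 and not (s[i - 1].isdigit() or s[i - 1] == "."):
        i -= 1
    value, unit = s[:i].strip(), s[i:].strip()
    if not value:
        raise ValueError(f"no numeric part in {text!r}")
    return float(value), unit


def parse_time_h(text: str | float, default_unit: str = "h") -> float:
    """Parse a time with optional unit suffix into hours.

    >>> parse_time_h("1 yr")
    8766.0
    """
    if isinstance(text, (int, float)):
        return float(text) * _TIME_FACTORS[default_unit.lower()]
    value, unit = _split(text)
    unit = (unit or default_unit).lower()
    if unit not in _TIME_FACTORS:
        raise ValueError(f"unknown time unit {unit!r}")
    return value * _TIME_FACTORS[unit]


def parse_concentration_M(text: str | float, default_unit: str = "M") -> float:
    """Parse a concentration with optional suffix into mol/L."""
    if isinstance(text, (int, float)):
        return float(text) * _CONC_FACTORS[default_unit.lower()]
    value, unit = _split(text)
    unit = (unit or default_unit).lower()
    if unit not in _CONC_FACTORS:
        raise ValueError(f"unknown concentration unit {unit!r}")
    return value * _CONC_FACTORS[unit]
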