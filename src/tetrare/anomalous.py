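"""Anomalous-scattering signal arithmetic for wavelength choice.

The anomalous difference peak height of a heavy-atom site is taken as
proportional to occupancy × f″, where f″ is the imaginary part of the
anomalous scattering factor at the chosen wavelength.  Tuning the
wavelength to the Re L_I absorption edge (f″ = 12.1 e at 0.9763 Å)
roughly doubles the expected peak over a Cu Kα home source
(f″ = 5.9 e at 1.5418 Å) — the cancellation of occupancy in the ratio is
what lets low-occupancy sites be found at the optimised wavelength too.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AnomalousPoint",
    "RE_L1_EDGE",
    "CU_KALPHA",
    "enhancement_factor",
    "relative_peak_contribution",
]


@dataclass(frozen=True)
class AnomalousPoint:
    """f″ (electrons) at an X-ray wavelength (Å)."""

    wavelength: float
    f_double_prime: float

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if self.f_double_prime < 0:
            raise ValueError("f_double_prime must be >= 0")


#: Re f″ at the L_I absorption edge, synchrotron-selected wavelength
RE_L1_EDGE = AnomalousPoint(wavelength=0.9763, f_double_prime=12.1)
#: Re f″ at the Cu Kα laboratory wavelength
CU_KALPHA = AnomalousPoint(wavelength=1.5418, f_double_prime=5.9)


def enhancement_factor(
    optimized: AnomalousPoint, reference: AnomalousPoint
) -> float:
    """Expected peak-height multiple from choosing ``optimized`` over
    ``reference``: the ratio of the two f″ values.

    Rounding (e.g. reporting 2.05 as "2.1") is presentation only.
    """
    if not reference.f_double_prime > 0:
        raise ValueError("reference f_double_prime must be positive")
    return optimized.f_double_prime / reference.f_double_prime


def relative_peak_contribution(occupancy: float, point: AnomalousPoint) -> float:
    """Expected effective f″ (electrons) of a partially occupied site:
    occupancy × f″, linear in both arguments."""
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    return occupancy * point.f_double_prime
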