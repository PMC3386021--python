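"""Convert transformation-frequency measurements into gene uptake rates.

In a transformation experiment, exponentially growing cells (division rate
r) are exposed to marker DNA for a time T; a fraction epsilon of colony
forming units has taken up the marker at the end.  With uptake rate sigma,
the marker-free and marker-carrying subpopulations obey
ds/dt = r*s - sigma*s and dm/dt = r*m + sigma*s, so the division rate
cancels and epsilon = 1 - exp(-sigma*T).  Inverting gives the estimator
sigma = -ln(1 - epsilon)/T (units: 1/hour when T is in hours).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["UptakeExperiment", "sigma_from_transformation",
           "transformation_from_sigma", "sigma_order_of_magnitude"]


@dataclass(frozen=True)
class UptakeExperiment:
    """epsilon: transformation frequency in [0, 1); T: exposure time (hours);
    r: division rate (1/hour), informational only — it cancels."""

    epsilon: float
    T: float
    r: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError(
                f"epsilon must be in [0, 1), got {self.epsilon} "
                "(the uptake rate diverges as epsilon -> 1)")
        if not (self.T > 0):
            raise ValueError(f"T must be positive, got {self.T}")


def sigma_from_transformation(exp: UptakeExperiment | None = None, *,
                              epsilon: float | None = None,
                              T: float | None = None) -> float:
    """Gene uptake rate sigma = -ln(1 - epsilon)/T (per hour)."""
    if exp is None:
        exp = UptakeExperiment(epsilon, T)
    return -math.log1p(-exp.epsilon) / exp.T


def transformation_from_sigma(sigma: float, T: float) -> float:
    """Forward map epsilon = 1 - exp(-sigma*T); inverse of the estimator."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not (T > 0):
        raise ValueError("T must be positive")
    return -math.expm1(-sigma * T)


def sigma_order_of_magnitude(sigma: float) -> int:
    """Nearest power of ten, round(log10(sigma)).

    Half-decade ties (e.g. 10**-4.5) round away from zero, so 3.16e-5 reports
    order -5.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = math.log10(sigma)
    return int(math.copysign(math.floor(abs(x) + 0.5), x))
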