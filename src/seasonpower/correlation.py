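"""Dampened autoregressive correlation between repeated seasonal measurements.

The law has two parameters: a base correlation ``rho`` between values one
time unit apart, and a dampening exponent ``theta`` controlling how quickly
the dependence fades with increasing time lag.  At lag ``l`` the correlation
is ``rho ** (l ** theta)``:

* ``theta = 0`` gives compound symmetry — every pair of measurements shares
  the same correlation ``rho`` (the "plug in the ACF directly" mode);
* ``theta = 1`` is an ordinary AR(1) decay ``rho ** l``;
* ``theta > 1`` roughens the decay, ``0 < theta < 1`` smooths it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterDomainError

__all__ = ["SeasonalModel", "correlation_at_lag", "dampened_ar_correlation"]


@dataclass(frozen=True)
class SeasonalModel:
    """Seasonal correlation model with base correlation and dampening.

    Attributes
    ----------
    rho : float
        Correlation between values one time unit apart; must lie in [0, 1).
    theta : float
        Dampening exponent; any non-negative number.
    """

    rho: float
    theta: float

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ParameterDomainError("rho", self.rho, "rho in [0, 1)")
        if self.theta < 0.0:
            raise ParameterDomainError("theta", self.theta, "theta >= 0")


def correlation_at_lag(model: SeasonalModel, lag: float) -> float:
    """Correlation ``rho ** (lag ** theta)`` at a (possibly fractional) lag.

    ``lag = 0`` returns 1 by convention.
    """
    if lag < 0:
        raise ParameterDomainError("lag", lag, "lag >= 0")
    if lag == 0:
        return 1.0
    if model.rho == 0.0:
        return 0.0
    return float(model.rho ** (lag ** model.theta))


def dampened_ar_correlation(model: SeasonalModel, k: int) -> float:
    """Correlation between the first and the last of ``k`` repeated measurements.

    Returns ``rho ** ((k - 1) ** theta)``; ``k = 1`` returns 1.0 (a single
    measurement has no between-measurement correlation, and the lag-0
    correlation of any process is 1).
    """
    if not isinstance(k, (int,)) or isinstance(k, bool):
        raise ParameterDomainError("k", k, "a positive integer")
    if k < 1:
        raise ParameterDomainError("k", k, "k >= 1")
    return correlation_at_lag(model, k - 1)
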