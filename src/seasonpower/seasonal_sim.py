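"""Seasonal population-curve simulator.

Draws one realisation of a stationary Gaussian process whose lag-l
autocorrelation follows the dampened-AR law ``rho ** (l ** theta)``, with
mean equal to the initial population size and marginal variance equal to the
seasonal noise.  Negative draws are truncated at zero (populations are
counts).  This is a visual-elicitation aid: nothing simulated here feeds the
power analysis, which depends only on the analytic correlation law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import SeasonalModel, correlation_at_lag
from .errors import ParameterDomainError

__all__ = ["SeasonalCurveSpec", "SeasonalCurve", "simulate_seasonal_curve"]

_JITTERS = (0.0, 1e-12, 1e-10, 1e-8, 1e-6)


@dataclass(frozen=True)
class SeasonalCurveSpec:
    """Length, level, noise and seed of a simulated seasonal curve."""

    k_max: int
    n_initial: float
    noise: float
    seed: int

    def __post_init__(self):
        if self.k_max < 2:
            raise ParameterDomainError("k_max", self.k_max, "k_max >= 2")
        if self.n_initial <= 0:
            raise ParameterDomainError("N", self.n_initial, "N > 0")
        if self.noise < 0:
            raise ParameterDomainError("noise", self.noise, "noise >= 0")


@dataclass(frozen=True)
class SeasonalCurve:
    """Simulated expected population per survey time unit."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")


def _correlation_matrix(model: SeasonalModel, k_max: int) -> np.ndarray:
    lags = np.abs(np.subtract.outer(np.arange(k_max), np.arange(k_max)))
    corr = np.ones((k_max, k_max))
    pos = lags > 0
    if model.rho == 0.0:
        corr[pos] = 0.0
    else:
        corr[pos] = model.rho ** (lags[pos].astype(float) ** model.theta)
    return corr


def simulate_seasonal_curve(
    spec: SeasonalCurveSpec, model: SeasonalModel
) -> SeasonalCurve:
    """One seeded realisation of the seasonal Gaussian process.

    Identical spec + model + seed give an identical curve.  A jitter ladder
    is applied if the correlation matrix is numerically indefinite; if it
    stays indefinite a diagnostic error is raised.
    """
    times = np.arange(1, spec.k_max + 1)
    if spec.noise == 0.0:
        values = np.full(spec.k_max, float(spec.n_initial))
        return SeasonalCurve(times=times, values=values)
    corr = _correlation_matrix(model, spec.k_max)
    chol = None
    for jitter in _JITTERS:
        try:
            chol = np.linalg.cholesky(corr + jitter * np.eye(spec.k_max))
            break
        except np.linalg.LinAlgError:
            continue
    if chol is None:
        raise np.linalg.LinAlgError(
            f"correlation matrix not positive semi-definite for rho="
            f"{model.rho}, theta={model.theta}, k_max={spec.k_max}, even "
            f"after jitter up to {_JITTERS[-1]}")
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal(spec.k_max)
    values = spec.n_initial + np.sqrt(spec.noise) * (chol @ z)
    values = np.maximum(values, 0.0)
    return SeasonalCurve(times=times, values=values)


def sample_acf(values: np.ndarray, lag: int) -> float:
    """Sample autocorrelation at ``lag`` (test/diagnostic helper)."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        raise ParameterDomainError("values", "constant", "a varying series")
    return float(x[:-lag] @ x[lag:] / denom)


def expected_acf(model: SeasonalModel, lag: int) -> float:
    """Model autocorrelation at integer ``lag`` (the lag-generalised law)."""
    return correlation_at_lag(model, lag)
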