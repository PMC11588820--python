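"""Closed-form sample-size calculations for clustered, seasonal survey designs.

All functions are pure.  Sizes are returned as integers (ceiling of the real
requirement) and never drop below 2, the minimum needed to estimate a
variance.  Standard-normal and t quantiles come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import (
    ConvergenceError,
    DegenerateVarianceError,
    ParameterDomainError,
)

__all__ = [
    "ALLOWED_ALPHAS",
    "MIN_SAMPLE_SIZE",
    "StudySpec",
    "VarianceComponents",
    "TaylorParams",
    "normal_quantile_term",
    "sample_size_ttest",
    "sample_size_taylor",
    "sample_size_seasonal",
    "variance_inflation_factor",
    "intra_cluster_correlation",
    "sample_size_cluster",
    "small_sample_adjustment",
    "variance_ratio",
]

#: Significance levels the tool accepts.
ALLOWED_ALPHAS = (0.1, 0.05, 0.025, 0.001)

#: Smallest sample size ever returned.
MIN_SAMPLE_SIZE = 2

_MAX_ITER = 100_000


def _check_alpha(alpha: float) -> None:
    if alpha not in ALLOWED_ALPHAS:
        raise ParameterDomainError("alpha", alpha, f"one of {ALLOWED_ALPHAS}")


@dataclass(frozen=True)
class StudySpec:
    """Everything the closed-form sample-size formulas consume.

    Attributes
    ----------
    x : float
        Minimum detectable difference, in percent (20 means a 20% change).
    sd_effect_1 : float
        Standard deviation of the effect for species 1, in count units.
    m_1 : int
        Expected catch per site per measurement for species 1 (>= 1).
    rho_c : float
        Between-site clustering (intra-cluster correlation), in [0, 1].
    alpha : float
        Significance level; one of :data:`ALLOWED_ALPHAS`.
    power : float
        Target power 1 - beta, in (0, 1).
    n_species : int
        1 or 2; with 2, the effect is standardized by the mean of the two
        standard deviations and anchored on the mean of the two catches.
    sd_effect_2, m_2 : optional
        Species-2 analogues, required when ``n_species == 2``.
    """

    x: float
    sd_effect_1: float
    m_1: int
    rho_c: float
    alpha: float = 0.05
    power: float = 0.8
    n_species: int = 1
    sd_effect_2: float | None = None
    m_2: int | None = None

    def __post_init__(self):
        if self.x <= 0:
            raise ParameterDomainError("x", self.x, "x > 0 (percent)")
        if self.sd_effect_1 <= 0:
            raise ParameterDomainError(
                "sd_effect_1", self.sd_effect_1, "sd_effect_1 > 0")
        if not (isinstance(self.m_1, int) and self.m_1 >= 1):
            raise ParameterDomainError("m_1", self.m_1, "an integer >= 1")
        if not 0.0 <= self.rho_c <= 1.0:
            raise ParameterDomainError("rho_c", self.rho_c, "rho_c in [0, 1]")
        _check_alpha(self.alpha)
        if not 0.0 < self.power < 1.0:
            raise ParameterDomainError("power", self.power, "power in (0, 1)")
        if self.n_species not in (1, 2):
            raise ParameterDomainError("n_species", self.n_species, "1 or 2")
        if self.n_species == 2:
            if self.sd_effect_2 is None or self.sd_effect_2 <= 0:
                raise ParameterDomainError(
                    "sd_effect_2", self.sd_effect_2,
                    "sd_effect_2 > 0 when n_species == 2")
            if not (isinstance(self.m_2, int) and self.m_2 >= 1):
                raise ParameterDomainError(
                    "m_2", self.m_2, "an integer >= 1 when n_species == 2")

    # -- derived scalars -------------------------------------------------

    @property
    def sd_effect(self) -> float:
        """Effect SD; mean of the two species SDs in two-species mode."""
        if self.n_species == 2:
            return 0.5 * (self.sd_effect_1 + self.sd_effect_2)
        return self.sd_effect_1

    @property
    def mean_catch(self) -> float:
        """Abundance anchor m; mean of the two catches in two-species mode."""
        if self.n_species == 2:
            return 0.5 * (self.m_1 + self.m_2)
        return float(self.m_1)

    @property
    def total_catch(self) -> float:
        """Mosquitoes per trap-visit summed over species."""
        if self.n_species == 2:
            return float(self.m_1 + self.m_2)
        return float(self.m_1)

    @property
    def x_proportion(self) -> float:
        """Detectable difference as a proportion of the mean (x / 100)."""
        return self.x / 100.0

    @property
    def x_absolute(self) -> float:
        """Detectable difference in count units: (x/100) * mean catch."""
        return self.x_proportion * self.mean_catch

    @property
    def x_standardized(self) -> float:
        """Standardized effect: absolute difference over the effect SD."""
        return self.x_absolute / self.sd_effect


@dataclass(frozen=True)
class VarianceComponents:
    """Variance decomposition of the survey outcome.

    ``sigma_b2`` is the between-sample-unit effect variance and ``sigma2``
    the repeated-measurement error variance (the seasonal-design pair);
    ``sigma_T2`` is the total outcome variance and ``tau2`` the
    between-cluster share of it (the cluster-design pair), with
    ``sigma_T2 = tau2 + within-cluster variance``.
    """

    sigma_b2: float
    sigma2: float
    sigma_T2: float
    tau2: float

    def __post_init__(self):
        for name in ("sigma_b2", "sigma2", "sigma_T2", "tau2"):
            if getattr(self, name) < 0:
                raise ParameterDomainError(name, getattr(self, name), ">= 0")
        if self.tau2 > self.sigma_T2 + 1e-12:
            raise ParameterDomainError(
                "tau2", self.tau2, "tau2 <= sigma_T2")


@dataclass(frozen=True)
class TaylorParams:
    """Variance-mean power-law parameters: variance = a * mean**b."""

    a: float
    b: float
    xbar: float

    def __post_init__(self):
        if self.a <= 0:
            raise ParameterDomainError("a", self.a, "a > 0")
        if self.xbar <= 0:
            raise ParameterDomainError("xbar", self.xbar, "xbar > 0")


def normal_quantile_term(alpha: float, power: float) -> float:
    """(Z_{alpha/2} + Z_beta)**2, the squared quantile sum of the normal
    approximation to a two-sided test at level ``alpha`` and power
    ``power``."""
    _check_alpha(alpha)
    if not 0.0 < power < 1.0:
        raise ParameterDomainError("power", power, "power in (0, 1)")
    return float((stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) ** 2)


def _solve_t_circular(multiplier: float, x_std: float, alpha: float) -> int:
    """Smallest n >= 2 with ceil(multiplier * (t_{n-1} / (Z * x))**2) <= n.

    The t-test size formula is circular (its t quantile needs n's degrees
    of freedom).  A naive fixed-point iteration can 2-cycle for large
    standardized effects, so the self-consistent minimum is located by an
    upward scan from the normal-approximation seed; the requirement
    function is decreasing in n, so the scan terminates at the smallest
    solution.
    """
    z = stats.norm.ppf(1 - alpha / 2)

    def requirement(n: int) -> float:
        t_crit = stats.t.ppf(1 - alpha / 2, n - 1)
        return multiplier * (t_crit / (z * x_std)) ** 2

    n = max(MIN_SAMPLE_SIZE, math.ceil(multiplier / x_std**2))
    for _ in range(_MAX_ITER):
        if math.ceil(requirement(n) - 1e-12) <= n:
            return n
        n += 1
    raise ConvergenceError(
        f"t-quantile iteration did not converge within {_MAX_ITER} steps")


def sample_size_ttest(x_std: float, alpha: float) -> int:
    """Two-sample, two-tailed t-test baseline size n = (t / (Z_alpha x))**2.

    ``x_std`` is the standardized effect.  The circular t quantile
    (df = n - 1) is resolved to the smallest self-consistent integer.
    """
    if x_std <= 0:
        raise ParameterDomainError("x_std", x_std, "x_std > 0")
    _check_alpha(alpha)
    return _solve_t_circular(1.0, x_std, alpha)


def sample_size_taylor(taylor: TaylorParams, x_std: float, alpha: float) -> int:
    """Sample size under a variance-mean power law:
    n = a * xbar**(b-2) * (t / (Z_alpha x))**2."""
    if x_std <= 0:
        raise ParameterDomainError("x_std", x_std, "x_std > 0")
    _check_alpha(alpha)
    multiplier = taylor.a * taylor.xbar ** (taylor.b - 2.0)
    return _solve_t_circular(multiplier, x_std, alpha)


def sample_size_seasonal(
    x_abs: float,
    vc: VarianceComponents,
    k: int,
    rho_delta: float,
    alpha: float,
    power: float,
    adjust: bool = False,
) -> int:
    """Units needed for a repeated-measures comparison with ``k`` visits.

    n = (2/x**2) [sigma_b2 + (sigma2/k)(1 + (k-1) rho_delta)]
        (Z_{alpha/2} + Z_beta)**2

    With ``adjust=True`` the small-sample exact-F correction
    (:func:`small_sample_adjustment`) replaces the plain ceiling.
    """
    if x_abs <= 0:
        raise ParameterDomainError("x_abs", x_abs, "x_abs > 0")
    if k < 1:
        raise ParameterDomainError("k", k, "k >= 1")
    if not 0.0 <= rho_delta <= 1.0:
        raise ParameterDomainError("rho_delta", rho_delta, "in [0, 1]")
    quant = normal_quantile_term(alpha, power)
    variance = vc.sigma_b2 + (vc.sigma2 / k) * (1 + (k - 1) * rho_delta)
    n_raw = (2.0 / x_abs**2) * variance * quant
    if adjust:
        return small_sample_adjustment(n_raw, 2, alpha, power)
    return max(MIN_SAMPLE_SIZE, math.ceil(n_raw - 1e-12))


def variance_inflation_factor(m: int, rho_c: float) -> float:
    """Design effect 1 + (m - 1) * rho_c for m correlated units per cluster."""
    if m < 1:
        raise ParameterDomainError("m", m, "m >= 1")
    if not 0.0 <= rho_c <= 1.0:
        raise ParameterDomainError("rho_c", rho_c, "rho_c in [0, 1]")
    return 1.0 + (m - 1) * rho_c


def intra_cluster_correlation(vc: VarianceComponents) -> float:
    """rho_c = tau2 / sigma_T2, the between-cluster share of total variance."""
    if vc.sigma_T2 <= 0:
        raise DegenerateVarianceError("sigma_T2 must be positive")
    return vc.tau2 / vc.sigma_T2


def sample_size_cluster(
    x_abs: float,
    sigma_T2: float,
    m: int,
    rho_c: float,
    alpha: float,
    power: float,
) -> int:
    """Number of clusters (locations) under clustering:

    n_c = (2/x**2) sigma_T2 [1 + (m-1) rho_c] (Z_{alpha/2} + Z_beta)**2

    The full sample size is ``n_c * m``.
    """
    if x_abs <= 0:
        raise ParameterDomainError("x_abs", x_abs, "x_abs > 0")
    if sigma_T2 <= 0:
        raise DegenerateVarianceError("sigma_T2 must be positive")
    vif = variance_inflation_factor(m, rho_c)
    quant = normal_quantile_term(alpha, power)
    n_raw = (2.0 / x_abs**2) * sigma_T2 * vif * quant
    return max(MIN_SAMPLE_SIZE, math.ceil(n_raw - 1e-12))


def _noncentral_f_power(n: int, k: int, lam_per_unit: float, alpha: float) -> float:
    """Power of the one-way exact F test with k groups and n units per group,
    noncentrality lam_per_unit * n."""
    df1 = k - 1
    df2 = k * (n - 1)
    f_crit = stats.f.ppf(1 - alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam_per_unit * n))


def small_sample_adjustment(
    n_raw: float, k: int, alpha: float, power: float
) -> int:
    """Exact-F small-sample correction of a normal-approximation size.

    The effect implied by ``n_raw`` under the normal approximation
    (x**2 = 2 (Z_{alpha/2}+Z_beta)**2 / n_raw, Cohen f**2 = x**2 / 4) is
    carried into the one-way design whose test statistic follows a
    noncentral F distribution; the returned size is the smallest n whose
    exact-F power reaches the target.
    """
    if n_raw <= 0:
        raise ParameterDomainError("n_raw", n_raw, "n_raw > 0")
    if k < 2:
        raise ParameterDomainError("k", k, "k >= 2 groups")
    quant = normal_quantile_term(alpha, power)
    x2 = 2.0 * quant / n_raw
    lam_per_unit = k * (x2 / 4.0)
    upper = max(200, math.ceil(10 * n_raw) + 100)
    for n in range(MIN_SAMPLE_SIZE, upper + 1):
        if _noncentral_f_power(n, k, lam_per_unit, alpha) >= power:
            return n
    raise ConvergenceError(
        f"exact-F power search exhausted n <= {upper} without reaching "
        f"power {power}")


def variance_ratio(vc: VarianceComponents, k: int, rho_delta: float) -> float:
    """Variance of the correlated-repeats test relative to a test of two
    independent means; 1 - VR is the variance reduction bought by the
    repeated measurements."""
    if k < 1:
        raise ParameterDomainError("k", k, "k >= 1")
    if not 0.0 <= rho_delta <= 1.0:
        raise ParameterDomainError("rho_delta", rho_delta, "in [0, 1]")
    total = vc.sigma_b2 + vc.sigma2
    if total <= 0:
        raise DegenerateVarianceError("sigma_b2 + sigma2 must be positive")
    corr = vc.sigma_b2 + (vc.sigma2 / k) * (1 + (k - 1) * rho_delta)
    return corr / total
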