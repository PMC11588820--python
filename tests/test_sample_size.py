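import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from seasonpower import (
    StudySpec,
    TaylorParams,
    VarianceComponents,
    intra_cluster_correlation,
    sample_size_cluster,
    sample_size_seasonal,
    sample_size_taylor,
    sample_size_ttest,
    small_sample_adjustment,
    variance_inflation_factor,
    variance_ratio,
)
from seasonpower.errors import DegenerateVarianceError, ParameterDomainError
from seasonpower.sample_size import normal_quantile_term


# -- independent oracles -------------------------------------------------

def oracle_ttest(multiplier, x_std, alpha, n_max=5000):
    """Brute scan for the smallest self-consistent t-based size."""
    z = stats.norm.ppf(1 - alpha / 2)
    for n in range(2, n_max):
        t_crit = stats.t.ppf(1 - alpha / 2, n - 1)
        if math.ceil(multiplier * (t_crit / (z * x_std)) ** 2 - 1e-12) <= n:
            return n
    raise AssertionError("oracle exhausted")


def oracle_adjustment(n_raw, k, alpha, power, n_max=5000):
    """Brute scan of exact noncentral-F power over n."""
    quant = (stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) ** 2
    f2 = (2 * quant / n_raw) / 4
    for n in range(2, n_max):
        df1, df2 = k - 1, k * (n - 1)
        f_crit = stats.f.ppf(1 - alpha, df1, df2)
        if stats.ncf.sf(f_crit, df1, df2, k * f2 * n) >= power:
            return n
    raise AssertionError("oracle exhausted")


# -- t-test baseline -----------------------------------------------------

def test_ttest_unit_effect_matches_oracle():
    assert sample_size_ttest(1.0, 0.05) == oracle_ttest(1.0, 1.0, 0.05) == 4


def test_ttest_proportional_effect():
    # The reference parameter set's independent-data baseline.
    assert sample_size_ttest(0.2, 0.05) == oracle_ttest(1.0, 0.2, 0.05) == 28


@pytest.mark.parametrize("x", [0.05, 0.1, 0.37, 0.5, 2.0])
@pytest.mark.parametrize("alpha", [0.1, 0.05, 0.025, 0.001])
def test_ttest_matches_oracle_grid(x, alpha):
    assert sample_size_ttest(x, alpha) == oracle_ttest(1.0, x, alpha)


def test_ttest_halving_effect_quadruples_n():
    n1 = sample_size_ttest(0.02, 0.05)
    n2 = sample_size_ttest(0.01, 0.05)
    assert n2 / n1 == pytest.approx(4.0, rel=1e-3)


def test_ttest_large_effect_clamps_at_two():
    assert sample_size_ttest(50.0, 0.05) == 2


def test_ttest_domain_errors():
    with pytest.raises(ParameterDomainError):
        sample_size_ttest(0.0, 0.05)
    with pytest.raises(ParameterDomainError):
        sample_size_ttest(1.0, 0.07)   # alpha not among the app levels


# -- Taylor's power law --------------------------------------------------

def test_taylor_b2_is_scaled_ttest():
    taylor = TaylorParams(a=3.0, b=2.0, xbar=123.0)
    assert sample_size_taylor(taylor, 0.3, 0.05) == \
        oracle_ttest(3.0, 0.3, 0.05)


def test_taylor_poisson_case():
    # a=1, b=1: random (Poisson) spatial pattern, n = (1/xbar)(t/(Z x))^2
    taylor = TaylorParams(a=1.0, b=1.0, xbar=10.0)
    assert sample_size_taylor(taylor, 0.2, 0.05) == \
        oracle_ttest(1 / 10.0, 0.2, 0.05)


def test_taylor_derived_example():
    taylor = TaylorParams(a=2.0, b=1.5, xbar=25.0)
    n = sample_size_taylor(taylor, 0.5, 0.05)
    assert n == oracle_ttest(2.0 * 25.0 ** -0.5, 0.5, 0.05) == 5


def test_taylor_validation():
    with pytest.raises(ParameterDomainError):
        TaylorParams(a=0.0, b=1.0, xbar=5.0)
    with pytest.raises(ParameterDomainError):
        TaylorParams(a=1.0, b=1.0, xbar=0.0)


# -- seasonal repeated-measures size -------------------------------------

VC = VarianceComponents(sigma_b2=1.0, sigma2=1.0, sigma_T2=2.0, tau2=0.5)


def test_seasonal_derived_example():
    # 2 * [1 + 0.25*(1 + 3*0.5)] * (1.959964 + 0.841621)^2 = 25.51 -> 26
    n = sample_size_seasonal(1.0, VC, k=4, rho_delta=0.5,
                             alpha=0.05, power=0.8)
    quant = (stats.norm.ppf(0.975) + stats.norm.ppf(0.8)) ** 2
    assert n == math.ceil(2 * (1 + 0.25 * 2.5) * quant) == 26


def test_seasonal_k1_is_classic_two_sample():
    n = sample_size_seasonal(1.0, VC, k=1, rho_delta=0.7,
                             alpha=0.05, power=0.8)
    quant = (stats.norm.ppf(0.975) + stats.norm.ppf(0.8)) ** 2
    assert n == math.ceil(2 * (VC.sigma_b2 + VC.sigma2) * quant)


def test_seasonal_inverse_k_when_uncorrelated():
    vc = VarianceComponents(sigma_b2=0.0, sigma2=1.0, sigma_T2=1.0, tau2=0.0)
    quant = (stats.norm.ppf(0.975) + stats.norm.ppf(0.8)) ** 2
    for k in (1, 2, 4, 8):
        n = sample_size_seasonal(0.1, vc, k=k, rho_delta=0.0,
                                 alpha=0.05, power=0.8)
        assert n == math.ceil(2 * quant / (k * 0.01) - 1e-12)


@given(
    x=st.floats(0.2, 3.0),
    sb2=st.floats(0.0, 4.0),
    s2=st.floats(0.1, 4.0),
    k=st.integers(1, 30),
    rho=st.floats(0.0, 1.0),
)
@settings(max_examples=60, deadline=None)
def test_seasonal_monotonicities(x, sb2, s2, k, rho):
    vc = VarianceComponents(sigma_b2=sb2, sigma2=s2,
                            sigma_T2=sb2 + s2, tau2=sb2)
    base = sample_size_seasonal(x, vc, k, rho, 0.05, 0.8)
    # non-decreasing in rho_delta
    assert sample_size_seasonal(x, vc, k, min(1.0, rho + 0.1), 0.05, 0.8) >= base
    # non-increasing in k
    assert sample_size_seasonal(x, vc, k + 1, rho, 0.05, 0.8) <= base
    # non-increasing in x
    assert sample_size_seasonal(x * 1.5, vc, k, rho, 0.05, 0.8) <= base


# -- VIF / ICC / cluster size --------------------------------------------

@pytest.mark.parametrize(
    "m, rho_c, expected",
    [(1, 0.9, 1.0), (15, 0.0, 1.0), (15, 0.2, 3.8)],
)
def test_vif(m, rho_c, expected):
    assert variance_inflation_factor(m, rho_c) == pytest.approx(expected)


@pytest.mark.parametrize(
    "tau2, sigma_T2, expected",
    [(0.0, 5.0, 0.0), (3.3, 3.3, 1.0), (2.0, 8.0, 0.25)],
)
def test_icc(tau2, sigma_T2, expected):
    vc = VarianceComponents(sigma_b2=0.0, sigma2=sigma_T2 - tau2,
                            sigma_T2=sigma_T2, tau2=tau2)
    assert intra_cluster_correlation(vc) == pytest.approx(expected)


def test_icc_degenerate():
    vc = VarianceComponents(sigma_b2=0.0, sigma2=0.0, sigma_T2=0.0, tau2=0.0)
    with pytest.raises(DegenerateVarianceError):
        intra_cluster_correlation(vc)


def test_cluster_derived_example():
    # ceil(2 * 1 * 3.8 * 7.84888...) = 60
    assert sample_size_cluster(1.0, 1.0, 15, 0.2, 0.05, 0.8) == 60


def test_cluster_independent_reduces_to_two_sample():
    quant = (stats.norm.ppf(0.975) + stats.norm.ppf(0.8)) ** 2
    n = sample_size_cluster(0.5, 2.0, 7, 0.0, 0.05, 0.8)
    assert n == math.ceil(2 * 2.0 * quant / 0.25)


@given(m=st.integers(1, 40), rho_c=st.floats(0.0, 0.95))
@settings(max_examples=40, deadline=None)
def test_cluster_monotone_in_clustering(m, rho_c):
    base = sample_size_cluster(1.0, 1.0, m, rho_c, 0.05, 0.8)
    assert sample_size_cluster(1.0, 1.0, m + 1, rho_c, 0.05, 0.8) >= base
    assert sample_size_cluster(1.0, 1.0, m, min(1.0, rho_c + 0.05),
                               0.05, 0.8) >= base


def test_cross_formula_consistency():
    # Eq-4 at k=1 and the cluster formula at rho_c=0, m=1 agree when the
    # variance budgets agree (sigma_T2 = sigma_b2 + sigma2).
    vc = VarianceComponents(sigma_b2=0.7, sigma2=1.3, sigma_T2=2.0, tau2=0.0)
    n_seasonal = sample_size_seasonal(0.8, vc, 1, 0.0, 0.05, 0.8)
    n_cluster = sample_size_cluster(0.8, 2.0, 1, 0.0, 0.05, 0.8)
    assert n_seasonal == n_cluster


# -- small-sample exact-F adjustment -------------------------------------

def test_adjustment_derived_example():
    n = small_sample_adjustment(10.0, 2, 0.05, 0.8)
    assert n == oracle_adjustment(10.0, 2, 0.05, 0.8)


@pytest.mark.parametrize("n_raw", [3.0, 7.5, 10.0, 25.0, 60.0])
@pytest.mark.parametrize("k", [2, 3, 5])
def test_adjustment_matches_oracle(n_raw, k):
    assert small_sample_adjustment(n_raw, k, 0.05, 0.8) == \
        oracle_adjustment(n_raw, k, 0.05, 0.8)


def test_adjustment_large_n_near_identity():
    for n_raw in (200.0, 347.2, 512.0):
        adj = small_sample_adjustment(n_raw, 2, 0.05, 0.8)
        assert abs(adj - math.ceil(n_raw)) <= 1


def test_adjustment_monotone_in_alpha_and_power():
    base = small_sample_adjustment(12.0, 2, 0.025, 0.8)
    assert small_sample_adjustment(12.0, 2, 0.05, 0.8) <= base
    assert small_sample_adjustment(12.0, 2, 0.025, 0.9) >= base


# -- variance ratio ------------------------------------------------------

def test_variance_ratio_k1_is_one():
    assert variance_ratio(VC, 1, 0.3) == pytest.approx(1.0)


def test_variance_ratio_perfect_dependence_is_one():
    for k in (2, 5, 12):
        assert variance_ratio(VC, k, 1.0) == pytest.approx(1.0)


def test_variance_ratio_inverse_k():
    vc = VarianceComponents(sigma_b2=0.0, sigma2=1.0, sigma_T2=1.0, tau2=0.0)
    assert variance_ratio(vc, 4, 0.0) == pytest.approx(0.25)


def test_variance_ratio_degenerate():
    vc = VarianceComponents(sigma_b2=0.0, sigma2=0.0, sigma_T2=0.0, tau2=0.0)
    with pytest.raises(DegenerateVarianceError):
        variance_ratio(vc, 3, 0.5)


# -- StudySpec -----------------------------------------------------------

def test_study_spec_derived_scalars():
    spec = StudySpec(x=20.0, sd_effect_1=3.0, m_1=15, rho_c=0.2)
    assert spec.x_proportion == pytest.approx(0.2)
    assert spec.x_absolute == pytest.approx(3.0)
    assert spec.x_standardized == pytest.approx(1.0)
    assert spec.mean_catch == 15.0
    assert spec.total_catch == 15.0


def test_study_spec_two_species_means():
    spec = StudySpec(x=20.0, sd_effect_1=3.0, m_1=15, rho_c=0.2,
                     n_species=2, sd_effect_2=5.0, m_2=25)
    assert spec.sd_effect == pytest.approx(4.0)
    assert spec.mean_catch == pytest.approx(20.0)
    assert spec.total_catch == pytest.approx(40.0)


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(x=0.0), "x"),
        (dict(sd_effect_1=-1.0), "sd_effect_1"),
        (dict(m_1=0), "m_1"),
        (dict(rho_c=1.2), "rho_c"),
        (dict(alpha=0.07), "alpha"),
        (dict(power=1.0), "power"),
        (dict(n_species=3), "n_species"),
        (dict(n_species=2), "sd_effect_2"),
    ],
)
def test_study_spec_validation(kwargs, field):
    base = dict(x=20.0, sd_effect_1=3.0, m_1=15, rho_c=0.2)
    base.update(kwargs)
    with pytest.raises(ParameterDomainError) as err:
        StudySpec(**base)
    assert err.value.field == field


def test_quantile_term_value():
    assert normal_quantile_term(0.05, 0.8) == pytest.approx(7.84888, abs=5e-5)
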