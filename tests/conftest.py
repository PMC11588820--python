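import pytest

from seasonpower import SeasonalModel, StudySpec

#: Parameters of the headline worked example (reference design grid).
REFERENCE_PARAMS = dict(
    x=20.0, sd_effect_1=3.0, m_1=15, rho_c=0.2, alpha=0.05, power=0.8,
    n_species=1,
)

#: (rho, theta) -> (optimal k, optimal locations, effort), 18 published rows.
REFERENCE_GRID = {
    (0.1, 1.00): (19, 15, 285),
    (0.2, 1.00): (18, 16, 288),
    (0.3, 1.00): (18, 16, 288),
    (0.4, 1.00): (17, 17, 289),
    (0.5, 1.00): (16, 18, 288),
    (0.6, 1.00): (15, 19, 285),
    (0.7, 1.00): (14, 21, 294),
    (0.8, 1.00): (13, 22, 286),
    (0.9, 1.00): (12, 24, 288),
    (0.5, 0.50): (15, 19, 285),
    (0.5, 0.75): (15, 19, 285),
    (0.5, 1.25): (17, 17, 289),
    (0.5, 1.50): (18, 16, 288),
    (0.5, 1.75): (18, 16, 288),
    (0.5, 2.00): (18, 16, 288),
    (0.5, 2.25): (18, 16, 288),
    (0.5, 2.50): (19, 15, 285),
}

REFERENCE_K_MAX = 10


@pytest.fixture
def reference_spec() -> StudySpec:
    return StudySpec(**REFERENCE_PARAMS)


@pytest.fixture
def reference_model() -> SeasonalModel:
    """The screenshot parameter set's correlation model."""
    return SeasonalModel(rho=0.2, theta=0.1)
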