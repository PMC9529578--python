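import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from itakit import (
    SyntheticConfig,
    build_design_matrix,
    default_catalog,
    generate_survey,
)


@pytest.fixture(autouse=True)
def _quiet_convergence():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@pytest.fixture(scope="session")
def small_config():
    """A small but non-degenerate survey: 3 themes x 3 vars, 10% prevalence."""
    return SyntheticConfig(
        n_respondents=3000, n_themes=3, vars_per_theme=3, categories_per_var=3,
        n_noise_vars=8, n_redundant_vars=2, theme_effects=(1.2, 1.0, 0.8),
        within_theme_correlation=0.5, target_prevalence=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def small_survey(small_config):
    return generate_survey(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_survey):
    table = small_survey.table.copy()
    table["outcome"] = small_survey.outcome
    return build_design_matrix(table, default_catalog(small_survey))


@pytest.fixture(scope="session")
def logistic_instance():
    """Fixed random logistic-regression problem for solver checks."""
    rng = np.random.default_rng(42)
    n, p = 500, 5
    X = rng.standard_normal((n, p))
    beta = np.array([1.0, -0.5, 0.0, 0.8, 0.0])
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-(X @ beta - 1.0))))
    return X, y
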