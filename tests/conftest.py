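"""Shared fixtures: synthetic trial sets reused across test modules."""

import warnings

import pytest

from onioncnd import GeneratorConfig, assemble, generate_trials, impute
from onioncnd.feature_table import TISSUE_COLUMNS

#: Fixed study seeds for the test suite.
DEFAULT_SEED = 11
SCENARIO_SEED = 7
RECOVERY_SEED = 77


@pytest.fixture(scope="session")
def default_trials():
    """Default multi-environment trial set (~1190 rows, dose gradients, 13% missing)."""
    return generate_trials(GeneratorConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_matrix(default_trials):
    """All-groups feature matrix of the default trials, imputed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = assemble(default_trials.observations)
        return impute(matrix, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def balanced_trials():
    """Balanced-management scenario: uniform recommended N dose, complete records."""
    return generate_trials(GeneratorConfig.balanced_management(seed=SCENARIO_SEED))


@pytest.fixture(scope="session")
def balanced_matrix(balanced_trials):
    """Cultivar + tissue matrix of the balanced-management scenario."""
    matrix = assemble(balanced_trials.observations, groups=("management", "tissue"))
    return matrix.select(["cultivar", *TISSUE_COLUMNS])
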