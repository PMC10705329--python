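import numpy as np
import pytest

import deerpop as dp

# Observed point estimates and the matrix they imply
BASE_RATES = dict(S_f=0.157, S_y=0.952, S_a=0.835, F_y=0.519, F_a=0.597)

# Published per-scenario summaries used by the acceptance tests:
# (mean lambda, IQR low, IQR high, fraction of replicates growing)
PUBLISHED_SUMMARIES = {
    "1": (0.960, 0.949, 0.971, 0.01),
    "2": (0.979, 0.969, 0.990, 0.10),
    "3": (0.933, 0.923, 0.943, 0.00),
    "4": (1.018, 1.008, 1.028, 0.89),
    "5": (1.085, 1.074, 1.095, 1.00),
}

# Published scenario-1 averaged perturbation metrics per parameter
PUBLISHED_SCENARIO1_METRICS = {
    "F_y": (0.022, 0.012),
    "F_a": (0.157, 0.097),
    "S_f": (0.586, 0.109),
    "S_y": (0.100, 0.097),
    "S_a": (0.783, 0.685),
}


@pytest.fixture(scope="session")
def base_matrix() -> np.ndarray:
    return dp.assemble(**BASE_RATES)


@pytest.fixture(scope="session")
def base_vitals() -> dp.StageVitalRates:
    return dp.StageVitalRates(
        S_f=0.157, S_f_bounds=(0.091, 0.273),
        S_y=0.952, S_y_bounds=(0.866, 1.000),
        S_a=0.835, S_a_bounds=(0.748, 0.931),
    )


@pytest.fixture(scope="session")
def scenario_results() -> dict[str, dp.ProjectionResult]:
    """All five built-in scenarios at full replication (shared across
    acceptance tests to avoid recomputation)."""
    return {k: dp.run_scenario(s) for k, s in dp.builtin_scenarios(seed=20260926).items()}
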