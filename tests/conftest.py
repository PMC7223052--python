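import numpy as np
import pytest

import pwbi
from pwbi.sem import ParameterSet


@pytest.fixture(scope="session")
def default_params() -> pwbi.PopulationParams:
    return pwbi.PopulationParams()


@pytest.fixture(scope="session")
def spec() -> pwbi.ModelSpec:
    return pwbi.DEFAULT_MODEL


@pytest.fixture(scope="session")
def true_params(default_params, spec) -> ParameterSet:
    """Standardized generating parameters as a ParameterSet."""
    return ParameterSet.from_population(default_params, spec)


@pytest.fixture(scope="session")
def cohort_1248(default_params):
    """One seeded study-sized cohort with its true latent scores."""
    cohort, wbi = pwbi.generate_cohort(default_params, 1248, 3, return_latent=True)
    return cohort, wbi


@pytest.fixture(scope="session")
def indicators_1248(cohort_1248):
    cohort, _ = cohort_1248
    return pwbi.score_cohort(cohort)


@pytest.fixture(scope="session")
def fitted_1248(indicators_1248, spec):
    return pwbi.fit_from_data(indicators_1248, spec)


def run_recovery(default_params, spec, n_reps: int, n: int, seed0: int = 1):
    """Simulate-and-refit: return per-replicate standardized betas."""
    betas = {k: [] for k in spec.factors}
    for i in range(n_reps):
        cohort = pwbi.generate_cohort(default_params, n, seed0 + i)
        ind = pwbi.score_cohort(cohort)
        est, res = pwbi.fit_from_data(ind, spec)
        assert res.converged, f"fit did not converge for seed {seed0 + i}"
        for k in spec.factors:
            betas[k].append(est.betas[k])
    return {k: np.array(v) for k, v in betas.items()}
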