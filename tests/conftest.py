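import numpy as np
import pytest

from markovcea import (
    build_transition_matrix,
    reference_case,
    resolve_strategies,
    run_strategy,
)


@pytest.fixture(scope="session")
def ref_config():
    return reference_case()


@pytest.fixture(scope="session")
def strategies(ref_config):
    """Calibrated (OPD, LPD) strategy parameter pair."""
    return resolve_strategies(ref_config)


@pytest.fixture(scope="session")
def opd_matrix():
    return build_transition_matrix(14, 22)


@pytest.fixture(scope="session")
def baseline_results(strategies):
    """(trace, EconResult) per strategy at the 120-cycle horizon."""
    return {s.label: run_strategy(s) for s in strategies}


def random_valid_matrix(rng: np.random.Generator):
    """A random row-stochastic 3-state matrix with the structural zeros."""
    p_dfs_pd, p_dfs_d = rng.dirichlet([1, 1, 1])[:2]
    p_pd_d = rng.uniform(0, 1)
    from markovcea import TransitionMatrix

    return TransitionMatrix(p_dfs_pd=p_dfs_pd, p_dfs_d=p_dfs_d, p_pd_d=p_pd_d)
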