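import numpy as np
import pytest

from promedip import (
    SimulationConfig,
    assign_truth,
    ks_probe_scores,
    normalize_center,
    simulate_tiling_experiment,
    truth_promoters,
)


@pytest.fixture(scope="session")
def fast_cfg():
    """Reduced-geometry simulation used by unit tests (fast, deterministic)."""
    return SimulationConfig.fast(n_genes=60, seed=5)


@pytest.fixture(scope="session")
def fast_truth(fast_cfg):
    return assign_truth(fast_cfg)


@pytest.fixture(scope="session")
def fast_experiment(fast_cfg, fast_truth):
    return simulate_tiling_experiment(fast_cfg, fast_truth, stages=["MBT"])["MBT"]


@pytest.fixture(scope="session")
def fast_profiles(fast_experiment):
    rep1, rep2 = fast_experiment
    return (
        ks_probe_scores(normalize_center(rep1)),
        ks_probe_scores(normalize_center(rep2)),
    )


@pytest.fixture(scope="session")
def fast_promoters(fast_truth):
    return truth_promoters(fast_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
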