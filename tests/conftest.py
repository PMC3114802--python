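import numpy as np
import pytest

from qanet.synth import TruthConfig, make_chip_layout, simulate_experiment_set


@pytest.fixture(scope="session")
def small_layout():
    """A scaled-down chip: 400 gene features (2% duplicated), 60 negatives."""
    return make_chip_layout(400, 60, 0.02, seed=101)


@pytest.fixture(scope="session")
def small_truth_config():
    return TruthConfig(
        n_qa_immediate=8, n_qa_gradual=3, n_qa_delayed=3, n_qa_concave=2,
        n_leaky=2, n_starvation=8, n_both=2, n_down_in_control=3,
        n_qa1f_spurious=1,
    )


@pytest.fixture(scope="session")
def small_simulation(small_layout, small_truth_config):
    """One noisy four-experiment simulation reused across read-only tests."""
    chipset, truth = simulate_experiment_set(
        small_layout, small_truth_config, noise_sd_log2=0.4, seed=202)
    return chipset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
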