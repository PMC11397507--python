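import numpy as np
import pytest

from presaccsf.csf import CSFParams
from presaccsf.qcsf import ParamGrid, QCSFEngine, build_stimulus_space
from presaccsf.synth import EffectConfig, ExperimentConfig, make_population


@pytest.fixture(scope="session")
def example_params() -> CSFParams:
    """peakCS=100, peakSF=2 cpd, FWHM bandwidth=1 decade."""
    return CSFParams.from_linear(100.0, 2.0, 1.0)


@pytest.fixture(scope="session")
def stimulus_space():
    return build_stimulus_space()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse parameter grid; fast enough for per-test adaptive loops."""
    return ParamGrid.regular((15, 12, 8))


@pytest.fixture(scope="session")
def small_engine(small_grid, stimulus_space):
    return QCSFEngine(grid=small_grid, space=stimulus_space)


@pytest.fixture(scope="session")
def tiny_config():
    return ExperimentConfig(n_participants=2, trials_per_individual=25)


@pytest.fixture(scope="session")
def tiny_population(tiny_config):
    return make_population(tiny_config, EffectConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_valid_params(rng, n):
    """Uniform draws inside the parameter truncation boxes."""
    from presaccsf.csf import PARAM_BOUNDS

    lo, hi = PARAM_BOUNDS[:, 0], PARAM_BOUNDS[:, 1]
    return lo + (hi - lo) * rng.random((n, 3))
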