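import numpy as np
import pytest

from painflow import PipelineConfig, SimConfig, simulate_study
from painflow.simulate import make_partition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A toy study small enough for per-test pipeline runs."""
    return SimConfig(
        n_patients=3,
        n_controls=3,
        n_nodes=21,
        community_sizes=[3, 3, 3, 3, 3, 3, 3],
        n_trs=80,
        n_events_per_run=6,
        n_painful=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cfg):
    return simulate_study(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_partition(tiny_cfg):
    return make_partition(tiny_cfg)


@pytest.fixture
def fast_pipeline_cfg():
    return PipelineConfig(levels=("community",), contrasts=("group",), metrics=("pc",))
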