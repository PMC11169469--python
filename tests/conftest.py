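import pytest
from hypothesis import HealthCheck, settings

import orthosplice as osp
from orthosplice.pipeline import run_study, workspace_from_study

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> osp.SimConfig:
    return osp.SimConfig(seed=11, n_genes=60, n_planted_conserved=8,
                         n_decoy_events=30)


@pytest.fixture(scope="session")
def small_study(small_config):
    return osp.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_result(small_study):
    return run_study(workspace_from_study(small_study))


@pytest.fixture
def toy_genome() -> osp.GenomeSource:
    # one gene on each strand: flank [0,3), intron, target [6,9),
    # intron, flank [12,15)
    return osp.GenomeSource("toy", {
        "chr1": "AAATTTCCCTTTGGG",
        "chr2": "AACCGGTT",
    })
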