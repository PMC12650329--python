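import pytest

from pufminer.profiles import build_profile
from pufminer.report import PipelineConfig, run_pipeline
from pufminer.simulate import SimConfig, generate_dataset

#: fixed seed for the test-suite instance of the default study conditions
TEST_SEED = 1


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(rng_seed=TEST_SEED)


@pytest.fixture(scope="session")
def dataset(sim_config):
    return generate_dataset(sim_config)


@pytest.fixture(scope="session")
def rc_profile(dataset):
    return build_profile(dataset.rc_seed, name="RC_domain")


@pytest.fixture(scope="session")
def ompa_profile(dataset):
    return build_profile(dataset.ompa_seed, name="OmpA_like")


@pytest.fixture(scope="session")
def pipeline(sim_config, dataset):
    return run_pipeline(PipelineConfig(sim=sim_config), dataset=dataset)


def base_id(seq_id: str) -> str:
    """Strip the N_/C_ fusion-domain prefix."""
    return seq_id[2:] if seq_id.startswith(("N_", "C_")) else seq_id


def true_group(truth, seq_id):
    """(family, clade) a sequence or split domain truly belongs to."""
    t = truth.sequences[base_id(seq_id)]
    family = t.family
    if family == "fusion":
        family = "PufL" if seq_id.startswith("N_") else "PufM"
    return family, t.clade
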