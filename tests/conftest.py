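import numpy as np
import pytest
from hypothesis import settings

import neuronorm as nn

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def atlas():
    return nn.default_atlas()


@pytest.fixture(scope="session")
def small_reference(atlas):
    """Healthy reference cohort, small but big enough to train on."""
    spec = nn.SimulationSpec(group_sizes={"HC": 300}, atlas=atlas, seed=11,
                             name="smallref")
    return nn.generate_reference_cohort(spec)


@pytest.fixture(scope="session")
def quick_config():
    """Short AAE schedule for fast plumbing tests."""
    return nn.AAEConfig(epochs=5, batch_size=64, seed=21)


@pytest.fixture(scope="session")
def trained_small_model(small_reference):
    """One non-degenerate trained model shared across tests."""
    cfg = nn.AAEConfig(epochs=60, batch_size=128, seed=13)
    return nn.train(small_reference, cfg)


@pytest.fixture(scope="session")
def graded_clinical(atlas):
    """Clinical cohort with EMCI/LMCI/AD analogues at graded severity."""
    spec = nn.graded_ad_spec(n_per_group=80, seed=17, atlas=atlas,
                             name="clinical")
    return nn.generate_clinical_cohort(spec)


def make_cohort_frame(cohort):
    return cohort.to_frame()
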