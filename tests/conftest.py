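import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hdseizure import (SynthConfig, build_item_memory, generate,
                       learn_prototypes_from_intervals, run_detection)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def im_small():
    """Didactic memory: L=3 (4 symbols), 3 electrodes, D=10,000."""
    return build_item_memory(L=3, n_electrodes=3, D=10_000, seed=7)


@pytest.fixture(scope="session")
def im_clinical():
    """Clinical-scale memory: L=9 (256 symbols), 60 electrodes, D=10,000."""
    return build_item_memory(L=9, n_electrodes=60, D=10_000, seed=1)


class E2E:
    """One full train-on-seizure-1 / detect-on-seizure-2 run, shared by tests."""

    def __init__(self):
        self.im = build_item_memory(L=9, n_electrodes=60, D=10_000, seed=1)
        train_cfg = SynthConfig(duration_s=75.0, seizures=((40.0, 70.0),), seed=101)
        self.train_rec, self.train_labels = generate(train_cfg)
        self.p_int, self.p_ict = learn_prototypes_from_intervals(
            self.train_rec, self.im, interictal_ref=(5.0, 35.0),
            ictal_ref=(40.0, 70.0), window_s=1.0, tie_seed=2)
        test_cfg = SynthConfig(duration_s=60.0, seizures=((20.0, 40.0),), seed=202)
        self.test_rec, self.test_labels = generate(test_cfg)
        self.trace = run_detection(self.test_rec, self.im, self.p_int,
                                   self.p_ict, tie_seed=5)


@pytest.fixture(scope="session")
def e2e():
    return E2E()
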