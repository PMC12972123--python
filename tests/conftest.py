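import numpy as np
import pytest

import informrc as rc


@pytest.fixture(scope="session")
def dataset():
    """Full synthetic dataset (20 main + 4 transition trials), fixed seed."""
    return rc.generate_dataset(seed=777)


@pytest.fixture(scope="session")
def series(dataset):
    """Splits, normaliser and merged series for the session dataset."""
    return rc.prepare_series(dataset, seed=5)


@pytest.fixture(scope="session")
def arm():
    return rc.ArmModel()


@pytest.fixture()
def tiny_configs():
    """Small reservoirs for fast architecture-level tests."""
    def make(arch_name):
        cfg = rc.ReservoirConfig(n_neurons=40, spectral_radius=0.9,
                                 connectivity=0.2, input_scaling=0.3,
                                 feedback_scaling=0.3, leak_rate=0.6, seed=0)
        if arch_name == "InFoRM":
            return {"inform": cfg}
        return {"inverse": cfg, "forward": cfg}
    return make
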