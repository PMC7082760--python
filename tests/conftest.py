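import numpy as np
import pytest

from dlvm import DGPParams, DLVMConfig, fit_dlvm, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient confounded cohort with constant effect tau=1."""
    return generate_cohort(DGPParams(n=300, seed=42))


@pytest.fixture(scope="session")
def tiny_config():
    """A deliberately small DLVM for fast structural tests."""
    return DLVMConfig.desk_scale(
        seed=0, dim_Z=6, dim_z1=6, dim_z2=6, hidden_sizes=(24, 12),
        epochs=6, batch_size=64,
    )


@pytest.fixture(scope="session")
def tiny_model(small_cohort, tiny_config):
    """One fitted model shared by the structural/inference tests."""
    rng = np.random.default_rng(1)
    idx = rng.permutation(small_cohort.n)
    valid = small_cohort.subset(idx[:60])
    train = small_cohort.subset(idx[60:])
    return fit_dlvm(train, valid, tiny_config)
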