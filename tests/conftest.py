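import numpy as np
import pytest

import qtune
from qtune.objective import LossConfig, OptimizerSettings
from qtune.synthetic import recovery_config


@pytest.fixture(scope="session")
def small_dataset():
    """Small split-assigned synthetic dataset for unit tests."""
    cfg = qtune.GeneratorConfig(n_molecules=8, atoms_min=4, atoms_max=8, m=8,
                                n_clusters=3, n_frames=60, seed=42)
    ds = qtune.generate_dataset(cfg)
    return qtune.assign_splits(ds, 0.5, seed=7)


@pytest.fixture(scope="session")
def small_basis(small_dataset):
    return qtune.fit_basis(qtune.pool_embeddings(small_dataset), 3)


@pytest.fixture(scope="session")
def small_loss_config():
    """Loss config whose ESS thresholds fit the 60-frame unit fixture."""
    return LossConfig(a_onset=40.0, ess_stop=30.0)


@pytest.fixture(scope="session")
def recovery_run():
    """Full fitted recovery experiment: hidden true perturbation, 75% train.

    Session-scoped because several statistical checks reuse the same
    fitted parameters.
    """
    cfg = recovery_config(seed=11)
    ds = qtune.assign_splits(qtune.generate_dataset(cfg), 0.75, seed=11)
    basis = qtune.fit_basis(qtune.pool_embeddings(ds), cfg.theta_true.r)
    lc = LossConfig(k_reg=100.0, a_onset=750.0, ess_stop=500.0)
    theta, trace = qtune.finetune(ds, basis, lc, OptimizerSettings(max_iter=200))
    return {"config": cfg, "dataset": ds, "basis": basis, "theta": theta,
            "trace": trace, "loss_config": lc}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
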