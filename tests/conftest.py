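"""Shared fixtures: a small synthetic heart/torso environment.

All fixtures are deterministic (fixed seeds) and generated at test time;
nothing is read from disk.
"""

import numpy as np
import pytest

from p2an.pipeline import ExperimentConfig, build_environment


@pytest.fixture(scope="session")
def small_config() -> ExperimentConfig:
    """Smoke-scale setting: 32 heart nodes, 16 electrodes, 2 ms / 400 ms grid."""
    return ExperimentConfig(
        m_nodes=32,
        n_electrodes=16,
        dt=2.0,
        duration=400.0,
        apd=200.0,
        n_eval_cases=4,
        n_train_cases=12,
        lesion_radius=25.0,
        seed=7,
        p2an={"n_res": 2, "n_attn": 2, "d_k": 16, "d_ff": 32, "epochs": 8},
        ista={"epochs": 8},
        ffnn={"hidden_sizes": (64,), "epochs": 8},
    )


@pytest.fixture(scope="session")
def small_env(small_config):
    return build_environment(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
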