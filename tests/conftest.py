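import logging

import numpy as np
import pytest

from gaitphase.nn.network import ModelConfig, TrainConfig
from gaitphase.pipeline import run_split
from gaitphase.synthetic import SyntheticConfig, simulate_dataset, simulate_subject
from gaitphase.windowing import WindowSpec

logging.getLogger("gaitphase").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def noiseless_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        n_subjects=2, duration_s=10.0, noise_sd_imu=0.0, noise_sd_force=0.0, seed=3
    )


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_cfg):
    return simulate_subject(noiseless_cfg, 0)


def tiny_model_cfg(**overrides) -> ModelConfig:
    defaults = dict(
        conv_filters=(2, 2, 4, 4, 4, 4),
        dense_units=(8, 8),
        lstm_units=4,
        seed=0,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


@pytest.fixture(scope="session")
def trained_run():
    """One reduced end-to-end training run shared by the expensive tests.

    11 synthetic subjects, 10 train + 1 unseen, 10 epochs; reaches > 0.90
    plain accuracy on the held-out subject in about two minutes on one CPU.
    """
    cfg = SyntheticConfig(
        n_subjects=11,
        duration_s=20.0,
        noise_sd_imu=0.05,
        noise_sd_force=0.005,
        subject_gain_sd=0.1,
        seed=42,
    )
    dataset = simulate_dataset(cfg)
    model_cfg = ModelConfig(
        conv_filters=(6, 6, 12, 12, 24, 24), dense_units=(64, 32), seed=0
    )
    train_cfg = TrainConfig(epochs=10, batch_size=4, seed=0)
    wspec = WindowSpec(window_len=30, shift=4)
    result = run_split(
        dataset,
        unseen_subject="subject_10",
        model_cfg=model_cfg,
        train_cfg=train_cfg,
        window_spec=wspec,
        seq_len=48,
        split_seed=0,
    )
    result["dataset"] = dataset
    result["synth_cfg"] = cfg
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
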