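import numpy as np
import pytest

import poligen as pg
from poligen.networks import DenoiserConfig, EncoderConfig
from poligen.schedule import NoiseSchedule
from poligen.train import TrainConfig, train

# Scaled-down study conditions: 200 two-family synthetic complexes, a
# 2-layer denoiser with latent size k=16 and a T=50 schedule.  Trained once
# per session and shared by every conditioning/efficacy test.
TOY_DATA_SEED = 0
TOY_TRAIN_SEED = 1
TOY_T = 50
TOY_ENCODER = dict(layers=3, hidden=32, edge_dim=8, k=16, n_rbf=8)
TOY_DENOISER = dict(layers=2, hidden=48, edge_dim=16, k=16, n_rbf=8)
TOY_TRAIN = dict(epochs=40, batch_size=8, lr=2e-3, seed=TOY_TRAIN_SEED,
                 lam_min=0.25)


@pytest.fixture(scope="session")
def toy_dataset():
    rng = np.random.default_rng(TOY_DATA_SEED)
    complexes, prior = pg.make_dataset(200, rng)
    return complexes, prior


@pytest.fixture(scope="session")
def toy_checkpoint(toy_dataset):
    complexes, prior = toy_dataset
    sched = NoiseSchedule(T=TOY_T)
    return train(complexes, TrainConfig(**TOY_TRAIN), schedule=sched,
                 prior=prior,
                 encoder_config=EncoderConfig(**TOY_ENCODER),
                 denoiser_config=DenoiserConfig(**TOY_DENOISER))


@pytest.fixture(scope="session")
def toy_model(toy_checkpoint):
    return toy_checkpoint.build()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
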