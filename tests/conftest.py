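"""Shared fixtures.

The expensive fixtures (a trained encoder/prior on the high-SNR scaled
dataset) are session-scoped so the end-to-end property tests share one
training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from eeg2img import (MONTAGE_18, NERVConfig, OptConfig, PriorConfig,
                     assemble_dataset, build_encoder, build_prior,
                     fit_contrastive, make_concept_bank, make_forward_model,
                     train_prior)
from eeg2img.contrastive import embed_split
from eeg2img.prior import PriorOptConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_bank():
    return make_concept_bank(K=12, D_img=16, n_test=4, seed=0)


@pytest.fixture()
def small_fm():
    return make_forward_model(MONTAGE_18, sampling_rate=50.0, rank=4,
                              d_img=16, posterior_boost=2.0, noise_sd=0.1,
                              seed=1)


@pytest.fixture()
def tiny_dataset(small_bank, small_fm):
    return assemble_dataset(small_bank, small_fm, images_per_train_cat=2,
                            reps=2, n_subjects=2, seed=3)


#: the high-SNR zero-shot study condition: noise-free trials through an
#: invertible (full sensor rank) forward model, 200 train categories x 2
#: images, 20 held-out test categories, posterior_boost 4.
HIGHSNR = dict(n_categories=220, d_img=64, n_test=20, cluster_spread=0.5,
               rank=18, posterior_boost=4.0, noise_sd=0.0,
               images_per_train_cat=2, n_subjects=1, epochs=80,
               batch_size=128)


@pytest.fixture(scope="session")
def highsnr_dataset():
    bank = make_concept_bank(HIGHSNR["n_categories"], HIGHSNR["d_img"],
                             HIGHSNR["n_test"], seed=0,
                             cluster_spread=HIGHSNR["cluster_spread"])
    fm = make_forward_model(MONTAGE_18, sampling_rate=100.0,
                            rank=HIGHSNR["rank"], d_img=HIGHSNR["d_img"],
                            posterior_boost=HIGHSNR["posterior_boost"],
                            noise_sd=HIGHSNR["noise_sd"], seed=1)
    ds = assemble_dataset(bank, fm,
                          images_per_train_cat=HIGHSNR["images_per_train_cat"],
                          reps=1, n_subjects=HIGHSNR["n_subjects"], seed=2)
    return bank, fm, ds


@pytest.fixture(scope="session")
def trained_pipeline(highsnr_dataset):
    """Encoder + head trained contrastively, prior trained on its outputs."""
    _, _, ds = highsnr_dataset
    encoder = build_encoder(
        NERVConfig.mini(n_subjects=HIGHSNR["n_subjects"]), seed=0)
    result = fit_contrastive(encoder, ds,
                             OptConfig(epochs=HIGHSNR["epochs"],
                                       batch_size=HIGHSNR["batch_size"],
                                       seed=0))
    E_train, I_train = embed_split(encoder, result.head, ds, "train")
    prior = build_prior(PriorConfig(embed_dim=E_train.shape[1],
                                    hidden_dim=256, seed=0))
    train_prior(prior, E_train, np.tile(I_train, (ds.train.n_subjects, 1)),
                PriorOptConfig(lr=1e-3, steps=800, batch_size=256,
                               cond_noise_sd=0.2, seed=0))
    return ds, encoder, result.head, prior
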