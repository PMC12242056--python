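"""Synthetic dataset generator: contracts, determinism, latent structure."""

import numpy as np
import pytest

from eeg2img import (EEGTrial, MONTAGE_18, MONTAGE_64, POSTERIOR_CHANNELS,
                     assemble_dataset, average_repetitions,
                     dataset_image_manifest, make_concept_bank,
                     make_forward_model, make_tag_cards, sample_eeg_trial,
                     sample_image_embedding)
from eeg2img.exceptions import ConsistencyError
from eeg2img.montage import posterior_indices
from eeg2img.synthetic import (DEFAULT_TAG_VOCABULARY,
                               REFERENCE_IMAGES_PER_TRAIN_CATEGORY,
                               REFERENCE_N_TEST_CATEGORIES,
                               REFERENCE_N_TRAIN_CATEGORIES, TagCard,
                               TagVocabulary)


class TestConceptBank:
    def test_smallest_legal_bank(self):
        bank = make_concept_bank(K=2, D_img=4, n_test=1, seed=0)
        assert np.allclose(np.linalg.norm(bank.concepts, axis=1), 1.0)
        assert len(bank.train_category_ids) == 1
        assert len(bank.test_category_ids) == 1

    def test_reference_split_sizes(self):
        bank = make_concept_bank(K=1854, D_img=16, n_test=200, seed=1)
        assert len(bank.train_category_ids) == 1654
        assert len(bank.test_category_ids) == 200

    def test_deterministic_given_seed(self):
        b1 = make_concept_bank(20, 8, 5, seed=7)
        b2 = make_concept_bank(20, 8, 5, seed=7)
        assert np.array_equal(b1.concepts, b2.concepts)
        assert np.array_equal(b1.is_test, b2.is_test)

    def test_split_disjoint(self, small_bank):
        assert not set(small_bank.train_category_ids) & \
            set(small_bank.test_category_ids)

    @pytest.mark.parametrize("K,n_test", [(5, 0), (5, 5), (5, 6), (1, 1)])
    def test_invalid_counts_rejected(self, K, n_test):
        with pytest.raises(ValueError):
            make_concept_bank(K, 8, n_test, seed=0)


class TestImageEmbedding:
    def test_zero_noise_returns_concept(self, small_bank, rng):
        cat = int(small_bank.category_ids[0])
        emb = sample_image_embedding(small_bank, cat, 0.0, rng)
        assert np.allclose(emb, small_bank.concept_for(cat))

    def test_unit_norm_for_any_sigma(self, small_bank, rng):
        for sigma in (0.0, 0.1, 3.0):
            emb = sample_image_embedding(small_bank, 0, sigma, rng)
            assert np.linalg.norm(emb) == pytest.approx(1.0, abs=1e-6)

    def test_small_noise_stays_near_concept(self, small_bank, rng):
        cat = 0
        concept = small_bank.concept_for(cat)
        sims = [sample_image_embedding(small_bank, cat, 0.1, rng) @ concept
                for _ in range(1000)]
        # Monte-Carlo oracle, D_img=16: E[cos] ~ 1/sqrt(1 + sigma^2 D) = 0.928
        assert np.mean(sims) == pytest.approx(0.93, abs=0.02)

    def test_unknown_category(self, small_bank, rng):
        with pytest.raises(KeyError):
            sample_image_embedding(small_bank, 10_000, 0.1, rng)


class TestEEGTrial:
    def test_noiseless_trial_is_deterministic(self, small_bank):
        fm = make_forward_model(MONTAGE_18, 50.0, 4, 16, posterior_boost=1.0,
                                noise_sd=0.0, seed=1)
        t1 = sample_eeg_trial(small_bank, 0, fm, 0, np.random.default_rng(0))
        t2 = sample_eeg_trial(small_bank, 0, fm, 0, np.random.default_rng(9))
        assert np.array_equal(t1.data, t2.data)

    def test_categories_distinguishable_at_zero_noise(self, small_bank):
        fm = make_forward_model(MONTAGE_18, 50.0, 4, 16, posterior_boost=1.0,
                                noise_sd=0.0, seed=1)
        rng = np.random.default_rng(0)
        t0 = sample_eeg_trial(small_bank, 0, fm, 0, rng)
        t1 = sample_eeg_trial(small_bank, 1, fm, 0, rng)
        assert not np.allclose(t0.data, t1.data)

    def test_posterior_snr_ratio(self, small_bank):
        """posterior_boost=4 means ~16x signal power on posterior channels."""
        fm = make_forward_model(MONTAGE_18, 50.0, 4, 16, posterior_boost=4.0,
                                noise_sd=1.0, seed=1)
        clean = make_forward_model(MONTAGE_18, 50.0, 4, 16,
                                   posterior_boost=4.0, noise_sd=0.0, seed=1)
        rng = np.random.default_rng(0)
        post = posterior_indices(MONTAGE_18)
        other = [i for i in range(18) if i not in post]
        ratios = []
        for _ in range(200):
            cat = int(rng.choice(small_bank.category_ids))
            sig = sample_eeg_trial(small_bank, cat, clean, 0, rng).data
            p_post = np.mean(sig[post] ** 2)
            p_other = np.mean(sig[other] ** 2)
            ratios.append(p_post / p_other)
        # loadings are random, so compare mean power ratios, not per trial
        assert np.mean(ratios) == pytest.approx(16.0, rel=0.5)

    def test_posterior_variance_share_increases_with_boost(self, small_bank):
        shares = []
        for boost in (1.0, 2.0, 4.0):
            fm = make_forward_model(MONTAGE_18, 50.0, 4, 16,
                                    posterior_boost=boost, noise_sd=0.0,
                                    seed=1)
            rng = np.random.default_rng(0)
            post = posterior_indices(MONTAGE_18)
            data = np.stack([
                sample_eeg_trial(small_bank, int(c), fm, 0, rng).data
                for c in small_bank.category_ids])
            total = np.sum(data ** 2)
            shares.append(np.sum(data[:, post] ** 2) / total)
        assert shares[0] < shares[1] < shares[2]


class TestAverageRepetitions:
    def test_mean_of_identical_trials(self, small_bank, small_fm, rng):
        t = sample_eeg_trial(small_bank, 0, small_fm, 0, rng)
        avg = average_repetitions([t, t])
        assert np.array_equal(avg.data, t.data)
        assert avg.n_repetitions_averaged == 2

    def test_elementwise_mean(self, small_fm):
        mk = lambda v: EEGTrial(np.full((18, 50), v), MONTAGE_18, 50.0,
                                0, 0, 0)
        avg = average_repetitions([mk(0.0), mk(2.0)])
        assert np.array_equal(avg.data, np.ones((18, 50)))

    def test_noise_shrinks_like_sqrt_R(self, small_bank):
        """Averaging R=4 repetitions halves the residual noise SD."""
        fm = make_forward_model(MONTAGE_18, 50.0, 4, 16, posterior_boost=1.0,
                                noise_sd=1.0, seed=1)
        clean = sample_eeg_trial(small_bank, 0,
                                 make_forward_model(MONTAGE_18, 50.0, 4, 16,
                                                    posterior_boost=1.0,
                                                    noise_sd=0.0, seed=1),
                                 0, np.random.default_rng(0))
        rng = np.random.default_rng(0)
        sds = {}
        for R in (1, 4):
            resid = []
            for _ in range(200):
                avg = average_repetitions([
                    sample_eeg_trial(small_bank, 0, fm, 0, rng)
                    for _ in range(R)])
                resid.append(np.std(avg.data - clean.data))
            sds[R] = np.mean(resid)
        assert sds[1] / sds[4] == pytest.approx(2.0, rel=0.2)

    def test_mismatched_metadata_rejected(self, small_bank, small_fm, rng):
        t0 = sample_eeg_trial(small_bank, 0, small_fm, 0, rng, image_id=0)
        t1 = sample_eeg_trial(small_bank, 0, small_fm, 1, rng, image_id=0)
        with pytest.raises(ConsistencyError):
            average_repetitions([t0, t1])


class TestAssembleDataset:
    def test_reference_image_count(self):
        """1654 train cats x 10 images + 200 test cats x 1 = 16,740 images."""
        bank = make_concept_bank(
            REFERENCE_N_TRAIN_CATEGORIES + REFERENCE_N_TEST_CATEGORIES, 16,
            REFERENCE_N_TEST_CATEGORIES, seed=0)
        manifest = dataset_image_manifest(
            bank, REFERENCE_IMAGES_PER_TRAIN_CATEGORY)
        assert len(manifest) == 16_740
        assert manifest["image_id"].is_unique

    def test_scaled_config_counts(self):
        bank = make_concept_bank(25, 8, 5, seed=0)
        fm = make_forward_model(MONTAGE_18, 50.0, 4, 8, seed=1)
        ds = assemble_dataset(bank, fm, images_per_train_cat=3, reps=1,
                              n_subjects=2, seed=2)
        assert ds.train.n_images == 60 and ds.test.n_images == 5
        assert ds.train.eeg.shape == (2, 60, 18, 50)
        assert not set(ds.train.category_ids) & set(ds.test.category_ids)

    def test_deterministic_given_seed(self, small_bank, small_fm):
        d1 = assemble_dataset(small_bank, small_fm, 2, 2, 1, seed=5)
        d2 = assemble_dataset(small_bank, small_fm, 2, 2, 1, seed=5)
        assert np.array_equal(d1.train.eeg, d2.train.eeg)
        assert np.array_equal(d1.test.image_embeddings,
                              d2.test.image_embeddings)


class TestTagCards:
    def test_one_card_per_test_image_five_slots(self, small_bank, rng):
        cards = make_tag_cards(small_bank, rng=rng)
        assert len(cards) == len(small_bank.test_category_ids)
        assert all(len(c.tags) == 5 and all(c.tags) for c in cards)

    def test_reference_scale_1000_tag_slots(self):
        bank = make_concept_bank(400, 8, 200, seed=0)
        cards = make_tag_cards(bank)
        assert len(cards) * 5 == 1000

    def test_same_cluster_shares_broad_tag(self):
        bank = make_concept_bank(24, 8, 12, seed=0, n_clusters=3)
        cards = make_tag_cards(bank)
        by_cluster = {}
        test_cats = np.sort(bank.test_category_ids)
        for card, cat in zip(cards, test_cats):
            by_cluster.setdefault(bank.cluster_for(cat), set()).add(
                card.broad_1)
        assert all(len(b) == 1 for b in by_cluster.values())

    def test_vocabulary_validation(self):
        with pytest.raises(ValueError):
            TagVocabulary(broad_pairs=(("a", "b"),), specific=("x", "y"),
                          background=("u", "v"), attribute=("p", "q"))

    def test_tag_card_rejects_empty_slot(self):
        with pytest.raises(ValueError):
            TagCard(0, "a", "b", "", "d", "e")


def test_montages_contain_posterior_channels():
    for montage in (MONTAGE_18, MONTAGE_64):
        assert set(POSTERIOR_CHANNELS) <= set(montage)
    assert len(MONTAGE_64) == 64
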