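"""CAT score and FID: identities, closed forms, and properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eeg2img import (TagCard, ToyImageDecoder, cat_score, fid, match_tags,
                     toy_generator_and_features)
from eeg2img.exceptions import ShapeError

CARD = TagCard(0, "animal", "mammal", "cat", "indoor", "furry")


class TestMatchTags:
    def test_all_five_matched(self):
        assert match_tags({"animal", "mammal", "cat", "indoor", "furry"},
                          CARD) == 5

    def test_disjoint_sets_score_zero(self):
        assert match_tags({"vehicle", "metal"}, CARD) == 0

    def test_partial_match_counts_slots(self):
        # {animal, cat} hit broad_1 and specific; "outdoor" hits nothing
        assert match_tags({"animal", "cat", "outdoor"}, CARD) == 2

    def test_normalization_case_and_whitespace(self):
        assert match_tags({" Animal ", "CAT"}, CARD) == 2

    def test_non_card_rejected(self):
        with pytest.raises(TypeError):
            match_tags({"a"}, {"broad_1": "a"})

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.sets(st.sampled_from(list(CARD.tags) + ["x", "y", "z"])),
           st.sampled_from(list(CARD.tags)))
    def test_adding_a_correct_tag_never_decreases_score(self, tags, extra):
        assert match_tags(tags | {extra}, CARD) >= match_tags(tags, CARD)


class TestCatScore:
    def _cards(self, n):
        return [TagCard(i, "animal", "mammal", f"s{i}", "indoor", "furry")
                for i in range(n)]

    def test_200_images_fully_matched_totals_1000(self):
        cards = self._cards(200)
        result = cat_score([set(c.tags) for c in cards], cards)
        assert result.total == 1000 and result.max_possible == 1000

    def test_no_matches_total_zero(self):
        cards = self._cards(200)
        result = cat_score([{"nothing"} for _ in cards], cards)
        assert result.total == 0

    def test_mixed_scores_sum(self):
        cards = self._cards(3)
        tags = [set(cards[0].tags), set(), {"animal", "mammal", "s2"}]
        result = cat_score(tags, cards)
        assert result.per_image_points == [5, 0, 3]
        assert result.total == 8 and result.max_possible == 15

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cat_score([set()], self._cards(2))


class TestFID:
    def test_identical_sets_give_zero(self):
        X = np.random.default_rng(0).standard_normal((50, 4))
        assert fid(X, X).value == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((60, 5))
        B = rng.standard_normal((40, 5)) + 1.0
        assert fid(A, B).value == pytest.approx(fid(B, A).value, abs=1e-8)

    def test_point_masses_reduce_to_squared_mean_distance(self):
        mu1 = np.array([1.0, 2.0, 3.0])
        mu2 = np.array([0.0, 0.0, 1.0])
        A = np.tile(mu1, (10, 1))
        B = np.tile(mu2, (10, 1))
        assert fid(A, B).value == pytest.approx(np.sum((mu1 - mu2) ** 2),
                                                abs=1e-10)

    def test_univariate_gaussian_closed_form(self):
        """FID(N(0,1), N(0,4)) -> (sigma1-sigma2)^2 = 1 at large n."""
        rng = np.random.default_rng(2)
        A = rng.standard_normal((1_000_000, 1))
        B = 2.0 * rng.standard_normal((1_000_000, 1))
        assert fid(A, B).value == pytest.approx(1.0, abs=0.05)

    def test_mean_shift_adds_squared_norm(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((4000, 3))
        delta = np.array([0.5, -1.0, 2.0])
        base = fid(A, A).value
        shifted = fid(A, A + delta).value
        assert shifted - base == pytest.approx(np.sum(delta ** 2), rel=0.01)

    def test_matches_scipy_sqrtm_route(self):
        """Independent cross-check against scipy's general matrix sqrt."""
        from scipy import linalg

        rng = np.random.default_rng(4)
        A = rng.standard_normal((200, 4))
        B = rng.standard_normal((150, 4)) @ np.diag([1.0, 2.0, 0.5, 1.5]) + 0.3
        mu_r, mu_g = A.mean(0), B.mean(0)
        S_r = np.cov(A, rowvar=False)
        S_g = np.cov(B, rowvar=False)
        covmean = linalg.sqrtm(S_r @ S_g).real
        expected = (np.sum((mu_r - mu_g) ** 2)
                    + np.trace(S_r + S_g - 2 * covmean))
        assert fid(A, B).value == pytest.approx(expected, rel=1e-8)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            fid(np.zeros((5, 3)), np.zeros((5, 4)))

    def test_nonfinite_rejected(self):
        X = np.zeros((5, 2))
        Y = X.copy()
        Y[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            fid(X, Y)

    def test_small_sample_warns(self):
        X = np.random.default_rng(5).standard_normal((3, 8))
        with pytest.warns(UserWarning, match="rank-deficient"):
            fid(X, X)


class TestToyDecoder:
    def test_deterministic_image_from_embedding(self):
        dec = ToyImageDecoder(8, seed=0)
        emb = np.random.default_rng(0).standard_normal(8)
        img1, feat1 = toy_generator_and_features(emb, dec)
        img2, feat2 = toy_generator_and_features(emb, dec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert img1.pixels.min() >= 0 and img1.pixels.max() <= 1

    def test_identity_feature_extractor(self):
        dec = ToyImageDecoder(8, seed=0)
        emb = np.random.default_rng(1).standard_normal(8)
        _, feat = toy_generator_and_features(emb, dec)
        assert np.array_equal(feat, emb)
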