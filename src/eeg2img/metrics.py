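"""Semantic (CAT) and distributional (FID) evaluation of generated images.

CAT — Category-based Assessment Table — scores each generated image by how
many of the five annotation slots of its ground-truth test image it matches
(two broad categories, one specific category, one background, one
attribute).  One point per matched slot, so a 200-image test set has a
1000-point ceiling.  Matching here is exact string equality after
lowercasing/trimming; producing the candidate tags for a generated image
(vision-language model, human rater...) is an external, pluggable step.

FID compares feature distributions of real and generated image sets:

    FID = ||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2})

with sample covariances (1/(n-1)) and the matrix square root taken by
eigendecomposition of the symmetrized product.  The feature extractor is
pluggable; at desk scale the identity map on embedding vectors is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ShapeError
from .synthetic import ImageStimulus, TagCard


# --------------------------------------------------------------------------
# CAT score
# --------------------------------------------------------------------------

@dataclass
class CATResult:
    per_image_points: list[int]
    total: int
    max_possible: int

    def __post_init__(self):
        if self.total != sum(self.per_image_points):
            raise ValueError("total must equal the per-image sum")
        if not 0 <= self.total <= self.max_possible:
            raise ValueError("total outside [0, max_possible]")


def _normalize_tags(tags) -> set[str]:
    return {str(t).strip().lower() for t in tags if str(t).strip()}


def match_tags(generated_tags, card: TagCard) -> int:
    """Number of the card's five slots hit by the generated tag set (0-5)."""
    if not isinstance(card, TagCard):
        raise TypeError("card must be a TagCard")
    gen = _normalize_tags(generated_tags)
    return sum(1 for slot_tag in card.tags if slot_tag in gen)


def cat_score(all_generated_tags, cards: list[TagCard]) -> CATResult:
    """Sum of per-image tag matches; ``max_possible = 5 * n_images``."""
    if len(all_generated_tags) != len(cards):
        raise ValueError(
            f"{len(all_generated_tags)} tag sets vs {len(cards)} cards")
    points = [match_tags(tags, card)
              for tags, card in zip(all_generated_tags, cards)]
    return CATResult(per_image_points=points, total=sum(points),
                     max_possible=5 * len(cards))


# --------------------------------------------------------------------------
# FID
# --------------------------------------------------------------------------

@dataclass
class FIDResult:
    value: float
    n_real: int
    n_gen: int
    feature_dim: int


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition with clipping."""
    sym = (M + M.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(features_real: np.ndarray, features_gen: np.ndarray) -> FIDResult:
    """Frechet distance between Gaussian fits of two feature clouds.

    The covariance square-root term is computed as
    ``Tr((S_r^{1/2} S_g S_r^{1/2})^{1/2})``, which equals
    ``Tr((S_r S_g)^{1/2})`` but stays symmetric; eigenvalues below zero
    (numerical noise) are clipped.
    """
    Xr = np.atleast_2d(np.asarray(features_real, dtype=float))
    Xg = np.atleast_2d(np.asarray(features_gen, dtype=float))
    if Xr.shape[1] != Xg.shape[1]:
        raise ShapeError(
            f"feature dims differ: {Xr.shape[1]} vs {Xg.shape[1]}")
    if not (np.all(np.isfinite(Xr)) and np.all(np.isfinite(Xg))):
        raise FloatingPointError("non-finite feature values")
    F = Xr.shape[1]
    if min(len(Xr), len(Xg)) < F + 1:
        import warnings
        warnings.warn(
            f"fewer samples than feature_dim+1={F + 1}; covariance estimates "
            "are rank-deficient", stacklevel=2)
    mu_r, mu_g = Xr.mean(axis=0), Xg.mean(axis=0)
    S_r = np.cov(Xr, rowvar=False, ddof=1) if len(Xr) > 1 else np.zeros((F, F))
    S_g = np.cov(Xg, rowvar=False, ddof=1) if len(Xg) > 1 else np.zeros((F, F))
    S_r, S_g = np.atleast_2d(S_r), np.atleast_2d(S_g)
    sr = _psd_sqrt(S_r)
    cross = _psd_sqrt(sr @ S_g @ sr)
    value = float(np.sum((mu_r - mu_g) ** 2)
                  + np.trace(S_r) + np.trace(S_g) - 2.0 * np.trace(cross))
    return FIDResult(value=max(value, 0.0), n_real=len(Xr), n_gen=len(Xg),
                     feature_dim=F)


# --------------------------------------------------------------------------
# toy decoder (stand-in generator + feature extractor)
# --------------------------------------------------------------------------

class ToyImageDecoder:
    """Deterministic linear embedding -> small grayscale image decoder.

    A fixed random readout maps an embedding to ``size x size`` logits
    squashed into [0, 1].  The paired feature extractor is the identity on
    embeddings, so FID over "generated images" reduces to FID over the
    embeddings that produced them — enough to exercise the full generation
    -> scoring loop at desk scale.
    """

    def __init__(self, embed_dim: int, size: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.embed_dim = embed_dim
        self.size = size
        self.readout = rng.standard_normal((embed_dim, size * size))
        self.readout /= np.sqrt(embed_dim)

    def decode(self, embedding: np.ndarray, image_id: int = 0) -> ImageStimulus:
        emb = np.asarray(embedding, dtype=float)
        if emb.shape != (self.embed_dim,):
            raise ShapeError(f"expected ({self.embed_dim},), got {emb.shape}")
        logits = emb @ self.readout
        pixels = 1.0 / (1.0 + np.exp(-logits))
        return ImageStimulus(pixels.reshape(self.size, self.size, 1),
                             image_id)

    def features(self, embedding: np.ndarray) -> np.ndarray:
        """Identity feature extractor."""
        return np.asarray(embedding, dtype=float)


def toy_generator_and_features(embedding: np.ndarray,
                               decoder: ToyImageDecoder,
                               image_id: int = 0) \
        -> tuple[ImageStimulus, np.ndarray]:
    """Render one embedding to a toy image and return its feature vector."""
    return (decoder.decode(embedding, image_id), decoder.features(embedding))
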