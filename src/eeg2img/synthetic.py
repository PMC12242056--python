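"""Synthetic ThingsEEG-like data with known latent structure.

The real benchmark pairs 64-channel EEG trials (0-1000 ms after stimulus
onset, averaged over repetitions) with natural-image stimuli: 1654 training
categories of 10 images each plus 200 held-out test categories of 1 image,
so the retrieval task is strictly zero-shot.  This module emulates that
structure with a controllable generative model so every downstream stage
(contrastive training, diffusion prior, retrieval, CAT/FID scoring,
channel perturbation) can be exercised end to end without any downloads.

Latent model
------------
Each category owns a unit-norm *concept vector* living in the image-embedding
space.  Image embeddings are noisy renormalized copies of the concept.  EEG
trials are produced by a linear forward model: the concept is projected to
``r`` source coefficients, mixed through per-channel spatial loadings and a
unit-norm temporal basis, and corrupted by Gaussian sensor noise.  A
``posterior_boost`` gain concentrates signal on the six visual-cortex
channels, mirroring the empirical dominance of occipital/parieto-occipital
electrodes in visual decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, ShapeError
from .montage import MONTAGE_18, MONTAGE_64, posterior_indices

REFERENCE_N_TRAIN_CATEGORIES = 1654
REFERENCE_N_TEST_CATEGORIES = 200
REFERENCE_IMAGES_PER_TRAIN_CATEGORY = 10


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptBank:
    """Per-category unit-norm concept vectors with a disjoint train/test split."""

    concepts: np.ndarray          # (K, D_img), unit rows
    category_ids: np.ndarray      # (K,) int
    is_test: np.ndarray           # (K,) bool
    cluster_ids: np.ndarray       # (K,) int; categories sharing broad semantics

    def __post_init__(self):
        norms = np.linalg.norm(self.concepts, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("concept rows must be unit norm")
        if len(self.category_ids) < 2:
            raise ValueError("need at least 2 categories")
        if not (0 < self.is_test.sum() < len(self.category_ids)):
            raise ValueError("both train and test categories are required")

    @property
    def d_img(self) -> int:
        return self.concepts.shape[1]

    @property
    def train_category_ids(self) -> np.ndarray:
        return self.category_ids[~self.is_test]

    @property
    def test_category_ids(self) -> np.ndarray:
        return self.category_ids[self.is_test]

    def _row(self, category_id: int) -> int:
        rows = np.flatnonzero(self.category_ids == category_id)
        if len(rows) == 0:
            raise KeyError(f"unknown category id {category_id}")
        return int(rows[0])

    def concept_for(self, category_id: int) -> np.ndarray:
        return self.concepts[self._row(category_id)]

    def cluster_for(self, category_id: int) -> int:
        return int(self.cluster_ids[self._row(category_id)])


@dataclass
class EEGTrial:
    """One (possibly repetition-averaged) EEG recording of a stimulus."""

    data: np.ndarray              # (e, d) channels x time
    channel_names: tuple[str, ...]
    sampling_rate: float          # Hz; trials span 0-1000 ms, so d = rate * 1 s
    subject_id: int
    category_id: int
    image_id: int
    n_repetitions_averaged: int = 1

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")
        if self.data.shape[0] != len(self.channel_names):
            raise ShapeError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} "
                "channel names")
        if self.n_repetitions_averaged < 1:
            raise ValueError("n_repetitions_averaged must be >= 1")


@dataclass(frozen=True)
class ImageStimulus:
    """Toy stimulus image with values in [0, 1]."""

    pixels: np.ndarray            # (h, w, ch)
    image_id: int

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] not in (1, 3):
            raise ShapeError("pixels must be (h, w, ch) with ch in {1, 3}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")


@dataclass(frozen=True)
class TagCard:
    """Five-tag semantic annotation of one test image.

    Two broad-category tags, one specific category, one background, one
    object attribute — the scheme behind the 1000-point CAT scale
    (200 test images x 5 tags).
    """

    image_id: int
    broad_1: str
    broad_2: str
    specific: str
    background: str
    attribute: str

    def __post_init__(self):
        for slot in ("broad_1", "broad_2", "specific", "background",
                     "attribute"):
            value = getattr(self, slot)
            if not isinstance(value, str) or not value.strip():
                raise ValueError(f"tag slot {slot!r} must be a non-empty string")
            object.__setattr__(self, slot, value.strip().lower())

    @property
    def tags(self) -> tuple[str, str, str, str, str]:
        return (self.broad_1, self.broad_2, self.specific, self.background,
                self.attribute)


@dataclass(frozen=True)
class ForwardModel:
    """Linear concept -> EEG map with posterior signal concentration."""

    spatial_loadings: np.ndarray  # (e, r)
    temporal_basis: np.ndarray    # (r, d), unit rows
    concept_projection: np.ndarray  # (D_img, r), fixed per model
    channel_names: tuple[str, ...]
    sampling_rate: float
    posterior_boost: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.posterior_boost < 1.0:
            raise ValueError("posterior_boost must be >= 1")
        row_norms = np.linalg.norm(self.temporal_basis, axis=1)
        if not np.allclose(row_norms, 1.0, atol=1e-6):
            raise ValueError("temporal basis rows must be unit norm")
        if self.spatial_loadings.shape[0] != len(self.channel_names):
            raise ShapeError("spatial loadings rows must match montage size")
        if self.spatial_loadings.shape[1] != self.temporal_basis.shape[0]:
            raise ShapeError("spatial/temporal rank mismatch")

    @property
    def n_channels(self) -> int:
        return self.spatial_loadings.shape[0]

    @property
    def n_samples(self) -> int:
        return self.temporal_basis.shape[1]

    @property
    def channel_gains(self) -> np.ndarray:
        gains = np.ones(self.n_channels)
        gains[posterior_indices(self.channel_names)] = self.posterior_boost
        return gains


@dataclass
class SplitData:
    """One dataset split as dense arrays (one averaged trial per subject)."""

    eeg: np.ndarray               # (n_subjects, n_images, e, d)
    image_embeddings: np.ndarray  # (n_images, D_img)
    category_ids: np.ndarray      # (n_images,)
    image_ids: np.ndarray         # (n_images,)

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    @property
    def n_subjects(self) -> int:
        return self.eeg.shape[0]


@dataclass
class SyntheticDataset:
    train: SplitData
    test: SplitData
    channel_names: tuple[str, ...]
    sampling_rate: float
    subject_ids: tuple[int, ...]
    images: dict[int, ImageStimulus] = field(default_factory=dict)

    def trial(self, split: str, subject: int, index: int) -> EEGTrial:
        """Materialize one averaged trial as an :class:`EEGTrial`."""
        part = self.train if split == "train" else self.test
        s = self.subject_ids.index(subject)
        return EEGTrial(part.eeg[s, index], self.channel_names,
                        self.sampling_rate, subject,
                        int(part.category_ids[index]),
                        int(part.image_ids[index]))


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def make_concept_bank(K: int, D_img: int, n_test: int, seed: int,
                      n_clusters: int | None = None,
                      cluster_spread: float = 0.35) -> ConceptBank:
    """Draw ``K`` unit-norm concept vectors with cluster structure.

    Concepts are sampled around shared cluster centres so that categories
    within a cluster have correlated embeddings and can legitimately share
    broad semantic tags.  ``n_test`` categories are flagged as the held-out
    zero-shot split.
    """
    if not (0 < n_test < K):
        raise ValueError(f"need 0 < n_test < K, got n_test={n_test}, K={K}")
    if D_img < 2:
        raise ValueError("D_img must be >= 2")
    rng = np.random.default_rng(seed)
    if n_clusters is None:
        n_clusters = max(2, min(10, K // 4)) if K > 3 else 1
    centers = rng.standard_normal((n_clusters, D_img))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    cluster_ids = np.arange(K) % n_clusters
    concepts = centers[cluster_ids] + cluster_spread * rng.standard_normal(
        (K, D_img))
    concepts /= np.linalg.norm(concepts, axis=1, keepdims=True)
    is_test = np.zeros(K, dtype=bool)
    is_test[rng.choice(K, size=n_test, replace=False)] = True
    return ConceptBank(concepts=concepts, category_ids=np.arange(K),
                       is_test=is_test, cluster_ids=cluster_ids)


def sample_image_embedding(bank: ConceptBank, category_id: int,
                           sigma_img: float,
                           rng: np.random.Generator) -> np.ndarray:
    """A unit-norm noisy copy of the category concept vector."""
    if sigma_img < 0:
        raise ValueError("sigma_img must be >= 0")
    concept = bank.concept_for(category_id)
    vec = concept + sigma_img * rng.standard_normal(bank.d_img)
    return vec / np.linalg.norm(vec)


def make_forward_model(channel_names=MONTAGE_18, sampling_rate: float = 100.0,
                       rank: int = 8, d_img: int = 64,
                       posterior_boost: float = 4.0, noise_sd: float = 0.1,
                       seed: int = 0) -> ForwardModel:
    """Build a random linear forward model for the given montage.

    ``d = round(sampling_rate * 1 s)`` samples span the 0-1000 ms epoch.
    """
    rng = np.random.default_rng(seed)
    e = len(channel_names)
    d = int(round(sampling_rate * 1.0))
    basis = rng.standard_normal((rank, d))
    basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    return ForwardModel(
        spatial_loadings=rng.standard_normal((e, rank)) / np.sqrt(rank),
        temporal_basis=basis,
        concept_projection=rng.standard_normal((d_img, rank)) / np.sqrt(d_img),
        channel_names=tuple(channel_names),
        sampling_rate=sampling_rate,
        posterior_boost=posterior_boost,
        noise_sd=noise_sd,
    )


def sample_eeg_trial(bank: ConceptBank, category_id: int, fm: ForwardModel,
                     subject_id: int, rng: np.random.Generator,
                     image_id: int = 0) -> EEGTrial:
    """Simulate one raw (single-repetition) EEG trial for a category."""
    concept = bank.concept_for(category_id)
    if fm.concept_projection.shape[0] != bank.d_img:
        raise ShapeError(
            f"forward model expects {fm.concept_projection.shape[0]}-D "
            f"concepts, bank has {bank.d_img}-D")
    coeff = concept @ fm.concept_projection             # (r,)
    signal = (fm.spatial_loadings * coeff) @ fm.temporal_basis
    signal = fm.channel_gains[:, None] * signal
    noise = fm.noise_sd * rng.standard_normal(signal.shape)
    return EEGTrial(signal + noise, fm.channel_names, fm.sampling_rate,
                    subject_id, int(category_id), int(image_id))


def average_repetitions(trials: list[EEGTrial]) -> EEGTrial:
    """Element-wise mean of repeated presentations of the same image."""
    if not trials:
        raise ValueError("no trials to average")
    ref = trials[0]
    for t in trials[1:]:
        if (t.data.shape != ref.data.shape
                or t.channel_names != ref.channel_names
                or t.subject_id != ref.subject_id
                or t.image_id != ref.image_id
                or t.sampling_rate != ref.sampling_rate):
            raise ConsistencyError(
                "repetitions must share shape, montage, subject and image id")
    mean = np.mean([t.data for t in trials], axis=0)
    return EEGTrial(mean, ref.channel_names, ref.sampling_rate,
                    ref.subject_id, ref.category_id, ref.image_id,
                    n_repetitions_averaged=sum(t.n_repetitions_averaged
                                               for t in trials))


def dataset_image_manifest(bank: ConceptBank,
                           images_per_train_cat: int) -> pd.DataFrame:
    """Enumerate every unique image the dataset will contain.

    Training categories contribute ``images_per_train_cat`` images each,
    test categories exactly one; the reference configuration
    (1654 x 10 + 200 x 1) therefore yields 16,740 unique images.
    """
    if images_per_train_cat < 1:
        raise ValueError("images_per_train_cat must be >= 1")
    rows = []
    image_id = 0
    for cat in np.sort(bank.train_category_ids):
        for _ in range(images_per_train_cat):
            rows.append((image_id, int(cat), "train"))
            image_id += 1
    for cat in np.sort(bank.test_category_ids):
        rows.append((image_id, int(cat), "test"))
        image_id += 1
    return pd.DataFrame(rows, columns=["image_id", "category_id", "split"])


def _toy_image(embedding: np.ndarray, image_id: int, size: int = 8) -> ImageStimulus:
    """Deterministic small grayscale rendering of an embedding."""
    proj = np.random.default_rng(12345).standard_normal(
        (embedding.size, size * size))
    logits = embedding @ proj
    pixels = 1.0 / (1.0 + np.exp(-logits))
    return ImageStimulus(pixels.reshape(size, size, 1), image_id)


def assemble_dataset(bank: ConceptBank, fm: ForwardModel,
                     images_per_train_cat: int = 3, reps: int = 4,
                     n_subjects: int = 2, seed: int = 0,
                     sigma_img: float = 0.05,
                     with_toy_images: bool = False) -> SyntheticDataset:
    """Generate the full paired dataset.

    Every image gets one embedding and, per subject, one EEG trial averaged
    over ``reps`` repetitions (averaging shrinks sensor noise by 1/sqrt(R),
    as in the real benchmark's repetition averaging).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    manifest = dataset_image_manifest(bank, images_per_train_cat)
    subject_ids = tuple(range(n_subjects))
    splits: dict[str, SplitData] = {}
    images: dict[int, ImageStimulus] = {}
    for split_name in ("train", "test"):
        part = manifest[manifest["split"] == split_name]
        n = len(part)
        emb = np.empty((n, bank.d_img))
        eeg = np.empty((n_subjects, n, fm.n_channels, fm.n_samples))
        for j, (img_id, cat) in enumerate(
                zip(part["image_id"], part["category_id"])):
            emb[j] = sample_image_embedding(bank, cat, sigma_img, rng)
            if with_toy_images:
                images[int(img_id)] = _toy_image(emb[j], int(img_id))
            for s in subject_ids:
                trial = average_repetitions([
                    sample_eeg_trial(bank, cat, fm, s, rng, image_id=img_id)
                    for _ in range(reps)])
                eeg[s, j] = trial.data
        splits[split_name] = SplitData(
            eeg=eeg, image_embeddings=emb,
            category_ids=part["category_id"].to_numpy(),
            image_ids=part["image_id"].to_numpy())
    return SyntheticDataset(train=splits["train"], test=splits["test"],
                            channel_names=fm.channel_names,
                            sampling_rate=fm.sampling_rate,
                            subject_ids=subject_ids, images=images)


# --------------------------------------------------------------------------
# tag vocabulary and cards
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TagVocabulary:
    """Hierarchical tag vocabulary: broad pairs per cluster + flat slots."""

    broad_pairs: tuple[tuple[str, str], ...]
    specific: tuple[str, ...]
    background: tuple[str, ...]
    attribute: tuple[str, ...]

    def __post_init__(self):
        for name in ("broad_pairs", "specific", "background", "attribute"):
            if len(getattr(self, name)) < 2:
                raise ValueError(f"vocabulary slot {name!r} needs >= 2 entries")


DEFAULT_TAG_VOCABULARY = TagVocabulary(
    broad_pairs=(("animal", "mammal"), ("vehicle", "machine"),
                 ("food", "produce"), ("tool", "object"),
                 ("plant", "nature"), ("clothing", "fabric"),
                 ("furniture", "household"), ("instrument", "device"),
                 ("building", "structure"), ("toy", "plaything")),
    specific=("cat", "truck", "apple", "hammer", "fern", "jacket", "chair",
              "violin", "barn", "kite", "sheep", "canoe"),
    background=("indoor", "outdoor", "studio", "forest", "street", "sky"),
    attribute=("furry", "metallic", "red", "wooden", "striped", "round"),
)


def make_tag_cards(bank: ConceptBank,
                   vocab: TagVocabulary = DEFAULT_TAG_VOCABULARY,
                   rng: np.random.Generator | None = None,
                   image_ids=None) -> list[TagCard]:
    """One five-tag card per test image (= per test category).

    Categories in the same concept cluster share their broad tags, so
    partial semantic matches arise by construction.  ``image_ids`` aligns
    the cards with a dataset's test split (sorted test-category order);
    by default the cards are numbered 0..n_test-1.
    """
    rng = rng or np.random.default_rng(0)
    cards = []
    test_cats = np.sort(bank.test_category_ids)
    if image_ids is None:
        image_ids = np.arange(len(test_cats))
    if len(image_ids) != len(test_cats):
        raise ValueError("image_ids must have one entry per test category")
    for img_id, cat in zip(image_ids, test_cats):
        cluster = bank.cluster_for(cat)
        broad_1, broad_2 = vocab.broad_pairs[cluster % len(vocab.broad_pairs)]
        cards.append(TagCard(
            image_id=int(img_id),
            broad_1=broad_1, broad_2=broad_2,
            specific=vocab.specific[cat % len(vocab.specific)],
            background=str(rng.choice(vocab.background)),
            attribute=str(rng.choice(vocab.attribute)),
        ))
    return cards


def perturbed_copy(split: SplitData, **changes) -> SplitData:
    """Shallow dataclass copy helper used by the perturbation module."""
    return replace(split, **changes)
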