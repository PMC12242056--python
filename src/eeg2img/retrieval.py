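"""Participant-dependent n-way zero-shot retrieval.

Each test EEG embedding is scored by cosine similarity against a panel of
``n_way`` candidate image embeddings: the ground-truth image plus
``n_way - 1`` distractors drawn without replacement from other unseen
categories.  A prediction is correct when the true image is ranked highest
(ties count against the model).  Panels are resampled per trial with a
seeded generator; the full-set task uses the single deterministic panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: task presets mirroring the benchmark's n-way levels
NWAY_PRESETS = (2, 4, 10, 50, 100, 200)


@dataclass
class RetrievalReport:
    n_way: int
    top_k: int
    n_trials: int
    accuracy: float
    per_trial_ranks: list[int]

    def __post_init__(self):
        ranks = np.asarray(self.per_trial_ranks)
        if len(ranks) and not ((1 <= ranks).all() and (ranks <= self.n_way).all()):
            raise ValueError("ranks must lie in [1, n_way]")

    def to_dict(self) -> dict:
        return {"n_way": self.n_way, "top_k": self.top_k,
                "n_trials": self.n_trials, "accuracy": self.accuracy}


def _unit(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    return x / np.where(norms == 0, 1.0, norms)


def rank_of_truth(eeg_emb: np.ndarray, candidate_embs: np.ndarray,
                  true_index: int) -> int:
    """1-based rank of the true candidate under descending cosine similarity.

    Any distractor tying the truth's similarity is counted as ranked above
    it (strict "ranked highest" reading).
    """
    candidate_embs = np.asarray(candidate_embs, dtype=float)
    if not 0 <= true_index < len(candidate_embs):
        raise ValueError(
            f"true_index {true_index} out of range for "
            f"{len(candidate_embs)} candidates")
    sims = _unit(candidate_embs) @ _unit(np.asarray(eeg_emb, dtype=float))
    true_sim = sims[true_index]
    others = np.delete(sims, true_index)
    return 1 + int(np.sum(others >= true_sim))


def evaluate_nway(eeg_embs: np.ndarray, image_embs: np.ndarray,
                  labels: np.ndarray, n_way: int, top_k: int = 1,
                  n_trials: int = 1000,
                  rng: np.random.Generator | int | None = None) \
        -> RetrievalReport:
    """n-way retrieval accuracy over resampled distractor panels.

    ``eeg_embs[i]`` is a test EEG embedding with category ``labels[i]``;
    ``image_embs`` holds one image embedding per row with categories
    ``labels`` repeated per subject block allowed via matching lengths.
    Distractors are image embeddings of *other* categories.  When ``n_way``
    equals the number of distinct categories the full panel is evaluated
    once per EEG item (no sampling).
    """
    eeg_embs = np.asarray(eeg_embs, dtype=float)
    image_embs = np.asarray(image_embs, dtype=float)
    labels = np.asarray(labels)
    if len(eeg_embs) % len(image_embs):
        raise ValueError("eeg rows must be a whole number of image blocks")
    if len(labels) != len(image_embs):
        raise ValueError("labels must align with image embeddings")
    categories = np.unique(labels)
    if not 2 <= n_way <= len(categories):
        raise ValueError(
            f"n_way={n_way} must be in [2, {len(categories)}] for this set")
    if not 1 <= top_k <= n_way:
        raise ValueError("top_k must be in [1, n_way]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    eeg_labels = np.tile(labels, len(eeg_embs) // len(image_embs))
    cat_to_row = {c: np.flatnonzero(labels == c)[0] for c in categories}

    ranks: list[int] = []
    if n_way == len(categories):
        for i in range(len(eeg_embs)):
            panel_cats = [eeg_labels[i]] + [c for c in categories
                                            if c != eeg_labels[i]]
            panel = image_embs[[cat_to_row[c] for c in panel_cats]]
            ranks.append(rank_of_truth(eeg_embs[i], panel, 0))
    else:
        for _ in range(n_trials):
            i = int(rng.integers(len(eeg_embs)))
            true_cat = eeg_labels[i]
            pool = categories[categories != true_cat]
            distractors = rng.choice(pool, size=n_way - 1, replace=False)
            panel = image_embs[[cat_to_row[true_cat]]
                               + [cat_to_row[c] for c in distractors]]
            ranks.append(rank_of_truth(eeg_embs[i], panel, 0))
    ranks_arr = np.asarray(ranks)
    return RetrievalReport(n_way=n_way, top_k=top_k, n_trials=len(ranks),
                           accuracy=float(np.mean(ranks_arr <= top_k)),
                           per_trial_ranks=ranks)


def evaluate_presets(eeg_embs, image_embs, labels, seed: int = 0,
                     n_trials: int = 1000) -> list[RetrievalReport]:
    """Run the preset n-way levels that fit the category count.

    The full-set task is reported at top-1 and top-5, mirroring the standard
    report structure.
    """
    n_cats = len(np.unique(labels))
    rng = np.random.default_rng(seed)
    reports = []
    for n_way in NWAY_PRESETS:
        if n_way < n_cats:
            reports.append(evaluate_nway(eeg_embs, image_embs, labels, n_way,
                                         top_k=1, n_trials=n_trials, rng=rng))
    for top_k in (1, 5):
        if top_k <= n_cats:
            reports.append(evaluate_nway(eeg_embs, image_embs, labels,
                                         n_way=n_cats, top_k=top_k, rng=rng))
    return reports
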