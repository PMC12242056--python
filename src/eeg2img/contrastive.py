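"""Symmetric InfoNCE alignment of EEG and image embeddings.

Matched EEG-image pairs within a batch are positives; every other pairing
in the batch is a negative.  Similarities are cosines scaled by a learned
temperature: the logit scale is the log-parameterized 1/tau, initialized at
log(1/0.07) and clamped so exp(logit_scale) <= 100.  Both modalities pass
through small MLP projectors into the shared space before scoring.

The optimization recipe follows the reference setup: AdamW with lr 2e-4 and
betas (0.5, 0.999); the nominal batch size of 1024 is capped at the dataset
size for desk-scale corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, concat, gelu, log_softmax, no_grad
from .encoder import NERVEncoder
from .exceptions import ShapeError
from .nn import AdamW, Linear, Module
from .synthetic import SyntheticDataset

LOGIT_SCALE_INIT = float(np.log(1.0 / 0.07))
LOGIT_SCALE_MAX = float(np.log(100.0))


def _normalize_rows(x: Tensor, what: str) -> Tensor:
    norms_sq = (x * x).sum(axis=-1, keepdims=True)
    bad = np.flatnonzero(norms_sq.numpy().ravel() == 0.0)
    if bad.size:
        raise FloatingPointError(
            f"zero-norm {what} row(s) at index {bad.tolist()}")
    return x * norms_sq.pow(-0.5)


def scaled_similarity(E, I, logit_scale=0.0) -> Tensor:
    """Temperature-scaled cosine similarity matrix.

    ``values[i, j] = exp(logit_scale) * cos(E_i, I_j)`` with EEG items on
    rows and image items on columns.  Accepts arrays or tensors; returns a
    Tensor so it can sit inside the training graph.
    """
    E = E if isinstance(E, Tensor) else Tensor(E)
    I = I if isinstance(I, Tensor) else Tensor(I)
    if E.shape[-1] != I.shape[-1]:
        raise ShapeError(f"embedding dims differ: {E.shape} vs {I.shape}")
    scale = logit_scale if isinstance(logit_scale, Tensor) \
        else Tensor(float(logit_scale))
    En = _normalize_rows(E, "EEG embedding")
    In = _normalize_rows(I, "image embedding")
    return scale.clip(None, LOGIT_SCALE_MAX).exp() * (En @ In.transpose(1, 0))


def info_nce_loss(S) -> Tensor:
    """Symmetric InfoNCE: mean cross-entropy over rows and columns.

    The diagonal of ``S`` holds the matched pairs.  For a uniform matrix the
    loss equals ln B; it is always >= 0.
    """
    S = S if isinstance(S, Tensor) else Tensor(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ShapeError(f"similarity matrix must be square, got {S.shape}")
    B = S.shape[0]
    idx = np.arange(B)
    loss_rows = -log_softmax(S, axis=1)[idx, idx].mean()
    loss_cols = -log_softmax(S, axis=0)[idx, idx].mean()
    return (loss_rows + loss_cols) * 0.5


class ContrastiveHead(Module):
    """Shared-space projectors for both modalities plus the logit scale."""

    def __init__(self, eeg_dim: int, img_dim: int, shared_dim: int | None = None,
                 seed: int = 0):
        super().__init__()
        shared_dim = shared_dim or eeg_dim
        rng = np.random.default_rng(seed)
        self.logit_scale = Tensor(LOGIT_SCALE_INIT, requires_grad=True)
        self.eeg_fc1 = Linear(eeg_dim, shared_dim, rng)
        self.eeg_fc2 = Linear(shared_dim, shared_dim, rng)
        self.img_fc1 = Linear(img_dim, shared_dim, rng)
        self.img_fc2 = Linear(shared_dim, shared_dim, rng)
        self.shared_dim = shared_dim

    def project_eeg(self, E) -> Tensor:
        E = E if isinstance(E, Tensor) else Tensor(E)
        return self.eeg_fc2(gelu(self.eeg_fc1(E)))

    def project_image(self, I) -> Tensor:
        I = I if isinstance(I, Tensor) else Tensor(I)
        return self.img_fc2(gelu(self.img_fc1(I)))

    def similarity(self, E, I) -> Tensor:
        return scaled_similarity(self.project_eeg(E), self.project_image(I),
                                 self.logit_scale)


@dataclass
class OptConfig:
    """Contrastive-training hyper-parameters (reference recipe defaults)."""

    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    weight_decay: float = 0.0
    batch_size: int = 1024        # auto-capped at the dataset size
    epochs: int = 30
    seed: int = 0


@dataclass
class ContrastivePairs:
    """Flat (EEG trial, image embedding, subject index) triples."""

    eeg: np.ndarray               # (N, e, d)
    image_embeddings: np.ndarray  # (N, D_img)
    subject_idx: np.ndarray       # (N,)

    def __post_init__(self):
        if not (len(self.eeg) == len(self.image_embeddings)
                == len(self.subject_idx)):
            raise ShapeError("pair arrays must have equal length")
        if len(self.eeg) == 0:
            raise ValueError("empty dataset")

    @staticmethod
    def from_dataset(ds: SyntheticDataset, split: str = "train") \
            -> "ContrastivePairs":
        part = ds.train if split == "train" else ds.test
        n_sub, n_img = part.eeg.shape[:2]
        eeg = part.eeg.reshape(n_sub * n_img, *part.eeg.shape[2:])
        emb = np.tile(part.image_embeddings, (n_sub, 1))
        sub = np.repeat(np.arange(n_sub), n_img)
        return ContrastivePairs(eeg, emb, sub)


def encode_with_subjects(encoder: NERVEncoder, eeg: np.ndarray,
                         subject_idx: np.ndarray) -> Tensor:
    """Encode a mixed-subject batch, preserving row order."""
    feats = encoder.forward_features(eeg)
    pieces, order = [], []
    for s in np.unique(subject_idx):
        rows = np.flatnonzero(subject_idx == s)
        pieces.append(encoder.subject_transform(feats[rows], int(s)))
        order.append(rows)
    stacked = concat(pieces, axis=0)
    inverse = np.argsort(np.concatenate(order))
    return encoder.project(stacked[inverse])


@dataclass
class TrainingResult:
    encoder: NERVEncoder
    head: ContrastiveHead
    loss_history: list[float] = field(default_factory=list)


def fit_contrastive(encoder: NERVEncoder, dataset, opt: OptConfig | None = None,
                    head: ContrastiveHead | None = None) -> TrainingResult:
    """Jointly train encoder, projectors and temperature on paired data.

    ``dataset`` is a :class:`SyntheticDataset` (train split used) or a
    :class:`ContrastivePairs`.  Returns the trained encoder/head plus the
    per-step loss history; ``epochs=0`` leaves the encoder untouched.
    """
    opt = opt or OptConfig()
    pairs = dataset if isinstance(dataset, ContrastivePairs) \
        else ContrastivePairs.from_dataset(dataset)
    if head is None:
        head = ContrastiveHead(encoder.config.embed_dim,
                               pairs.image_embeddings.shape[1],
                               seed=opt.seed)
    history: list[float] = []
    if opt.epochs == 0:
        return TrainingResult(encoder, head, history)
    rng = np.random.default_rng(opt.seed)
    n = len(pairs.eeg)
    batch = min(opt.batch_size, n)
    optimizer = AdamW(encoder.parameters() + head.parameters(), lr=opt.lr,
                      betas=opt.betas, weight_decay=opt.weight_decay)
    encoder.train()
    head.train()
    for _ in range(opt.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch):
            rows = perm[start:start + batch]
            if len(rows) < 2:      # a singleton batch has no negatives
                continue
            E = encode_with_subjects(encoder, pairs.eeg[rows],
                                     pairs.subject_idx[rows])
            S = head.similarity(E, pairs.image_embeddings[rows])
            loss = info_nce_loss(S)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            history.append(loss.item())
    encoder.eval()
    head.eval()
    return TrainingResult(encoder, head, history)


def fit_multiseed(build_encoder_fn, dataset, opt: OptConfig, seeds,
                  eval_fn=None) -> list[dict]:
    """Train once per seed; report final loss and an optional metric.

    Mirrors the multi-session protocol of averaging the best outcome over
    several random seeds.
    """
    results = []
    for seed in seeds:
        run_opt = OptConfig(lr=opt.lr, betas=opt.betas,
                            weight_decay=opt.weight_decay,
                            batch_size=opt.batch_size, epochs=opt.epochs,
                            seed=int(seed))
        res = fit_contrastive(build_encoder_fn(int(seed)), dataset, run_opt)
        entry = {"seed": int(seed),
                 "final_loss": res.loss_history[-1] if res.loss_history
                 else None}
        if eval_fn is not None:
            entry["metric"] = eval_fn(res)
        results.append(entry)
    return results


def embed_split(encoder: NERVEncoder, head: ContrastiveHead,
                ds: SyntheticDataset, split: str = "test") \
        -> tuple[np.ndarray, np.ndarray]:
    """Shared-space (EEG, image) embeddings for one split.

    EEG embeddings are stacked over subjects: shape
    ``(n_subjects * n_images, shared_dim)``; image embeddings are per-image.
    Rows are L2-normalized.
    """
    part = ds.train if split == "train" else ds.test
    encoder.eval()
    head.eval()
    with no_grad():
        img = head.project_image(part.image_embeddings).numpy()
        eeg_rows = []
        for s_idx in range(part.n_subjects):
            feats = encoder.encode(part.eeg[s_idx], ds.subject_ids[s_idx])
            eeg_rows.append(head.project_eeg(feats).numpy())
        eeg = np.concatenate(eeg_rows, axis=0)
    img /= np.linalg.norm(img, axis=1, keepdims=True)
    eeg /= np.linalg.norm(eeg, axis=1, keepdims=True)
    return eeg, img
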