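"""The NERV EEG encoder: convolution + attention mapping trials to embeddings.

Pipeline (per forward pass, input batch ``(B, e, d)``):

1. fixed sinusoidal positional encoding added over the time axis;
2. *channel attention* — a single-head transformer block over the channel
   axis (tokens = electrodes, features = time samples) that reweights
   electrodes by functional relevance;
3. two complementary convolutional branches: *spatial-temporal* (full-height
   spatial filter, then temporal convolution) and *temporal-spatial* (the
   reverse order), each producing ``F`` feature maps over time;
4. branch fusion by concatenation + linear projection to width ``F``;
5. adaptive average pooling of the time axis to ``L`` tokens;
6. multi-head self-attention (5 heads) over the pooled sequence;
7. cross-attention where a learned class token queries the sequence (8
   heads); its output is added residually to every token;
8. flatten (``L*F`` = ``intermediate_dim``, 1440 in the reference
   configuration) and a fully connected layer kept at that width.

A participant-specific linear map (identity-initialized so untrained
subjects are interchangeable) and a residual GELU/dropout projection head
then produce the final ``embed_dim``-D embedding (1024-D reference).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat, gelu, no_grad, unfold_last
from .exceptions import ConfigurationError, ShapeError
from .nn import Dropout, LayerNorm, Linear, Module, MultiheadAttention, \
    TransformerBlock


@dataclass(frozen=True)
class NERVConfig:
    """Architecture hyper-parameters.

    ``intermediate_dim`` must equal ``conv_feature_maps * pooled_len`` for an
    integer pooled sequence length; the constructor solves the pooling length
    and raises if the factorization is impossible.  Head counts default to
    the tuned values: 5 self-attention heads, 1 channel-attention head, 8
    cross-attention heads.
    """

    n_channels: int = 64
    n_samples: int = 250
    conv_feature_maps: int = 40
    temporal_kernel: int = 25
    n_heads_self: int = 5
    n_heads_channel_attn: int = 1
    n_heads_cross: int = 8
    intermediate_dim: int = 1440
    embed_dim: int = 1024
    dropout_p: float = 0.1
    n_subjects: int = 10

    def __post_init__(self):
        F = self.conv_feature_maps
        if self.intermediate_dim % F:
            raise ConfigurationError(
                f"intermediate_dim {self.intermediate_dim} is not a multiple "
                f"of conv_feature_maps {F} (flatten stage cannot match)")
        L = self.intermediate_dim // F
        if L > self.n_samples:
            raise ConfigurationError(
                f"pooled length {L} exceeds n_samples {self.n_samples} "
                "(pooling stage cannot match intermediate_dim)")
        for heads, stage in ((self.n_heads_self, "self-attention"),
                             (self.n_heads_cross, "cross-attention")):
            if F % heads:
                raise ConfigurationError(
                    f"{stage} width {F} not divisible by {heads} heads")
        if self.n_samples % self.n_heads_channel_attn:
            raise ConfigurationError(
                f"channel-attention width {self.n_samples} not divisible by "
                f"{self.n_heads_channel_attn} heads")
        if self.temporal_kernel % 2 == 0 or self.temporal_kernel < 1:
            raise ConfigurationError("temporal_kernel must be odd and >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError("dropout_p must be in [0, 1)")

    @property
    def pooled_len(self) -> int:
        return self.intermediate_dim // self.conv_feature_maps

    @property
    def pool_factor(self) -> float:
        """Approximate time-axis downsampling factor of the pooling stage."""
        return self.n_samples / self.pooled_len

    @staticmethod
    def reference(n_subjects: int = 10) -> "NERVConfig":
        """64 channels x 250 samples -> 1440-D intermediate, 1024-D output."""
        return NERVConfig(n_subjects=n_subjects)

    @staticmethod
    def mini(n_channels: int = 18, n_samples: int = 100,
             n_subjects: int = 2, embed_dim: int = 64) -> "NERVConfig":
        """Desk-scale configuration used by fast experiments and tests."""
        return NERVConfig(n_channels=n_channels, n_samples=n_samples,
                          conv_feature_maps=40, temporal_kernel=9,
                          intermediate_dim=40 * 6, embed_dim=embed_dim,
                          n_subjects=n_subjects)


def _sinusoidal_positional_encoding(e: int, d: int) -> np.ndarray:
    """Fixed (e, d) encoding: position = time sample, feature = channel."""
    pos = np.arange(d)[None, :]
    i = np.arange(e)[:, None]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / max(e, 1))
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


def _adaptive_pool_matrix(d: int, L: int) -> np.ndarray:
    """(L, d) averaging matrix with near-equal contiguous bins."""
    P = np.zeros((L, d))
    for i in range(L):
        lo, hi = i * d // L, (i + 1) * d // L
        P[i, lo:hi] = 1.0 / (hi - lo)
    return P


class NERVEncoder(Module):
    """Encoder state: all learnable parameters plus the configuration."""

    def __init__(self, config: NERVConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        e, d, F = config.n_channels, config.n_samples, config.conv_feature_maps
        k = config.temporal_kernel

        self.pos_enc = _sinusoidal_positional_encoding(e, d)   # constant
        self.pool = _adaptive_pool_matrix(d, config.pooled_len)  # constant

        self.channel_block = TransformerBlock(d, config.n_heads_channel_attn,
                                              rng, ff_mult=1)
        # spatial-temporal branch: full-height spatial filter then temporal conv
        self.spatial_a = Linear(e, F, rng)
        self.temporal_a = Linear(F * k, F, rng)
        # temporal-spatial branch: per-channel temporal conv then spatial mix
        self.temporal_b = Linear(k, F, rng, bias=False)
        self.spatial_b = Linear(e * F, F, rng)
        self.fuse = Linear(2 * F, F, rng)
        self.self_block = TransformerBlock(F, config.n_heads_self, rng)
        self.class_token = Tensor(rng.standard_normal((1, 1, F)) * 0.02,
                                  requires_grad=True)
        self.cross_norm = LayerNorm(F)
        self.cross_attn = MultiheadAttention(F, config.n_heads_cross, rng)
        self.fc = Linear(config.intermediate_dim, config.intermediate_dim, rng)

        # participant-specific linear maps, identity-initialized
        self.subject_layers = []
        for _ in range(config.n_subjects):
            layer = Linear(config.intermediate_dim, config.intermediate_dim,
                           rng)
            layer.weight.data = np.eye(config.intermediate_dim)
            layer.bias.data[:] = 0.0
            self.subject_layers.append(layer)

        # residual projection head -> embed_dim
        self.head_skip = Linear(config.intermediate_dim, config.embed_dim,
                                rng, bias=False)
        self.head_fc1 = Linear(config.intermediate_dim, config.embed_dim, rng)
        self.head_drop = Dropout(config.dropout_p,
                                 seed=int(rng.integers(2 ** 31)))
        self.head_fc2 = Linear(config.embed_dim, config.embed_dim, rng)

        flat = config.pooled_len * F
        if flat != config.intermediate_dim:  # unreachable given config checks
            raise ConfigurationError(
                f"flatten stage yields {flat}, expected "
                f"{config.intermediate_dim}")

    # -- stages ---------------------------------------------------------------
    def forward_features(self, batch) -> Tensor:
        """(B, e, d) trials -> (B, intermediate_dim) features."""
        x = batch if isinstance(batch, Tensor) else Tensor(batch)
        cfg = self.config
        if x.ndim != 3 or x.shape[1:] != (cfg.n_channels, cfg.n_samples):
            raise ShapeError(
                f"expected (B, {cfg.n_channels}, {cfg.n_samples}), "
                f"got {x.shape}")
        B = x.shape[0]
        e, d, F, k = cfg.n_channels, cfg.n_samples, cfg.conv_feature_maps, \
            cfg.temporal_kernel

        x = x + Tensor(self.pos_enc)
        x = self.channel_block(x)                      # (B, e, d)

        # spatial-temporal branch
        a = self.spatial_a(x.transpose(0, 2, 1))       # (B, d, F)
        a = gelu(a)
        a_w = unfold_last(a.transpose(0, 2, 1), k, pad=k // 2)  # (B,F,d,k)
        a = self.temporal_a(a_w.transpose(0, 2, 1, 3).reshape(B, d, F * k))
        a = gelu(a)                                    # (B, d, F)

        # temporal-spatial branch: factorized spatiotemporal convolution.
        # The per-channel temporal filter (k -> F) and the spatial mixer
        # (e*F -> F) compose linearly, so they are merged into one effective
        # (e*k -> F) kernel before touching the batch.
        wt = self.temporal_b.weight                    # (k, F)
        ws = self.spatial_b.weight.reshape(e, F, F).transpose(1, 0, 2) \
            .reshape(F, e * F)                         # (F, e*F)
        w_eff = (wt @ ws).reshape(k, e, F).transpose(1, 0, 2).reshape(e * k, F)
        b_w = unfold_last(x, k, pad=k // 2)            # (B, e, d, k)
        b = b_w.transpose(0, 2, 1, 3).reshape(B, d, e * k) @ w_eff
        b = gelu(b + self.spatial_b.bias)              # (B, d, F)

        h = self.fuse(concat([a, b], axis=-1))         # (B, d, F)
        h = (Tensor(self.pool) @ h)                    # (B, L, F) adaptive pool
        h = self.self_block(h)                         # (B, L, F)

        q = concat([self.class_token] * B, axis=0)     # (B, 1, F)
        ctx = self.cross_norm(h)
        h = h + self.cross_attn(q, ctx, ctx)           # residual class-token add
        flat = h.reshape(B, cfg.intermediate_dim)
        return self.fc(flat)

    def subject_transform(self, features: Tensor, subject_id: int) -> Tensor:
        if not 0 <= subject_id < self.config.n_subjects:
            raise KeyError(
                f"subject_id {subject_id} out of range "
                f"[0, {self.config.n_subjects})")
        f = features if isinstance(features, Tensor) else Tensor(features)
        return self.subject_layers[subject_id](f)

    def project(self, features: Tensor) -> Tensor:
        h = self.head_drop(gelu(self.head_fc1(features)))
        return self.head_skip(features) + self.head_fc2(h)

    def encode_batch(self, batch, subject_id: int) -> Tensor:
        """(B, e, d) trials -> (B, embed_dim) embeddings for one subject."""
        feats = self.forward_features(batch)
        feats = self.subject_transform(feats, subject_id)
        return self.project(feats)

    def encode(self, batch, subject_id: int) -> np.ndarray:
        """Inference helper: eval mode, no taping, numpy output."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.encode_batch(batch, subject_id).numpy()
        finally:
            if was_training:
                self.train()
        return out


def build_encoder(config: NERVConfig, seed: int = 0) -> NERVEncoder:
    """Deterministically initialize an encoder from ``config`` and ``seed``."""
    return NERVEncoder(config, seed)


def encoder_checkpoint(enc: NERVEncoder) -> dict:
    """Serializable checkpoint payload (parameters + config + seed)."""
    return {"format_version": 1,
            "config": dataclasses.asdict(enc.config),
            "seed": enc.seed,
            "state": enc.state_dict()}


def encoder_from_checkpoint(payload: dict) -> NERVEncoder:
    enc = NERVEncoder(NERVConfig(**payload["config"]), payload["seed"])
    enc.load_state_dict(payload["state"])
    return enc
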