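"""Embedding-space denoising diffusion prior with classifier-free guidance.

The prior translates an EEG embedding ``E`` (the condition) into a clean
image embedding by reversing a diffusion process that runs directly on
embedding vectors.  Forward noising uses the cosine cumulative-signal
schedule; the denoiser ``eps(I_t, t, E)`` is a 6-block residual network
with mirrored skip connections (3 "down" widths, 3 "up"), each block
conditioned on a sinusoidal time embedding and the condition vector via
feature-wise modulation.  Training randomly replaces ~10% of conditions
with a learned null token so a single network supports both conditional
and unconditional prediction; sampling blends the two as

    eps_hat = eps_null + w * (eps_cond - eps_null),   w >= 0,

with guidance scale w = 3.5 and 50 ancestral sampling steps by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat, gelu, no_grad
from .exceptions import ShapeError
from .nn import AdamW, LayerNorm, Linear, Module


# --------------------------------------------------------------------------
# noise schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSchedule:
    """Cumulative signal coefficients alpha_bar[0..T] of a diffusion chain."""

    T: int
    alpha_bar: np.ndarray        # length T+1, alpha_bar[0] == 1, decreasing
    s: float = 0.008

    def __post_init__(self):
        if self.alpha_bar[0] != 1.0:
            raise ValueError("alpha_bar[0] must be exactly 1")
        if not np.all(np.diff(self.alpha_bar) < 0):
            raise ValueError("alpha_bar must be strictly decreasing")


def cosine_alpha_bar(T: int, s: float = 0.008) -> NoiseSchedule:
    """Cosine schedule: alpha_bar(t) = f(t)/f(0), f(t)=cos^2(((t/T+s)/(1+s)) pi/2)."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    t = np.arange(T + 1)
    f = np.cos(((t / T + s) / (1.0 + s)) * (np.pi / 2.0)) ** 2
    alpha_bar = f / f[0]
    alpha_bar[0] = 1.0
    # floor the terminal coefficient so eps -> x0 conversion stays finite
    alpha_bar = np.maximum(alpha_bar, 1e-9)
    return NoiseSchedule(T=T, alpha_bar=alpha_bar, s=s)


def forward_diffuse(I0: np.ndarray, t: int, eps: np.ndarray,
                    sched: NoiseSchedule) -> np.ndarray:
    """Noisy embedding at step t: sqrt(ab_t) I0 + sqrt(1 - ab_t) eps."""
    if not 0 <= t <= sched.T:
        raise ValueError(f"t={t} outside [0, {sched.T}]")
    ab = sched.alpha_bar[t]
    return np.sqrt(ab) * np.asarray(I0) + np.sqrt(1.0 - ab) * np.asarray(eps)


# --------------------------------------------------------------------------
# prior network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    embed_dim: int = 64
    n_layers: int = 6
    hidden_dim: int = 128
    cond_dropout_p: float = 0.10
    guidance_w: float = 3.5
    sample_steps: int = 50
    T: int = 1000
    s: float = 0.008
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.cond_dropout_p < 1.0:
            raise ValueError("cond_dropout_p must be in [0, 1)")
        if self.guidance_w < 0:
            raise ValueError("guidance_w must be >= 0")
        if not 1 <= self.sample_steps <= self.T:
            raise ValueError("sample_steps must be in [1, T]")
        if self.n_layers != 6:
            raise ValueError("the prior is a fixed 6-block network")


def _time_embedding(t: np.ndarray, dim: int, T: int) -> np.ndarray:
    """Sinusoidal embedding of (possibly per-sample) diffusion steps."""
    t = np.atleast_1d(np.asarray(t, dtype=float)) / T
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(1000.0), half))
    angles = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(angles), np.cos(angles)], axis=1)


class _FiLMBlock(Module):
    """Residual MLP block modulated by the conditioning context."""

    def __init__(self, d_in: int, d_out: int, ctx_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(d_in)
        self.fc1 = Linear(d_in, d_out, rng)
        self.film = Linear(ctx_dim, 2 * d_out, rng)
        self.fc2 = Linear(d_out, d_out, rng)
        self.skip = Linear(d_in, d_out, rng, bias=False) if d_in != d_out \
            else None
        self.d_out = d_out

    def __call__(self, x: Tensor, ctx: Tensor) -> Tensor:
        h = gelu(self.fc1(self.norm(x)))
        mod = self.film(ctx)
        scale, shift = mod[:, :self.d_out], mod[:, self.d_out:]
        h = h * (scale + 1.0) + shift
        h = self.fc2(h)
        return h + (self.skip(x) if self.skip is not None else x)


class PriorState(Module):
    """Denoiser parameters, learned null token, schedule and config."""

    def __init__(self, config: PriorConfig):
        super().__init__()
        self.config = config
        self.schedule = cosine_alpha_bar(config.T, config.s)
        rng = np.random.default_rng(config.seed)
        D, W = config.embed_dim, config.hidden_dim
        ctx = W
        self.null_token = Tensor(rng.standard_normal(D) * 0.02,
                                 requires_grad=True)
        self.time_mlp = Linear(W, ctx, rng)
        self.cond_mlp = Linear(D, ctx, rng)
        self.in_proj = Linear(D, W, rng)
        # 3 "down" blocks, then 3 "up" blocks fed by mirrored skip concats
        self.down1 = _FiLMBlock(W, W, ctx, rng)
        self.down2 = _FiLMBlock(W, W, ctx, rng)
        self.down3 = _FiLMBlock(W, W, ctx, rng)
        self.up1 = _FiLMBlock(2 * W, W, ctx, rng)
        self.up2 = _FiLMBlock(2 * W, W, ctx, rng)
        self.up3 = _FiLMBlock(2 * W, W, ctx, rng)
        self.out = Linear(W, D, rng)
        self.out.weight.data *= 0.1
        self._time_dim = W

    def _forward(self, x_t: Tensor, t: np.ndarray, cond: Tensor) -> Tensor:
        temb = Tensor(_time_embedding(t, self._time_dim, self.config.T))
        ctx = gelu(self.time_mlp(temb) + self.cond_mlp(cond))
        x0 = self.in_proj(x_t)
        d1 = self.down1(x0, ctx)
        d2 = self.down2(d1, ctx)
        d3 = self.down3(d2, ctx)
        u1 = self.up1(concat([d3, d2], axis=-1), ctx)
        u2 = self.up2(concat([u1, d1], axis=-1), ctx)
        u3 = self.up3(concat([u2, x0], axis=-1), ctx)
        return self.out(u3)


def build_prior(config: PriorConfig) -> PriorState:
    return PriorState(config)


def _as_batch(x: np.ndarray, D: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != D:
        raise ShapeError(f"{what} must be (B, {D}) or ({D},), got {x.shape}")
    return x


def prior_predict_noise(state: PriorState, I_t: np.ndarray, t,
                        condition: np.ndarray | None) -> np.ndarray:
    """Predicted noise eps_hat(I_t, t, condition); None selects the null token."""
    D = state.config.embed_dim
    squeeze = np.asarray(I_t).ndim == 1
    I_t = _as_batch(I_t, D, "I_t")
    B = len(I_t)
    if condition is None:
        cond = np.broadcast_to(state.null_token.numpy(), (B, D))
    else:
        cond = np.broadcast_to(_as_batch(condition, D, "condition"), (B, D))
    t_arr = np.broadcast_to(np.atleast_1d(t), (B,))
    state.eval()
    with no_grad():
        out = state._forward(Tensor(I_t), t_arr, Tensor(cond.copy())).numpy()
    return out[0] if squeeze else out


@dataclass
class PriorOptConfig:
    """Prior training hyper-parameters.

    ``cond_noise_sd`` adds Gaussian jitter to the (unit-norm) condition
    embeddings during training, renormalizing afterwards.  Test-time
    conditions are EEG embeddings of unseen categories, so smoothing the
    conditional field this way is a generalization regularizer in the same
    spirit as the classifier-free condition dropout.
    """

    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 256
    steps: int = 800
    cond_noise_sd: float = 0.0
    seed: int = 0


def train_prior(state: PriorState, E: np.ndarray, I: np.ndarray,
                opt: PriorOptConfig | None = None) -> list[float]:
    """Train by denoising score matching: MSE(eps_hat, eps) at uniform t.

    Each batch element's condition is replaced by the null token with
    probability ``cond_dropout_p`` (classifier-free training).  Returns the
    per-step loss history.
    """
    opt = opt or PriorOptConfig()
    D = state.config.embed_dim
    E = _as_batch(E, D, "E")
    I = _as_batch(I, D, "I")
    if len(E) != len(I):
        raise ValueError("E and I must pair up")
    if len(E) == 0:
        raise ValueError("empty training pairs")
    rng = np.random.default_rng(opt.seed)
    sched = state.schedule
    optimizer = AdamW(state.parameters(), lr=opt.lr, betas=opt.betas)
    history = []
    state.train()
    n = len(E)
    p = state.config.cond_dropout_p
    for _ in range(opt.steps):
        rows = rng.integers(n, size=min(opt.batch_size, n))
        t = rng.integers(1, sched.T + 1, size=len(rows))
        eps = rng.standard_normal((len(rows), D))
        ab = sched.alpha_bar[t][:, None]
        x_t = np.sqrt(ab) * I[rows] + np.sqrt(1.0 - ab) * eps
        cond_np = E[rows]
        if opt.cond_noise_sd > 0:
            cond_np = cond_np + opt.cond_noise_sd * rng.standard_normal(
                (len(rows), D))
            cond_np = cond_np / np.linalg.norm(cond_np, axis=1,
                                               keepdims=True)
        drop = rng.random(len(rows)) < p
        cond = Tensor(cond_np * ~drop[:, None]) \
            + state.null_token * Tensor(drop[:, None].astype(float))
        pred = state._forward(Tensor(x_t), t, cond)
        diff = pred - Tensor(eps)
        loss = (diff * diff).mean()
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        history.append(loss.item())
    state.eval()
    return history


def guided_noise(state: PriorState, I_t: np.ndarray, t,
                 E: np.ndarray, w: float) -> np.ndarray:
    """Classifier-free-guided noise estimate.

    ``w=0`` is the unconditional branch, ``w=1`` the conditional branch.
    """
    if w < 0:
        raise ValueError(f"guidance scale w must be >= 0, got {w}")
    eps_u = prior_predict_noise(state, I_t, t, None)
    eps_c = prior_predict_noise(state, I_t, t, E)
    return eps_u + w * (eps_c - eps_u)


def sample_embedding(state: PriorState, E: np.ndarray,
                     steps: int | None = None, w: float | None = None,
                     rng: np.random.Generator | int | None = None) \
        -> np.ndarray:
    """Ancestral sampling of a clean embedding conditioned on ``E``.

    Starts from Gaussian noise and denoises over an evenly strided subset
    of the schedule (defaults: 50 steps, w=3.5).  Deterministic given the
    seeded generator; the final step adds no noise.
    """
    cfg = state.config
    steps = cfg.sample_steps if steps is None else steps
    w = cfg.guidance_w if w is None else w
    if w < 0:
        raise ValueError("guidance scale w must be >= 0")
    if not 1 <= steps <= cfg.T:
        raise ValueError(f"steps must be in [1, {cfg.T}]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    squeeze = np.asarray(E).ndim == 1
    E = _as_batch(E, cfg.embed_dim, "E")
    B = len(E)
    ab = state.schedule.alpha_bar
    ts = np.unique(np.linspace(0, cfg.T, steps + 1).astype(int))[::-1]
    x = rng.standard_normal((B, cfg.embed_dim))
    for i in range(len(ts) - 1):
        t, t_prev = int(ts[i]), int(ts[i + 1])
        eps_hat = guided_noise(state, x, t, E, w)
        ab_t, ab_p = ab[t], ab[t_prev]
        x0_hat = (x - np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(ab_t)
        # static thresholding: embeddings live near the unit sphere, so a
        # generous clip only guards the first steps from pure noise
        x0_hat = np.clip(x0_hat, -5.0, 5.0)
        if t_prev == 0:
            x = x0_hat
            break
        var = (1.0 - ab_p) / (1.0 - ab_t) * (1.0 - ab_t / ab_p)
        var = max(var, 0.0)
        dir_coef = np.sqrt(max(1.0 - ab_p - var, 0.0))
        x = np.sqrt(ab_p) * x0_hat + dir_coef * eps_hat \
            + np.sqrt(var) * rng.standard_normal(x.shape)
    return x[0] if squeeze else x


def refine_embedding(state: PriorState, E: np.ndarray,
                     n_samples: int = 4, steps: int | None = None,
                     w: float | None = None,
                     rng: np.random.Generator | int | None = None) \
        -> np.ndarray:
    """Two-stage refinement estimate: mean of ``n_samples`` prior samples.

    Averaging ancestral samples approximates the conditional mean of the
    clean image embedding given the EEG condition, trading sample diversity
    for a lower-variance point estimate (the analogue of candidate
    selection in embedding-space priors).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    samples = [sample_embedding(state, E, steps=steps, w=w, rng=rng)
               for _ in range(n_samples)]
    return np.mean(samples, axis=0)


def prior_checkpoint(state: PriorState) -> dict:
    return {"format_version": 1,
            "config": dataclasses.asdict(state.config),
            "state": state.state_dict()}


def prior_from_checkpoint(payload: dict) -> PriorState:
    state = PriorState(PriorConfig(**payload["config"]))
    state.load_state_dict(payload["state"])
    return state
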