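"""End-to-end two-stage pipeline with a validated run configuration.

Stages: simulate -> train encoder (contrastive) -> zero-shot retrieval ->
train diffusion prior -> sample refined embeddings (1-stage = raw EEG
embeddings, 2-stage = prior-refined) -> toy generation -> CAT + FID ->
optional channel perturbation.  Every output file is listed in a manifest
with its SHA-256 hash; all randomness flows from the named seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .contrastive import ContrastiveHead, OptConfig, embed_split, \
    fit_contrastive
from .encoder import NERVConfig, build_encoder
from .exceptions import ConfigurationError
from .metrics import ToyImageDecoder, cat_score, fid
from .montage import MONTAGE_18, MONTAGE_64
from .perturb import PerturbationSpec, run_perturbation_experiment
from .prior import PriorConfig, PriorOptConfig, build_prior, \
    refine_embedding, train_prior
from .retrieval import evaluate_nway
from .synthetic import DEFAULT_TAG_VOCABULARY, assemble_dataset, \
    make_concept_bank, make_forward_model, make_tag_cards

log = logging.getLogger("eeg2img")


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class DatasetConfig:
    n_categories: int = 100
    n_test: int = 20
    d_img: int = 64
    images_per_train_cat: int = 3
    reps: int = 4
    n_subjects: int = 2
    montage: str = "mini"          # "mini" (18 ch) or "reference" (64 ch)
    sampling_rate: float = 100.0
    rank: int = 8
    posterior_boost: float = 4.0
    noise_sd: float = 0.1
    sigma_img: float = 0.05

    def channel_names(self):
        if self.montage == "mini":
            return MONTAGE_18
        if self.montage == "reference":
            return MONTAGE_64
        raise ConfigurationError(f"unknown montage {self.montage!r}")


@dataclass
class EncoderConfig:
    conv_feature_maps: int = 40
    temporal_kernel: int = 9
    pooled_len: int = 6
    embed_dim: int = 64
    dropout_p: float = 0.1

    def to_nerv(self, n_channels: int, n_samples: int,
                n_subjects: int) -> NERVConfig:
        return NERVConfig(
            n_channels=n_channels, n_samples=n_samples,
            conv_feature_maps=self.conv_feature_maps,
            temporal_kernel=self.temporal_kernel,
            intermediate_dim=self.conv_feature_maps * self.pooled_len,
            embed_dim=self.embed_dim, dropout_p=self.dropout_p,
            n_subjects=n_subjects)


@dataclass
class TrainConfig:
    lr: float = 2e-4
    batch_size: int = 1024
    epochs: int = 25


@dataclass
class PriorRunConfig:
    hidden_dim: int = 256
    T: int = 1000
    sample_steps: int = 50
    guidance_w: float = 3.5
    cond_dropout_p: float = 0.10
    lr: float = 1e-3
    steps: int = 800
    batch_size: int = 256
    cond_noise_sd: float = 0.2
    refine_samples: int = 4


@dataclass
class EvalConfig:
    n_ways: tuple[int, ...] = (2, 4, 10)
    n_trials: int = 500


@dataclass
class PerturbationRunConfig:
    enabled: bool = True
    n_way: int = 2


@dataclass
class RunConfig:
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    prior: PriorRunConfig = field(default_factory=PriorRunConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    perturbation: PerturbationRunConfig = field(
        default_factory=PerturbationRunConfig)
    seed: int = 0
    out_dir: str = "runs/default"
    log_level: str = "INFO"

    def __post_init__(self):
        if max(self.eval.n_ways) > self.dataset.n_test:
            raise ConfigurationError(
                f"n_way {max(self.eval.n_ways)} exceeds the "
                f"{self.dataset.n_test} test categories")

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        parsed = {}
        for key, sub in (("dataset", DatasetConfig),
                         ("encoder", EncoderConfig), ("train", TrainConfig),
                         ("prior", PriorRunConfig), ("eval", EvalConfig),
                         ("perturbation", PerturbationRunConfig)):
            if key in d:
                sub_d = d.pop(key)
                if key == "eval" and "n_ways" in sub_d:
                    sub_d["n_ways"] = tuple(sub_d["n_ways"])
                parsed[key] = _from_dict(sub, sub_d)
        cfg = _from_dict(RunConfig, {**d, **parsed})
        return cfg

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=float))


def simulate(cfg: RunConfig):
    ds_cfg = cfg.dataset
    bank = make_concept_bank(ds_cfg.n_categories, ds_cfg.d_img,
                             ds_cfg.n_test, seed=cfg.seed)
    fm = make_forward_model(ds_cfg.channel_names(), ds_cfg.sampling_rate,
                            ds_cfg.rank, ds_cfg.d_img,
                            ds_cfg.posterior_boost, ds_cfg.noise_sd,
                            seed=cfg.seed + 1)
    ds = assemble_dataset(bank, fm, ds_cfg.images_per_train_cat, ds_cfg.reps,
                          ds_cfg.n_subjects, seed=cfg.seed + 2,
                          sigma_img=ds_cfg.sigma_img)
    return bank, fm, ds


def tags_from_nearest_category(gen_embs: np.ndarray, img_embs: np.ndarray,
                               cards) -> list[set[str]]:
    """Stand-in tag adjudication: each generated embedding inherits the tag
    card of its nearest test image embedding (cosine).  An embedding that
    lands near the right category therefore earns that category's points."""
    gen = gen_embs / np.linalg.norm(gen_embs, axis=1, keepdims=True)
    img = img_embs / np.linalg.norm(img_embs, axis=1, keepdims=True)
    nearest = np.argmax(gen @ img.T, axis=1)
    return [set(cards[j].tags) for j in nearest]


def run_two_stage(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    manifest: dict = {"config": dataclasses.asdict(cfg), "seed": cfg.seed,
                      "stages": [], "files": {}}
    manifest_path = out / "manifest.json"

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    def finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        _write_json(manifest_path, manifest)

    stage = "simulate"
    try:
        bank, fm, ds = simulate(cfg)
        eio.save_dataset(ds, out / "dataset.h5")
        record("dataset", out / "dataset.h5")
        finish_stage(stage)

        stage = "train_encoder"
        nerv_cfg = cfg.encoder.to_nerv(len(ds.channel_names),
                                       fm.n_samples, cfg.dataset.n_subjects)
        encoder = build_encoder(nerv_cfg, seed=cfg.seed)
        opt = OptConfig(lr=cfg.train.lr, batch_size=cfg.train.batch_size,
                        epochs=cfg.train.epochs, seed=cfg.seed)
        result = fit_contrastive(encoder, ds, opt)
        eio.save_encoder(encoder, out / "encoder.npz")
        record("encoder", out / "encoder.npz")
        np.savetxt(out / "loss_history.csv",
                   np.asarray(result.loss_history), header="loss",
                   comments="")
        record("loss_history", out / "loss_history.csv")
        finish_stage(stage)

        stage = "retrieval_stage1"
        eeg, img = embed_split(encoder, result.head, ds, "test")
        labels = ds.test.category_ids
        stage1 = [evaluate_nway(eeg, img, labels, n, 1, cfg.eval.n_trials,
                                rng=cfg.seed).to_dict()
                  for n in cfg.eval.n_ways]
        _write_json(out / "retrieval_stage1.json", stage1)
        record("retrieval_stage1", out / "retrieval_stage1.json")
        finish_stage(stage)

        stage = "train_prior"
        train_eeg, train_img = embed_split(encoder, result.head, ds, "train")
        n_sub = ds.train.n_subjects
        prior = build_prior(PriorConfig(
            embed_dim=train_eeg.shape[1], hidden_dim=cfg.prior.hidden_dim,
            cond_dropout_p=cfg.prior.cond_dropout_p,
            guidance_w=cfg.prior.guidance_w,
            sample_steps=cfg.prior.sample_steps, T=cfg.prior.T,
            seed=cfg.seed))
        train_prior(prior, train_eeg, np.tile(train_img, (n_sub, 1)),
                    PriorOptConfig(lr=cfg.prior.lr, steps=cfg.prior.steps,
                                   batch_size=cfg.prior.batch_size,
                                   cond_noise_sd=cfg.prior.cond_noise_sd,
                                   seed=cfg.seed))
        eio.save_prior(prior, out / "prior.npz")
        record("prior", out / "prior.npz")
        finish_stage(stage)

        stage = "sample_and_retrieve_stage2"
        refined = refine_embedding(prior, eeg,
                                   n_samples=cfg.prior.refine_samples,
                                   rng=cfg.seed)
        stage2 = [evaluate_nway(refined, img, labels, n, 1,
                                cfg.eval.n_trials, rng=cfg.seed).to_dict()
                  for n in cfg.eval.n_ways]
        _write_json(out / "retrieval_stage2.json", stage2)
        record("retrieval_stage2", out / "retrieval_stage2.json")
        finish_stage(stage)

        stage = "generate_and_score"
        decoder = ToyImageDecoder(refined.shape[1], seed=cfg.seed)
        cards = make_tag_cards(bank, DEFAULT_TAG_VOCABULARY,
                               np.random.default_rng(cfg.seed),
                               image_ids=ds.test.image_ids)
        eio.save_tag_cards(cards, out / "tag_cards.csv")
        record("tag_cards", out / "tag_cards.csv")
        n_img = ds.test.n_images
        scores = {}
        import warnings
        for name, embs in (("stage1", eeg), ("stage2", refined)):
            tags = tags_from_nearest_category(embs[:n_img], img, cards)
            cat = cat_score(tags, cards)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = fid(np.tile(img, (n_sub, 1)), embs)
            scores[name] = {"cat_total": cat.total,
                            "cat_max": cat.max_possible, "fid": f.value}
        _write_json(out / "generation_metrics.json", scores)
        record("generation_metrics", out / "generation_metrics.json")
        finish_stage(stage)

        if cfg.perturbation.enabled:
            stage = "perturbation"
            report = run_perturbation_experiment(
                encoder, result.head, ds, PerturbationSpec(seed=cfg.seed),
                prior=prior, n_way=cfg.perturbation.n_way,
                n_trials=cfg.eval.n_trials, seed=cfg.seed)
            _write_json(out / "perturbation.json", report.to_dict())
            record("perturbation", out / "perturbation.json")
            finish_stage(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_json(manifest_path, manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_json(manifest_path, manifest)
    return manifest
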