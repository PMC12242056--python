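"""File formats: HDF5 datasets, JSON/CSV tag cards, npz checkpoints.

Dataset layout (HDF5): groups ``/train`` and ``/test``, each with datasets
``eeg`` (n_subjects, n_images, e, d), ``image_embedding`` (n_images, D),
``category_id`` and ``image_id``; channel names, sampling rate and subject
ids are stored as root attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .encoder import NERVEncoder, encoder_checkpoint, encoder_from_checkpoint
from .prior import PriorState, prior_checkpoint, prior_from_checkpoint
from .synthetic import SplitData, SyntheticDataset, TagCard

TAG_COLUMNS = ["image_id", "broad_1", "broad_2", "specific", "background",
               "attribute"]


def save_dataset(ds: SyntheticDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["channel_names"] = list(ds.channel_names)
        f.attrs["sampling_rate"] = ds.sampling_rate
        f.attrs["subject_ids"] = list(ds.subject_ids)
        for name, split in (("train", ds.train), ("test", ds.test)):
            g = f.create_group(name)
            g.create_dataset("eeg", data=split.eeg)
            g.create_dataset("image_embedding", data=split.image_embeddings)
            g.create_dataset("category_id", data=split.category_ids)
            g.create_dataset("image_id", data=split.image_ids)


def load_dataset(path) -> SyntheticDataset:
    with h5py.File(path, "r") as f:
        splits = {}
        for name in ("train", "test"):
            g = f[name]
            splits[name] = SplitData(
                eeg=g["eeg"][()],
                image_embeddings=g["image_embedding"][()],
                category_ids=g["category_id"][()],
                image_ids=g["image_id"][()])
        return SyntheticDataset(
            train=splits["train"], test=splits["test"],
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            subject_ids=tuple(int(s) for s in f.attrs["subject_ids"]))


def save_tag_cards(cards: list[TagCard], path) -> None:
    """JSON (list of objects) or CSV depending on the file suffix."""
    path = Path(path)
    rows = [{"image_id": c.image_id, "broad_1": c.broad_1,
             "broad_2": c.broad_2, "specific": c.specific,
             "background": c.background, "attribute": c.attribute}
            for c in cards]
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=TAG_COLUMNS).to_csv(path, index=False)


def load_tag_cards(path) -> list[TagCard]:
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    return [TagCard(image_id=int(r["image_id"]), broad_1=r["broad_1"],
                    broad_2=r["broad_2"], specific=r["specific"],
                    background=r["background"], attribute=r["attribute"])
            for r in rows]


def load_generated_tags(path) -> dict[int, set[str]]:
    """JSON mapping image_id -> list of tags for the generated images."""
    raw = json.loads(Path(path).read_text())
    return {int(k): {str(t).strip().lower() for t in v}
            for k, v in raw.items()}


def _save_checkpoint(payload: dict, path) -> None:
    meta = {k: v for k, v in payload.items() if k != "state"}
    arrays = {f"state/{k}": v for k, v in payload["state"].items()}
    with open(path, "wb") as fh:   # keep the exact path (no .npz appended)
        np.savez(fh, __meta__=np.bytes_(json.dumps(meta)), **arrays)


def _load_checkpoint(path) -> dict:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        meta["state"] = {k[len("state/"):]: f[k] for k in f.files
                         if k.startswith("state/")}
    return meta


def save_encoder(enc: NERVEncoder, path) -> None:
    _save_checkpoint(encoder_checkpoint(enc), path)


def load_encoder(path) -> NERVEncoder:
    return encoder_from_checkpoint(_load_checkpoint(path))


def save_prior(state: PriorState, path) -> None:
    _save_checkpoint(prior_checkpoint(state), path)


def load_prior(path) -> PriorState:
    return prior_from_checkpoint(_load_checkpoint(path))
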