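"""Model checkpoint persistence.

A checkpoint is a single ``.npz`` holding every parameter array plus a JSON
metadata blob: the model constructor arguments, the token vocabulary, the
label vocabulary ORDER at save time (head banks must reload against the
same label order to keep head↔label alignment), registered marker tokens
and any frozen prototype vectors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .augmentation import PrototypeTable
from .corpus import LabelVocabulary
from .encoders import TokenVocabulary
from .training import JointModel

__all__ = ["save_model", "load_model"]

_META_KEY = "__meta__"


def save_model(model: JointModel, path, model_kwargs: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "model_kwargs": model_kwargs,
        "tokens": sorted(model.bundle.ner_encoder.vocab._index,
                         key=model.bundle.ner_encoder.vocab._index.get),
        "entity_types": list(model.vocab.entity_types),
        "relation_types": list(model.vocab.relation_types),
        "prototypes": ({k: v.tolist() for k, v in model.prototypes.vectors.items()}
                       if model.prototypes is not None else None),
    }
    arrays = {f"param::{name}": arr for name, arr in model.state_dict().items()}
    arrays[_META_KEY] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path) -> tuple[JointModel, dict]:
    with np.load(path, allow_pickle=False) as blob:
        meta = json.loads(bytes(blob[_META_KEY]).decode("utf-8"))
        params = {k[len("param::"):]: blob[k] for k in blob.files
                  if k.startswith("param::")}
    tokens = meta["tokens"]
    token_vocab = TokenVocabulary(tokens)
    label_vocab = LabelVocabulary(meta["entity_types"], meta["relation_types"])
    model = JointModel(token_vocab, label_vocab, **meta["model_kwargs"])
    if meta["prototypes"] is not None:
        model.prototypes = PrototypeTable(
            vectors={k: np.asarray(v) for k, v in meta["prototypes"].items()})
    model.load_state_dict(params)
    return model, meta
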