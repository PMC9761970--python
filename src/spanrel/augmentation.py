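"""Relation-pair representations and the four augmentation modes.

The relation classifier scores a pair of entity mentions from a joined
vector built in one of four ways:

* ``vanilla`` — concatenation of the two span-summed RE hidden states (2d);
* ``type_embedding`` — vanilla interleaved with learned 50-d embeddings of
  the two entity-type labels (2d + 100);
* ``prototype`` — vanilla interleaved with frozen 50-d entity-type
  prototypes computed from the untrained base encoder before training
  (2d + 100);
* ``entity_marker`` — the sentence is rewritten with ``[Type_start]`` /
  ``[Type_end]`` tokens around each mention and the pair vector is the
  concatenation of the two start markers' hidden states (2d).

Type labels feeding the aux lookups are gold during training and predicted
during inference.  Span sums are plain sums (not means).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, no_grad
from .corpus import EntityMention, Sentence
from .layers import Module

__all__ = [
    "MarkedSentence", "insert_entity_markers", "strip_markers",
    "TypeEmbeddingTable", "PrototypeTable", "compute_prototypes",
    "maxpool_reduce", "pair_representation", "PairRepresentation",
    "AUGMENTATION_MODES",
]

AUGMENTATION_MODES = ("vanilla", "type_embedding", "prototype", "entity_marker")

_MARKER_RE = re.compile(r"^\[[^\[\]]+_(start|end)\]$")


@dataclass
class MarkedSentence:
    tokens: tuple[str, ...]
    start_marker_pos: dict[str, int]        # mention id -> index of its start marker
    marked_to_orig: dict[int, int]          # marked index -> original index (non-markers)

    def __len__(self):
        return len(self.tokens)


def insert_entity_markers(sentence: Sentence,
                          mentions: list[EntityMention]) -> MarkedSentence:
    """Wrap each mention in ``[Type_start]`` … ``[Type_end]`` tokens.

    Mentions must be non-overlapping; insertion preserves left-to-right text
    order, and the returned index maps make the rewriting invertible.
    """
    ordered = sorted(mentions, key=lambda m: m.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start <= prev.end:
            raise ValueError(
                f"overlapping mentions {prev.mention_id or prev.span} / "
                f"{cur.mention_id or cur.span}")
    for m in ordered:
        if m.end >= sentence.n:
            raise ValueError(f"mention {m.span} outside sentence of length {sentence.n}")

    starts = {m.start: m for m in ordered}
    ends = {m.end: m for m in ordered}
    tokens: list[str] = []
    start_marker_pos: dict[str, int] = {}
    marked_to_orig: dict[int, int] = {}
    for i, tok in enumerate(sentence.tokens):
        if i in starts:
            m = starts[i]
            start_marker_pos[m.mention_id] = len(tokens)
            tokens.append(f"[{m.type_label}_start]")
        marked_to_orig[len(tokens)] = i
        tokens.append(tok)
        if i in ends:
            tokens.append(f"[{ends[i].type_label}_end]")
    return MarkedSentence(tuple(tokens), start_marker_pos, marked_to_orig)


def strip_markers(marked: MarkedSentence | tuple[str, ...]) -> tuple[str, ...]:
    """Remove marker tokens, recovering the original token list exactly."""
    tokens = marked.tokens if isinstance(marked, MarkedSentence) else tuple(marked)
    return tuple(t for t in tokens if not _MARKER_RE.match(t))


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

class TypeEmbeddingTable(Module):
    """Learned 50-d embedding per entity type; appendable as types arrive."""

    def __init__(self, entity_types=(), dim: int = 50, seed: int = 0):
        super().__init__()
        self.dim = dim
        self._rng = np.random.default_rng(seed)
        self._table: dict[str, Tensor] = {}
        for t in entity_types:
            self.add_type(t)

    def add_type(self, label: str) -> None:
        if label not in self._table:
            vec = Tensor(self._rng.normal(0.0, 0.1, size=(self.dim,)),
                         requires_grad=True)
            self._table[label] = vec
            self._params[f"emb:{label}"] = vec

    def __contains__(self, label):
        return label in self._table

    def __len__(self):
        return len(self._table)

    def lookup(self, label: str) -> Tensor:
        if label not in self._table:
            raise KeyError(f"no embedding for entity type {label!r}")
        return self._table[label]


@dataclass(frozen=True)
class PrototypeTable:
    """Frozen 50-d prototype per entity type, fixed before training."""
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    dim: int = 50

    def lookup(self, label: str) -> np.ndarray:
        if label not in self.vectors:
            raise KeyError(f"no prototype for entity type {label!r}")
        return self.vectors[label]

    def __contains__(self, label):
        return label in self.vectors


def maxpool_reduce(vec: np.ndarray, out_dim: int = 50) -> np.ndarray:
    """Reduce a d-vector to ``out_dim`` by a chunked max: the vector is
    partitioned into ``out_dim`` contiguous chunks, each contributing its
    maximum."""
    vec = np.asarray(vec, dtype=np.float64)
    if vec.ndim != 1 or vec.size < out_dim:
        raise ValueError(f"need a 1-d vector of length >= {out_dim}, got {vec.shape}")
    return np.array([chunk.max() for chunk in np.array_split(vec, out_dim)])


def compute_prototypes(train_corpus, base_encoder, out_dim: int = 50,
                       entity_types=None) -> PrototypeTable:
    """Per-type mean of the max-pooled UNTRAINED base-encoder token vectors.

    For every mention token of a type, the base encoder's d-vector (computed
    in the token's sentence context) is reduced to ``out_dim`` dims by
    chunked max-pooling; the prototype is the mean over all such tokens.
    The table is frozen — training never touches it.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    with no_grad():
        for sent, mentions, _ in train_corpus.annotated():
            if not mentions:
                continue
            h = base_encoder(list(sent.tokens)).data
            for m in mentions:
                for i in range(m.start, m.end + 1):
                    pooled = maxpool_reduce(h[i], out_dim)
                    if m.type_label not in sums:
                        sums[m.type_label] = np.zeros(out_dim)
                        counts[m.type_label] = 0
                    sums[m.type_label] += pooled
                    counts[m.type_label] += 1
    if entity_types is not None:
        missing = [t for t in entity_types if counts.get(t, 0) == 0]
        if missing:
            raise ValueError(
                f"no mention tokens in the training corpus for types {missing}")
    vectors = {t: sums[t] / counts[t] for t in sums}
    return PrototypeTable(vectors=vectors, dim=out_dim)


# ---------------------------------------------------------------------------
# pair representations
# ---------------------------------------------------------------------------

@dataclass
class PairRepresentation:
    vector: Tensor
    mode: str
    mention_ids: tuple[str, str]

    @property
    def dim(self) -> int:
        return int(self.vector.shape[-1])


def _span_sum(h: Tensor, mention: EntityMention) -> Tensor:
    n = h.shape[0]
    if mention.end >= n:
        raise ValueError(f"span {mention.span} outside hidden states of length {n}")
    return h[mention.start:mention.end + 1].sum(axis=0)


def pair_representation(mode: str, h_re: Tensor, e_j: EntityMention,
                        e_k: EntityMention, aux=None,
                        type_labels: tuple[str, str] | None = None) -> PairRepresentation:
    """Build the joined RE vector for a mention pair under one mode.

    ``h_re`` is in marked coordinates for ``entity_marker`` mode (with
    ``aux`` the start-marker position map) and raw coordinates otherwise.
    ``type_labels`` supplies the (gold or predicted) types for the lookup
    modes.
    """
    if mode not in AUGMENTATION_MODES:
        raise ValueError(f"unknown augmentation mode {mode!r}")
    ids = (e_j.mention_id, e_k.mention_id)

    if mode == "vanilla":
        v = concat([_span_sum(h_re, e_j), _span_sum(h_re, e_k)])
    elif mode == "type_embedding":
        if not isinstance(aux, TypeEmbeddingTable):
            raise ValueError("type_embedding mode needs a TypeEmbeddingTable aux")
        if type_labels is None:
            raise ValueError("type_embedding mode needs type_labels")
        v = concat([_span_sum(h_re, e_j), aux.lookup(type_labels[0]),
                    _span_sum(h_re, e_k), aux.lookup(type_labels[1])])
    elif mode == "prototype":
        if not isinstance(aux, PrototypeTable):
            raise ValueError("prototype mode needs a PrototypeTable aux")
        if type_labels is None:
            raise ValueError("prototype mode needs type_labels")
        v = concat([_span_sum(h_re, e_j), Tensor(aux.lookup(type_labels[0])),
                    _span_sum(h_re, e_k), Tensor(aux.lookup(type_labels[1]))])
    else:  # entity_marker
        if not isinstance(aux, dict):
            raise ValueError("entity_marker mode needs the start-marker position map")
        for mid in ids:
            if mid not in aux:
                raise ValueError(f"no start marker recorded for mention {mid!r}")
        n = h_re.shape[0]
        for mid in ids:
            if aux[mid] >= n:
                raise ValueError(f"marker position {aux[mid]} outside hidden states")
        v = concat([h_re[aux[ids[0]]], h_re[aux[ids[1]]]])
    return PairRepresentation(vector=v, mode=mode, mention_ids=ids)
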