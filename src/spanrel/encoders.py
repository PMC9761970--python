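"""Token encoders for the NER and RE branches, with three sharing modes.

The default encoder is a small word-level transformer (learned token
embeddings + fixed sinusoidal positions + pre-norm self-attention blocks,
d = 64 by default) that trains on one CPU in minutes.  Entity-marker tokens
such as ``[Drug_start]`` live outside the word-embedding table in their own
appendable parameter slots, so registering markers for entity types learned
in later steps never reallocates (or perturbs) existing rows.

Sharing modes couple the two branches at three strengths:

* ``hard`` — one encoder serves both branches (one parameter set);
* ``none`` — two disjoint encoders, no interaction (the default);
* ``soft`` — two encoders, but every RE layer's output is fused with the
  NER encoder's final-layer states through cross-attention:
  ``fused = softmax(H_re · H_nerᵀ / √d) · H_ner ⊙ H_re``
  (the trailing product is elementwise; a matrix product of two n×d
  factors would be dimensionally inconsistent).  The fused states replace
  the RE layer's own output stream.
"""

from __future__ import annotations

import math
import re

import numpy as np

from .autograd import Tensor, no_grad
from .layers import Embedding, LayerNorm, Module, SelfAttentionLayer, sinusoidal_positions

__all__ = [
    "TokenVocabulary", "TinyTransformerEncoder", "EncoderBundle",
    "cross_attention_fuse", "encode_tokens", "UNK_TOKEN",
]

UNK_TOKEN = "[UNK]"
_MARKER_RE = re.compile(r"^\[[^\[\]]+_(start|end)\]$")


class TokenVocabulary:
    """Token → id map with an unknown-token fallback."""

    def __init__(self, tokens):
        self._index: dict[str, int] = {UNK_TOKEN: 0}
        for tok in tokens:
            if tok not in self._index:
                self._index[tok] = len(self._index)

    @classmethod
    def from_corpora(cls, corpora) -> "TokenVocabulary":
        def stream():
            for corpus in corpora:
                for sent in corpus.sentences:
                    yield from sent.tokens
        return cls(stream())

    def __len__(self):
        return len(self._index)

    def __contains__(self, tok):
        return tok in self._index

    def ids(self, tokens) -> np.ndarray:
        return np.array([self._index.get(t, 0) for t in tokens], dtype=np.intp)


class TinyTransformerEncoder(Module):
    def __init__(self, vocab: TokenVocabulary, d: int = 64, n_layers: int = 2,
                 n_heads: int = 4, ffn_dim: int = 128, seed: int = 0):
        super().__init__()
        self.vocab = vocab
        self.d = d
        self.n_layers = n_layers
        rng = np.random.default_rng(seed)
        self.token_emb = Embedding(len(vocab), d, rng)
        for i in range(n_layers):
            self.register(f"layer{i}", SelfAttentionLayer(d, n_heads, ffn_dim, rng))
        self.final_ln = LayerNorm(d)
        self._markers: dict[str, Tensor] = {}
        self._marker_rng = np.random.default_rng(seed + 1)

    # -- marker registry ----------------------------------------------------

    @property
    def marker_tokens(self) -> tuple[str, ...]:
        return tuple(self._markers)

    def register_marker(self, marker: str) -> None:
        """Add an indivisible marker token with a fresh trainable embedding."""
        if not _MARKER_RE.match(marker):
            raise ValueError(f"{marker!r} is not a marker-shaped token")
        if marker in self._markers:
            return
        vec = Tensor(self._marker_rng.normal(0.0, 0.1, size=(self.d,)),
                     requires_grad=True)
        self._markers[marker] = vec
        self._params[f"marker:{marker}"] = vec

    def register_markers_for_types(self, entity_types) -> None:
        for t in entity_types:
            self.register_marker(f"[{t}_start]")
            self.register_marker(f"[{t}_end]")

    # -- encoding -----------------------------------------------------------

    def _embed(self, tokens: list[str]) -> Tensor:
        n = len(tokens)
        ids = np.zeros(n, dtype=np.intp)
        keep = np.ones((n, 1))
        marker_positions: list[tuple[int, Tensor]] = []
        for i, tok in enumerate(tokens):
            if _MARKER_RE.match(tok):
                if tok not in self._markers:
                    raise KeyError(f"marker token {tok!r} is not registered")
                keep[i, 0] = 0.0
                marker_positions.append((i, self._markers[tok]))
            else:
                ids[i] = self.vocab.ids([tok])[0]
        x = self.token_emb(ids) * keep
        for i, vec in marker_positions:
            onehot = np.zeros((n, 1))
            onehot[i, 0] = 1.0
            x = x + vec * onehot
        return x

    def layers(self):
        return [self._modules[f"layer{i}"] for i in range(self.n_layers)]

    def __call__(self, tokens: list[str]) -> Tensor:
        if not tokens:
            raise ValueError("cannot encode an empty token list")
        x = self._embed(tokens) + sinusoidal_positions(len(tokens), self.d)
        for layer in self.layers():
            x = layer(x)
        return self.final_ln(x)

    def forward_layerwise(self, tokens: list[str], fuse_with: Tensor) -> Tensor:
        """Soft-sharing forward: each layer's output is replaced by its
        cross-attention fusion with ``fuse_with`` (the NER final states)."""
        x = self._embed(tokens) + sinusoidal_positions(len(tokens), self.d)
        for layer in self.layers():
            x = cross_attention_fuse(layer(x), fuse_with)
        return self.final_ln(x)


def cross_attention_fuse(h_re_l, h_ner_final) -> Tensor:
    """Fuse an RE layer's states with the NER final-layer states.

    ``softmax(H_re · H_nerᵀ / √d)`` row-normalizes attention from each RE
    token over all NER tokens; the attended NER summary is then combined
    with the RE states by an elementwise product.  Both inputs are n×d over
    the same token sequence.
    """
    h_re_l = h_re_l if isinstance(h_re_l, Tensor) else Tensor(h_re_l)
    h_ner_final = h_ner_final if isinstance(h_ner_final, Tensor) else Tensor(h_ner_final)
    if h_re_l.shape != h_ner_final.shape or h_re_l.ndim != 2:
        raise ValueError(
            f"shape mismatch: {h_re_l.shape} vs {h_ner_final.shape} (need equal n x d)")
    d = h_re_l.shape[1]
    scores = (h_re_l @ h_ner_final.transpose()) * (1.0 / math.sqrt(d))
    attn = scores.softmax(axis=-1)
    return (attn @ h_ner_final) * h_re_l


class EncoderBundle(Module):
    """The NER/RE encoder pair under a given sharing mode."""

    SHARING_MODES = ("hard", "soft", "none")

    def __init__(self, vocab: TokenVocabulary, sharing_mode: str = "none",
                 d: int = 64, n_layers: int = 2, n_heads: int = 4,
                 ffn_dim: int = 128, seed: int = 0, encoder_kind: str = "tiny"):
        super().__init__()
        if sharing_mode not in self.SHARING_MODES:
            raise ValueError(f"unknown sharing mode {sharing_mode!r}")
        if encoder_kind != "tiny":
            raise ValueError(f"unsupported encoder kind {encoder_kind!r}")
        self.sharing_mode = sharing_mode
        self.encoder_kind = encoder_kind
        self.d = d
        self.ner_encoder = TinyTransformerEncoder(vocab, d, n_layers, n_heads,
                                                  ffn_dim, seed=seed)
        if sharing_mode == "hard":
            # one parameter set; bypass module registration so parameters
            # are not enumerated (and hence updated) twice
            object.__setattr__(self, "re_encoder", self.ner_encoder)
        else:
            self.re_encoder = TinyTransformerEncoder(vocab, d, n_layers, n_heads,
                                                     ffn_dim, seed=seed + 1)

    def register_markers_for_types(self, entity_types) -> None:
        self.ner_encoder.register_markers_for_types(entity_types)
        if self.re_encoder is not self.ner_encoder:
            self.re_encoder.register_markers_for_types(entity_types)

    def encode(self, branch: str, tokens: list[str]) -> Tensor:
        if branch == "NER":
            return self.ner_encoder(tokens)
        if branch != "RE":
            raise ValueError(f"unknown branch {branch!r}")
        if self.sharing_mode == "soft":
            h_ner_final = self.ner_encoder(tokens)
            return self.re_encoder.forward_layerwise(tokens, h_ner_final)
        return self.re_encoder(tokens)


def encode_tokens(bundle: EncoderBundle, branch: str, tokens: list[str],
                  train: bool = True) -> Tensor:
    """Encode one token sequence on the requested branch (one d-vector per
    token).  ``train=False`` runs without building the autodiff graph."""
    if train:
        return bundle.encode(branch, tokens)
    with no_grad():
        return bundle.encode(branch, tokens)
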