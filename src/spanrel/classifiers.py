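"""Classification heads: the BIOES tagger, entity-typing and relation heads
in both single-head (multi-class) and expandable multi-head (one binary
classifier per label) forms, plus the weighted joint loss.

The multi-head form is what makes the label vocabulary continually
expandable: appending a freshly initialized binary head for a new label
never touches existing heads, and prediction takes the most confident head
above a decision threshold θ (ties broken toward the lowest vocabulary
index), or abstains when no head fires.  For relation pairs, abstention is
the explicit NO_RELATION outcome; the single-head relation classifier
carries NO_RELATION as a dedicated class at index 0 so appended relation
classes keep stable indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, no_grad
from .corpus import BIOES_TAGS
from .layers import FeedForward, Module

__all__ = [
    "LossWeights", "SPHead", "SingleHead", "MultiHeadBank", "NO_RELATION",
    "predict_sp", "predict_et", "predict_re", "aggregate_multihead",
    "joint_loss", "cross_entropy_loss", "binary_cross_entropy",
    "multihead_bce_sum", "softplus", "add_head",
]

NO_RELATION = "NO_RELATION"


@dataclass(frozen=True)
class LossWeights:
    sp: float = 0.4
    et: float = 0.25
    re: float = 0.35

    def __post_init__(self):
        if min(self.sp, self.et, self.re) < 0:
            raise ValueError("loss weights must be nonnegative")


class SPHead(Module):
    """Two-layer feed-forward tagger over the five BIOES classes."""

    def __init__(self, d: int, hidden_dim: int, seed: int = 0):
        super().__init__()
        self.net = FeedForward(d, hidden_dim, len(BIOES_TAGS),
                               np.random.default_rng(seed))

    def __call__(self, h: Tensor) -> Tensor:
        return self.net(h)


class SingleHead(Module):
    """Multi-class head over an ordered label list (optionally with an
    extra abstain class at index 0, used by the relation head)."""

    def __init__(self, in_dim: int, hidden_dim: int, labels, seed: int = 0,
                 with_null_class: bool = False):
        super().__init__()
        self.labels = list(labels)
        self.with_null_class = with_null_class
        self.in_dim, self.hidden_dim = in_dim, hidden_dim
        self._seed = seed
        out = len(self.labels) + (1 if with_null_class else 0)
        self.net = FeedForward(in_dim, hidden_dim, out, np.random.default_rng(seed))

    def class_index(self, label: str) -> int:
        base = 1 if self.with_null_class else 0
        if label == NO_RELATION and self.with_null_class:
            return 0
        return base + self.labels.index(label)

    def __call__(self, x: Tensor) -> Tensor:
        return self.net(x)

    def expand(self, new_labels) -> None:
        """Widen the output layer for new labels, copying trained rows.

        A multi-class head cannot grow in place without reallocating its
        output projection; existing class columns are copied verbatim, new
        ones freshly initialized (this reallocation is the structural
        weakness the multi-head form avoids).
        """
        fresh = [lab for lab in new_labels if lab not in self.labels]
        if not fresh:
            return
        self.labels.extend(fresh)
        old = self.net
        out = len(self.labels) + (1 if self.with_null_class else 0)
        new_net = FeedForward(self.in_dim, self.hidden_dim, out,
                              np.random.default_rng(self._seed + len(self.labels)))
        new_net.fc1.weight.data = old.fc1.weight.data.copy()
        new_net.fc1.bias.data = old.fc1.bias.data.copy()
        k = old.fc2.weight.data.shape[1]
        new_net.fc2.weight.data[:, :k] = old.fc2.weight.data
        new_net.fc2.bias.data[:k] = old.fc2.bias.data
        self.net = new_net


class MultiHeadBank(Module):
    """Ordered bank of per-label binary heads with decision threshold θ.

    Head order mirrors the label vocabulary order; appending heads never
    mutates existing ones.
    """

    def __init__(self, in_dim: int, hidden_dim: int, labels=(), theta: float = 0.5,
                 task: str = "ET", seed: int = 0):
        super().__init__()
        if task not in ("ET", "RE"):
            raise ValueError("task must be 'ET' or 'RE'")
        self.in_dim, self.hidden_dim = in_dim, hidden_dim
        self.theta = theta
        self.task = task
        self.labels: list[str] = []
        self._seed = seed
        for lab in labels:
            self.add_head(lab)

    def add_head(self, label: str) -> None:
        if label in self.labels:
            raise ValueError(f"label {label!r} already has a head")
        idx = len(self.labels)
        self.labels.append(label)
        head = FeedForward(self.in_dim, self.hidden_dim, 1,
                           np.random.default_rng(self._seed + 1000 * idx + 17))
        self.register(f"head{idx}", head)

    def head(self, label: str) -> FeedForward:
        return self._modules[f"head{self.labels.index(label)}"]

    def logit(self, label: str, x: Tensor) -> Tensor:
        """Scalar logit of one binary head (training path)."""
        return self.head(label)(x).reshape(())

    def probabilities(self, x: Tensor) -> dict[str, float]:
        """Sigmoid probability of every head on one input (inference path)."""
        with no_grad():
            return {lab: float(self.head(lab)(x).sigmoid().data.reshape(-1)[0])
                    for lab in self.labels}


def add_head(bank: MultiHeadBank, new_label: str) -> MultiHeadBank:
    """Append a freshly initialized binary head for ``new_label``."""
    bank.add_head(new_label)
    return bank


def aggregate_multihead(scores: dict[str, float], theta: float,
                        label_order: list[str] | None = None) -> str | None:
    """Most-confident-head rule: labels scoring strictly above θ are
    candidates; the best score wins, ties going to the lowest vocabulary
    index; no candidate → None."""
    order = label_order if label_order is not None else list(scores)
    best_label, best_score = None, None
    for lab in order:
        s = scores[lab]
        if s > theta and (best_score is None or s > best_score):
            best_label, best_score = lab, s
    return best_label


# ---------------------------------------------------------------------------
# prediction wrappers
# ---------------------------------------------------------------------------

def predict_sp(h_ner: Tensor, sp_head: SPHead) -> np.ndarray:
    """Per-token distributions over the five BIOES tags, shape (n, 5)."""
    with no_grad():
        return sp_head(h_ner).softmax(axis=-1).data


def sp_tags_from_distributions(dist: np.ndarray) -> tuple[str, ...]:
    return tuple(BIOES_TAGS[i] for i in dist.argmax(axis=-1))


def predict_et(h_ner: Tensor, span: tuple[int, int], bank_or_head) -> tuple[str | None, float]:
    """Type prediction for one span from the span-summed NER states."""
    lo, hi = span
    n = h_ner.shape[0]
    if not (0 <= lo <= hi < n):
        raise ValueError(f"invalid span {span} for {n} tokens")
    with no_grad():
        x = h_ner[lo:hi + 1].sum(axis=0)
        return _classify(x, bank_or_head)


def predict_re(pair_vector: Tensor, bank_or_head) -> tuple[str, float]:
    """Relation prediction for one pair vector; abstention → NO_RELATION."""
    with no_grad():
        label, conf = _classify(pair_vector, bank_or_head)
    return (label if label is not None else NO_RELATION), conf


def _classify(x: Tensor, bank_or_head) -> tuple[str | None, float]:
    if isinstance(bank_or_head, MultiHeadBank):
        probs = bank_or_head.probabilities(x)
        label = aggregate_multihead(probs, bank_or_head.theta, bank_or_head.labels)
        return label, (probs[label] if label is not None else
                       max(probs.values()) if probs else 0.0)
    head: SingleHead = bank_or_head
    if x.data.shape[-1] != head.net.fc1.weight.shape[0]:
        raise ValueError(
            f"input dim {x.data.shape[-1]} does not match head input "
            f"{head.net.fc1.weight.shape[0]}")
    probs = head(x).softmax(axis=-1).data
    idx = int(probs.argmax())
    if head.with_null_class:
        label = NO_RELATION if idx == 0 else head.labels[idx - 1]
    else:
        label = head.labels[idx]
    return label, float(probs[idx])


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softplus(t: Tensor) -> Tensor:
    """log(1 + exp(t)), computed overflow-safely on the tape."""
    t = t if isinstance(t, Tensor) else Tensor(t)
    absval = t.relu() + (-t).relu()
    return t.relu() + (1.0 + (-absval).exp()).log()


def cross_entropy_loss(logits: Tensor, target_idx) -> Tensor:
    """Mean negative log-softmax at the target indices.

    ``logits`` is (n, C) with ``target_idx`` length n, or (C,) with a
    scalar target.
    """
    logp = logits.log_softmax(axis=-1)
    if logits.ndim == 1:
        return -logp[int(target_idx)]
    idx = np.asarray(target_idx, dtype=np.intp)
    rows = np.arange(logits.shape[0])
    return -(logp[rows, idx].mean())


def binary_cross_entropy(logit: Tensor, target: float) -> Tensor:
    """BCE from a raw logit: softplus(z) − y·z."""
    return softplus(logit) - logit * float(target)


def multihead_bce_sum(bank: MultiHeadBank, x: Tensor,
                      gold_label: str | None) -> Tensor:
    """Sum of one-vs-rest BCE terms over every head in the bank.

    ``gold_label is None`` trains all heads negative (the no-relation /
    no-type case)."""
    total = None
    for lab in bank.labels:
        term = binary_cross_entropy(bank.logit(lab, x),
                                    1.0 if lab == gold_label else 0.0)
        total = term if total is None else total + term
    if total is None:
        raise ValueError("bank has no heads")
    return total


def joint_loss(sp_loss, et_loss, re_loss, weights: LossWeights):
    """Weighted sum α_SP·L_SP + α_ET·L_ET + α_RE·L_RE.

    Components may be tape Tensors (training) or plain floats; for the
    multi-head form the ET/RE components are already the per-head BCE sums.
    """
    return sp_loss * weights.sp + et_loss * weights.et + re_loss * weights.re
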