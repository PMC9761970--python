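"""Propagation-aware micro-F1 scoring for the extraction pipeline.

Counting rules:

* **SP** — token-level micro-F1 over the four positive BIOES tags
  (B/I/E/S); O is not a positive class, since counting it would collapse
  micro-F1 into token accuracy and mask boundary errors.
* **ET** — a predicted mention is a true positive only if BOTH its span and
  its type exactly match a gold mention; an unmatched prediction is one
  false positive, an unmatched gold mention one false negative (a
  wrong-type prediction on a correct span therefore costs FP *and* FN).
  Matching is one-to-one by exact (span, type) key.
* **RE** — a predicted triple counts only if both entities (span and type)
  and the relation label all match a gold triple; pairs are unordered.
* **combined** — counts are pooled across corpora before the single
  precision/recall ratio (micro pooling, never averaging of per-corpus F1).

ET⁺ / RE⁺ replace upstream stages with gold annotations before scoring,
isolating each stage's own errors from propagated ones; corpus-adaptation
evaluation runs the full pipeline on a corpus from a different annotation
effort than any training data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .corpus import Corpus, EntityMention, TagSequence, bioes_decode

__all__ = [
    "ConfusionCounts", "EvalReport", "evaluate_sp", "evaluate_et", "evaluate_re",
    "evaluate_combined", "evaluate_united_ner", "evaluate_pipeline",
    "corpus_adaptation_eval", "gold_triples", "mention_key", "triple_key",
    "united_tags",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall, "f1": self.f1}


@dataclass
class EvalReport:
    metrics: dict[str, dict]
    counts: dict[str, ConfusionCounts]

    def f1(self, task: str) -> float:
        return self.metrics[task]["f1"]


# ---------------------------------------------------------------------------
# matchers
# ---------------------------------------------------------------------------

def _match_multisets(pred_keys, gold_keys) -> ConfusionCounts:
    cp, cg = Counter(pred_keys), Counter(gold_keys)
    tp = sum((cp & cg).values())
    return ConfusionCounts(tp=tp, fp=sum(cp.values()) - tp,
                           fn=sum(cg.values()) - tp)


def evaluate_sp(pred: list, gold: list) -> ConfusionCounts:
    """Token-level micro counts over the positive (non-O) BIOES tags."""
    if len(pred) != len(gold):
        raise ValueError("prediction/gold sentence lists differ in length")
    counts = ConfusionCounts()
    for p_seq, g_seq in zip(pred, gold):
        p_tags, g_tags = tuple(p_seq), tuple(g_seq)
        if len(p_tags) != len(g_tags):
            raise ValueError(
                f"tag sequences of unequal length: {len(p_tags)} vs {len(g_tags)}")
        for p, g in zip(p_tags, g_tags):
            if p == g and p != "O":
                counts.tp += 1
            else:
                if p != "O":
                    counts.fp += 1
                if g != "O":
                    counts.fn += 1
    return counts


def mention_key(m: EntityMention) -> tuple:
    return (m.start, m.end, m.type_label)


def evaluate_et(pred_mentions: list, gold_mentions: list) -> ConfusionCounts:
    """Exact (span, type) one-to-one matching, per sentence then pooled."""
    if len(pred_mentions) != len(gold_mentions):
        raise ValueError("prediction/gold sentence lists differ in length")
    counts = ConfusionCounts()
    for pm, gm in zip(pred_mentions, gold_mentions):
        counts = counts + _match_multisets([mention_key(m) for m in pm],
                                           [mention_key(m) for m in gm])
    return counts


def triple_key(mention_a: EntityMention, mention_b: EntityMention, label: str) -> tuple:
    ends = tuple(sorted([mention_key(mention_a), mention_key(mention_b)]))
    return (ends, label)


def evaluate_re(pred_triples: list, gold_triples_: list) -> ConfusionCounts:
    """Exact (entity, entity, label) matching with unordered pairs."""
    if len(pred_triples) != len(gold_triples_):
        raise ValueError("prediction/gold sentence lists differ in length")
    counts = ConfusionCounts()
    for pt, gt in zip(pred_triples, gold_triples_):
        counts = counts + _match_multisets(
            [triple_key(a, b, lab) for (a, b, lab) in pt],
            [triple_key(a, b, lab) for (a, b, lab) in gt])
    return counts


def evaluate_combined(per_corpus_counts: list[ConfusionCounts]) -> ConfusionCounts:
    """Pool counts across corpora, then compute P/R/F1 once."""
    total = ConfusionCounts()
    for c in per_corpus_counts:
        total = total + c
    return total


# ---------------------------------------------------------------------------
# united-tag NER scoring (position + type in one label)
# ---------------------------------------------------------------------------

def united_tags(n_tokens: int, mentions: list[EntityMention]) -> tuple[str, ...]:
    """Render mentions as united tags, e.g. ``B_Drug I_Drug E_Drug`` / ``S_Drug``."""
    from .corpus import Sentence, bioes_encode
    sp = bioes_encode(Sentence(("x",) * n_tokens), mentions)
    out = []
    type_at = {}
    for m in mentions:
        for i in range(m.start, m.end + 1):
            type_at[i] = m.type_label
    for i, t in enumerate(sp):
        out.append("O" if t == "O" else f"{t}_{type_at[i]}")
    return tuple(out)


def _decode_united(tags) -> list[tuple]:
    """Recover (span, type) keys from united tags (conservative decoding,
    type-consistent segments only)."""
    sp, types = [], []
    for t in tags:
        if t == "O":
            sp.append("O")
            types.append(None)
        else:
            pos, _, typ = t.partition("_")
            sp.append(pos)
            types.append(typ)
    keys = []
    for (lo, hi) in bioes_decode(TagSequence(tuple(sp))):
        seg_types = {types[i] for i in range(lo, hi + 1)}
        if len(seg_types) == 1:
            keys.append((lo, hi, seg_types.pop()))
    return keys


def evaluate_united_ner(pred_united: list, gold_united: list) -> ConfusionCounts:
    """Score NER from united position+type labels: exact (span, type) match."""
    if len(pred_united) != len(gold_united):
        raise ValueError("prediction/gold sentence lists differ in length")
    counts = ConfusionCounts()
    for pt, gt in zip(pred_united, gold_united):
        counts = counts + _match_multisets(_decode_united(pt), _decode_united(gt))
    return counts


# ---------------------------------------------------------------------------
# pipeline-level evaluation
# ---------------------------------------------------------------------------

def gold_triples(corpus: Corpus, sent_idx: int) -> list[tuple]:
    out = []
    for r in corpus.relations[sent_idx]:
        a = corpus.mention_by_id(sent_idx, r.mention_a)
        b = corpus.mention_by_id(sent_idx, r.mention_b)
        out.append((a, b, r.label))
    return out


def evaluate_pipeline(model, corpus: Corpus, conditional: bool = True) -> EvalReport:
    """Run the full pipeline over ``corpus`` and score every task.

    Always reports SP, ET and RE; with ``conditional=True`` also ET⁺
    (typing on gold spans) and RE⁺ (relations on gold spans and types),
    plus united-tag NER.
    """
    from .corpus import bioes_encode
    from .training import infer_conditional, infer_sentence, predict_tag_sequence

    pred_tags, gold_tags = [], []
    pred_mentions, gold_mentions = [], []
    pred_rel, gold_rel = [], []
    pred_ment_plus, pred_rel_plus = [], []
    pred_united, gold_united = [], []

    for si, (sent, ments, _rels) in enumerate(corpus.annotated()):
        pred_tags.append(predict_tag_sequence(model, sent))
        gold_tags.append(bioes_encode(sent, ments))
        p_ments, p_triples = infer_sentence(model, sent)
        pred_mentions.append(p_ments)
        gold_mentions.append(ments)
        pred_rel.append(p_triples)
        gold_rel.append(gold_triples(corpus, si))
        pred_united.append(united_tags(sent.n, p_ments))
        gold_united.append(united_tags(sent.n, ments))
        if conditional:
            pred_ment_plus.append(infer_conditional(model, sent, ments, "gold_sp"))
            pred_rel_plus.append(infer_conditional(model, sent, ments, "gold_sp_et"))

    counts = {
        "SP": evaluate_sp(pred_tags, gold_tags),
        "ET": evaluate_et(pred_mentions, gold_mentions),
        "RE": evaluate_re(pred_rel, gold_rel),
        "NER": evaluate_united_ner(pred_united, gold_united),
    }
    if conditional:
        counts["ET+"] = evaluate_et(pred_ment_plus, gold_mentions)
        counts["RE+"] = evaluate_re(pred_rel_plus, gold_rel)
    return EvalReport(metrics={k: v.as_dict() for k, v in counts.items()},
                      counts=counts)


def corpus_adaptation_eval(model, foreign_corpus: Corpus) -> EvalReport:
    """Full-pipeline scoring on a corpus from a different annotation effort.

    The foreign corpus must be non-empty and its labels must already be in
    the model's vocabulary (the model is never trained on it)."""
    if len(foreign_corpus) == 0:
        raise ValueError("foreign corpus is empty")
    unknown_e = set(foreign_corpus.entity_type_labels()) - set(model.vocab.entity_types)
    unknown_r = set(foreign_corpus.relation_labels()) - set(model.vocab.relation_types)
    if unknown_e or unknown_r:
        raise ValueError(
            f"foreign corpus carries labels outside the model vocabulary: "
            f"entity types {sorted(unknown_e)}, relations {sorted(unknown_r)}")
    return evaluate_pipeline(model, foreign_corpus)
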