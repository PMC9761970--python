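"""Joint training over a schedule and the SP → ET → marker → RE pipeline.

Span detection, entity typing and relation extraction are trained
simultaneously on the same sentences through one weighted joint loss.  At
inference the stages run as a pipeline: BIOES tags are predicted and
decoded to spans, each span is typed, candidate mention pairs are built
(markers inserted from the *predicted* spans and types when the
entity-marker mode is configured), and the relation classifier scores each
pair, keeping only non-NO_RELATION predictions.

Schedules realize continual learning: step *t* starts from the parameters
selected at step *t−1*; labels first seen at a step trigger vocabulary
expansion, fresh classifier heads and fresh marker embeddings before
training begins, so earlier heads are never reallocated.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .augmentation import (PrototypeTable, TypeEmbeddingTable, compute_prototypes,
                           insert_entity_markers, pair_representation)
from .classifiers import (LossWeights, MultiHeadBank, NO_RELATION, SingleHead, SPHead,
                          cross_entropy_loss, joint_loss, multihead_bce_sum,
                          predict_et, predict_re, predict_sp,
                          sp_tags_from_distributions)
from .corpus import (BIOES_TAGS, Corpus, EntityMention, LabelVocabulary, Sentence,
                     TagSequence, bioes_decode, bioes_encode, expand_vocabulary)
from .encoders import EncoderBundle, TokenVocabulary, encode_tokens
from .layers import AdamW, Module
from .synthetic import TrainingSchedule

__all__ = [
    "TrainConfig", "JointModel", "StepCheckpoint", "train_step", "run_schedule",
    "infer_sentence", "infer_conditional", "predict_tag_sequence",
]


@dataclass
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 5e-4
    epochs: int = 30
    repetitions: int = 5
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    early_stopping_patience: int = 5   # epochs without validation-RE-F1 gain

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.repetitions) < 1:
            raise ValueError("batch_size, epochs and repetitions must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class JointModel(Module):
    """Encoder bundle + SP head + ET/RE classifiers + label vocabulary."""

    def __init__(self, token_vocab: TokenVocabulary, label_vocab: LabelVocabulary,
                 *, sharing_mode: str = "none", augmentation_mode: str = "entity_marker",
                 classifier_mode: str = "multi", d: int = 64, n_layers: int = 2,
                 n_heads: int = 4, ffn_dim: int = 128, head_hidden: int = 64,
                 theta: float = 0.5, aux_dim: int = 50, seed: int = 0):
        super().__init__()
        if classifier_mode not in ("single", "multi"):
            raise ValueError(f"unknown classifier mode {classifier_mode!r}")
        if augmentation_mode == "entity_marker" and sharing_mode == "hard":
            raise ValueError(
                "entity_marker augmentation cannot be combined with hard sharing: "
                "the NER branch must see the raw sentence while the RE branch "
                "sees the marked one, which a single shared input stream cannot do")
        self.augmentation_mode = augmentation_mode
        self.classifier_mode = classifier_mode
        self.vocab = label_vocab
        self.theta = theta
        self.d = d
        self.bundle = EncoderBundle(token_vocab, sharing_mode, d, n_layers,
                                    n_heads, ffn_dim, seed=seed)
        self.bundle.register_markers_for_types(label_vocab.entity_types)
        self.sp_head = SPHead(d, head_hidden, seed=seed + 2)
        pair_dim = 2 * d + (2 * aux_dim
                            if augmentation_mode in ("type_embedding", "prototype") else 0)
        if classifier_mode == "multi":
            self.et = MultiHeadBank(d, head_hidden, label_vocab.entity_types,
                                    theta, "ET", seed=seed + 3)
            self.re = MultiHeadBank(pair_dim, head_hidden, label_vocab.relation_types,
                                    theta, "RE", seed=seed + 4)
        else:
            self.et = SingleHead(d, head_hidden, label_vocab.entity_types, seed=seed + 3)
            self.re = SingleHead(pair_dim, head_hidden, label_vocab.relation_types,
                                 seed=seed + 4, with_null_class=True)
        self.type_emb = (TypeEmbeddingTable(label_vocab.entity_types, aux_dim,
                                            seed=seed + 5)
                         if augmentation_mode == "type_embedding" else None)
        if self.type_emb is not None:
            self.register("type_emb_table", self.type_emb)
        self.prototypes: PrototypeTable | None = None

    @property
    def sharing_mode(self) -> str:
        return self.bundle.sharing_mode

    def freeze_prototypes(self, train_corpus: Corpus) -> None:
        """Compute the frozen entity-type prototypes from the (still
        untrained) RE encoder; must run before any training step."""
        self.prototypes = compute_prototypes(
            train_corpus, self.bundle.re_encoder,
            entity_types=self.vocab.entity_types)

    def expand_labels(self, new_entity_types=(), new_relation_types=()) -> None:
        """Grow vocabulary, heads, markers and type embeddings for labels
        first seen at a new schedule step; existing parameters untouched."""
        fresh_e = [t for t in new_entity_types if t not in self.vocab.entity_types]
        fresh_r = [r for r in new_relation_types if r not in self.vocab.relation_types]
        expand_vocabulary(self.vocab, fresh_e, fresh_r)
        self.bundle.register_markers_for_types(fresh_e)
        if self.classifier_mode == "multi":
            for t in fresh_e:
                self.et.add_head(t)
            for r in fresh_r:
                self.re.add_head(r)
        else:
            self.et.expand(fresh_e)
            self.re.expand(fresh_r)
        if self.type_emb is not None:
            for t in fresh_e:
                self.type_emb.add_type(t)

    # -- shared forward pieces ----------------------------------------------

    def _re_states_and_coords(self, sentence: Sentence,
                              mentions: list[EntityMention], train: bool):
        """RE-branch hidden states plus the aux object for pair building."""
        if self.augmentation_mode == "entity_marker":
            marked = insert_entity_markers(sentence, mentions)
            h_re = encode_tokens(self.bundle, "RE", list(marked.tokens), train=train)
            return h_re, marked.start_marker_pos, None
        h_re = encode_tokens(self.bundle, "RE", list(sentence.tokens), train=train)
        if self.augmentation_mode == "type_embedding":
            return h_re, self.type_emb, None
        if self.augmentation_mode == "prototype":
            if self.prototypes is None:
                raise RuntimeError("prototype mode requires freeze_prototypes() "
                                   "before training/inference")
            return h_re, self.prototypes, None
        return h_re, None, None


@dataclass
class StepCheckpoint:
    step_name: str
    state: dict[str, np.ndarray]
    entity_types: tuple[str, ...]
    relation_types: tuple[str, ...]
    best_epoch: int
    val_metrics: dict


def _gold_relation_map(relations) -> dict[frozenset, str]:
    return {frozenset((r.mention_a, r.mention_b)): r.label for r in relations}


def _sentence_loss(model: JointModel, sentence: Sentence,
                   mentions: list[EntityMention], relations,
                   weights: LossWeights):
    h_ner = model.bundle.encode("NER", list(sentence.tokens))

    # SP: token-level cross-entropy against gold BIOES tags
    gold_tags = bioes_encode(sentence, mentions)
    target = np.array([BIOES_TAGS.index(t) for t in gold_tags], dtype=np.intp)
    sp_loss = cross_entropy_loss(model.sp_head(h_ner), target)

    # ET: supervised on gold mention spans only
    et_loss = 0.0
    if mentions:
        terms = []
        for m in mentions:
            x = h_ner[m.start:m.end + 1].sum(axis=0)
            if model.classifier_mode == "multi":
                terms.append(multihead_bce_sum(model.et, x, m.type_label))
            else:
                terms.append(cross_entropy_loss(
                    model.et(x), model.et.class_index(m.type_label)))
        et_loss = _mean(terms)

    # RE: every unordered gold-mention pair is a candidate
    re_loss = 0.0
    if len(mentions) >= 2:
        h_re, aux, _ = model._re_states_and_coords(sentence, mentions, train=True)
        gold_map = _gold_relation_map(relations)
        terms = []
        for a in range(len(mentions)):
            for b in range(a + 1, len(mentions)):
                mj, mk = mentions[a], mentions[b]
                gold = gold_map.get(frozenset((mj.mention_id, mk.mention_id)))
                v = pair_representation(model.augmentation_mode, h_re, mj, mk,
                                        aux=aux,
                                        type_labels=(mj.type_label, mk.type_label))
                if model.classifier_mode == "multi":
                    terms.append(multihead_bce_sum(model.re, v.vector, gold))
                else:
                    terms.append(cross_entropy_loss(
                        model.re(v.vector),
                        model.re.class_index(gold if gold is not None else NO_RELATION)))
        re_loss = _mean(terms)

    return joint_loss(sp_loss, et_loss, re_loss, weights)


def _mean(terms):
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def train_step(model: JointModel, batch, optimizer: AdamW,
               weights: LossWeights | None = None) -> float:
    """One optimizer update on the joint loss of a batch of annotated
    sentences (an iterable of (sentence, mentions, relations) triples)."""
    weights = weights or LossWeights()
    batch = list(batch)
    if not batch:
        raise ValueError("empty batch")
    total = None
    for sent, mentions, relations in batch:
        loss = _sentence_loss(model, sent, mentions, relations, weights)
        total = loss if total is None else total + loss
    total = total * (1.0 / len(batch))
    value = float(total.data)
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite joint loss on batch starting with sentence "
            f"{batch[0][0].sentence_id!r}")
    model.zero_grad()
    total.backward()
    optimizer.step(model.parameters())
    return value


# ---------------------------------------------------------------------------
# inference pipeline
# ---------------------------------------------------------------------------

def predict_tag_sequence(model: JointModel, sentence: Sentence) -> TagSequence:
    h_ner = encode_tokens(model.bundle, "NER", list(sentence.tokens), train=False)
    dist = predict_sp(h_ner, model.sp_head)
    return TagSequence(sp_tags_from_distributions(dist))


def _predict_relations(model: JointModel, sentence: Sentence,
                       mentions: list[EntityMention]):
    """Score all unordered pairs of the given (typed) mentions."""
    if len(mentions) < 2:
        return []
    h_re, aux, _ = model._re_states_and_coords(sentence, mentions, train=False)
    triples = []
    for a in range(len(mentions)):
        for b in range(a + 1, len(mentions)):
            mj, mk = mentions[a], mentions[b]
            v = pair_representation(model.augmentation_mode, h_re, mj, mk,
                                    aux=aux, type_labels=(mj.type_label, mk.type_label))
            label, _conf = predict_re(v.vector, model.re)
            if label != NO_RELATION:
                triples.append((mj, mk, label))
    return triples


def infer_sentence(model: JointModel, sentence: Sentence):
    """Full pipeline on a raw sentence → (predicted mentions, predicted
    relation triples).  Empty outputs are valid."""
    h_ner = encode_tokens(model.bundle, "NER", list(sentence.tokens), train=False)
    dist = predict_sp(h_ner, model.sp_head)
    spans = bioes_decode(TagSequence(sp_tags_from_distributions(dist)))
    mentions = []
    for i, (lo, hi) in enumerate(spans):
        label, _conf = predict_et(h_ner, (lo, hi), model.et)
        if label is None:
            continue   # no head above threshold: span stays untyped, dropped
        mentions.append(EntityMention(lo, hi, label, f"P{i}"))
    return mentions, _predict_relations(model, sentence, mentions)


def infer_conditional(model: JointModel, sentence: Sentence,
                      gold_mentions: list[EntityMention], condition: str):
    """Gold-conditioned inference for error-propagation analysis.

    ``gold_sp``      — type the GOLD spans (isolates typing from span errors);
    ``gold_sp_et``   — score relations over gold spans AND gold types
                       (isolates relation errors from both upstream stages).
    """
    if condition not in ("gold_sp", "gold_sp_et"):
        raise ValueError(f"unknown condition {condition!r}")
    if gold_mentions is None:
        raise ValueError("conditional inference needs gold mentions")
    if condition == "gold_sp":
        h_ner = encode_tokens(model.bundle, "NER", list(sentence.tokens), train=False)
        typed = []
        for i, m in enumerate(gold_mentions):
            label, _conf = predict_et(h_ner, m.span, model.et)
            if label is None:
                continue
            typed.append(EntityMention(m.start, m.end, label, f"P{i}"))
        return typed
    return _predict_relations(model, sentence, gold_mentions)


# ---------------------------------------------------------------------------
# schedule runner
# ---------------------------------------------------------------------------

def run_schedule(model: JointModel, schedule: TrainingSchedule, config: TrainConfig,
                 validation: Corpus | None = None,
                 optimizer: AdamW | None = None):
    """Train over an ordered schedule of corpus-subset steps.

    Per step: labels first seen in the step expand the vocabulary and heads;
    within a step, the epoch with the best validation RE micro-F1 is
    selected (ties → earlier epoch), with early stopping after
    ``early_stopping_patience`` epochs without improvement.  Step *t+1*
    continues from the parameters selected at step *t*.

    Returns ``(model, checkpoints, history)`` where ``history`` holds
    per-step per-epoch loss and validation records.
    """
    from .evaluation import evaluate_pipeline   # local import: module layering

    if not schedule.steps:
        raise ValueError("empty schedule")
    optimizer = optimizer or AdamW(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    checkpoints: list[StepCheckpoint] = []
    history: list[dict] = []

    for step in schedule.steps:
        corpus = step.corpus
        if len(corpus) == 0:
            raise ValueError(f"step {step.name} has no sentences")
        model.expand_labels(corpus.entity_type_labels(), corpus.relation_labels())
        if model.augmentation_mode == "prototype" and model.prototypes is None:
            model.freeze_prototypes(corpus)

        records = list(corpus.annotated())
        best_state, best_f1, best_epoch = None, -1.0, -1
        stale = 0
        epoch_log = []
        for epoch in range(config.epochs):
            order = rng.permutation(len(records))
            losses = []
            for lo in range(0, len(records), config.batch_size):
                batch = [records[i] for i in order[lo:lo + config.batch_size]]
                losses.append(train_step(model, batch, optimizer, config.weights))
            entry = {"step": step.name, "epoch": epoch,
                     "mean_loss": float(np.mean(losses))}
            if validation is not None:
                report = evaluate_pipeline(model, validation, conditional=False)
                val_f1 = report.metrics["RE"]["f1"]
                entry["val_re_f1"] = val_f1
                if val_f1 > best_f1:       # strict: ties keep the earlier epoch
                    best_f1, best_epoch = val_f1, epoch
                    best_state = model.state_dict()
                    stale = 0
                elif best_f1 > 0.0:
                    # patience only counts once the model has ever produced a
                    # nonzero validation score; stopping during the initial
                    # flat phase would freeze an untrained model
                    stale += 1
                if stale > config.early_stopping_patience:
                    epoch_log.append(entry)
                    break
            epoch_log.append(entry)
        if validation is not None and best_state is not None:
            model.load_state_dict(best_state)
        else:
            best_epoch = config.epochs - 1
        checkpoints.append(StepCheckpoint(
            step_name=step.name, state=model.state_dict(),
            entity_types=model.vocab.entity_types,
            relation_types=model.vocab.relation_types,
            best_epoch=best_epoch,
            val_metrics={"re_f1": best_f1} if validation is not None else {}))
        history.append({"step": step.name, "epochs": epoch_log,
                        "sources": step.sources})
    return model, checkpoints, history


def load_checkpoint(model: JointModel, checkpoint: StepCheckpoint) -> JointModel:
    """Restore a step checkpoint's parameters into a compatible model.

    Heads added after the checkpoint keep their current values (the
    checkpoint predates them); all parameters present in the snapshot are
    restored bit-exactly."""
    model.load_state_dict(checkpoint.state, strict=False)
    return model


def clone_model_state(model: JointModel) -> dict[str, np.ndarray]:
    return copy.deepcopy(model.state_dict())
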