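"""Training mechanics, the inference pipeline, and schedule bookkeeping."""

import numpy as np
import pytest

import spanrel.training as training_mod
from spanrel.classifiers import LossWeights
from spanrel.corpus import LabelVocabulary, Sentence, bioes_encode
from spanrel.encoders import TokenVocabulary
from spanrel.layers import AdamW
from spanrel.synthetic import SyntheticConfig, build_schedule, generate_corpus
from spanrel.training import (JointModel, TrainConfig, infer_conditional,
                              infer_sentence, run_schedule, train_step)


def _corpus(n=12, seed=3, **kw):
    base = dict(corpus_name="ade", entity_type_set=("Drug", "Disease"),
                relation_labels=("ADE",), n_sentences=n,
                relation_probability=1.0, mention_count_dist={1: 1.0}, seed=seed)
    base.update(kw)
    return generate_corpus(SyntheticConfig(**base))


def _model(corpus, seed=0, **kw):
    vocab = TokenVocabulary.from_corpora([corpus])
    lv = LabelVocabulary(corpus.entity_type_labels(), corpus.relation_labels())
    return JointModel(vocab, lv, seed=seed, **kw)


class TestTrainStep:
    def test_deterministic_updates(self):
        c = _corpus()
        batch = list(c.annotated())[:4]
        deltas = []
        for _ in range(2):
            model = _model(c, seed=1)
            before = model.state_dict()
            train_step(model, batch, AdamW(lr=5e-4))
            after = model.state_dict()
            deltas.append({k: after[k] - before[k] for k in after})
        for k in deltas[0]:
            assert np.array_equal(deltas[0][k], deltas[1][k])

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        c = _corpus()
        model = _model(c)
        before = model.state_dict()
        train_step(model, list(c.annotated())[:4], AdamW(lr=0.0))
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_loss_decreases_on_easy_batch(self):
        c = _corpus(n=6)
        model = _model(c)
        opt = AdamW(lr=5e-4)
        batch = list(c.annotated())
        losses = [train_step(model, batch, opt) for _ in range(50)]
        assert losses[-1] < losses[0] * 0.8

    def test_empty_batch_rejected(self):
        model = _model(_corpus())
        with pytest.raises(ValueError):
            train_step(model, [], AdamW())


class TestModelConstruction:
    def test_marker_mode_with_hard_sharing_rejected(self):
        c = _corpus()
        with pytest.raises(ValueError, match="hard"):
            _model(c, sharing_mode="hard", augmentation_mode="entity_marker")

    def test_hard_sharing_allowed_with_vanilla(self):
        c = _corpus()
        m = _model(c, sharing_mode="hard", augmentation_mode="vanilla")
        assert m.sharing_mode == "hard"

    def test_prototype_mode_requires_freezing_first(self):
        c = _corpus()
        m = _model(c, augmentation_mode="prototype")
        with pytest.raises(RuntimeError, match="freeze_prototypes"):
            infer_conditional(m, c.sentences[0], c.mentions[0], "gold_sp_et")

    def test_prototypes_frozen_through_training(self):
        c = _corpus(n=8)
        m = _model(c, augmentation_mode="prototype")
        m.freeze_prototypes(c)
        snapshot = {k: v.copy() for k, v in m.prototypes.vectors.items()}
        opt = AdamW(lr=5e-3)
        for _ in range(5):
            train_step(m, list(c.annotated())[:4], opt)
        for k in snapshot:
            assert np.array_equal(snapshot[k], m.prototypes.vectors[k])


class TestInference:
    def test_all_outside_tags_cascade_to_empty(self):
        c = _corpus()
        model = _model(c)
        # force the tagger to O everywhere (O is tag index 2)
        model.sp_head.net.fc2.weight.data[:] = 0.0
        model.sp_head.net.fc2.bias.data[:] = np.array([0.0, 0.0, 10.0, 0.0, 0.0])
        mentions, relations = infer_sentence(model, c.sentences[0])
        assert mentions == [] and relations == []

    def test_single_mention_yields_no_pairs(self, monkeypatch):
        c = _corpus()
        model = _model(c)
        calls = []
        monkeypatch.setattr(training_mod, "predict_re",
                            lambda v, h: calls.append(1) or ("ADE", 0.9))
        sent = c.sentences[0]
        gold = [c.mentions[0][0]]
        infer_conditional(model, sent, gold, "gold_sp_et")
        assert calls == []

    def test_pair_count_is_k_choose_2(self, monkeypatch):
        c = _corpus(mention_count_dist={2: 1.0})   # 2 per type -> 4 mentions
        model = _model(c)
        calls = []
        monkeypatch.setattr(training_mod, "predict_re",
                            lambda v, h: (calls.append(1), ("ADE", 0.9))[1])
        sent, ments = c.sentences[0], c.mentions[0]
        k = len(ments)
        infer_conditional(model, sent, ments, "gold_sp_et")
        assert len(calls) == k * (k - 1) // 2

    def test_gold_sp_equals_pipeline_when_sp_predicts_gold(self, monkeypatch):
        c = _corpus()
        model = _model(c)
        sent, gold = c.sentences[0], c.mentions[0]
        gold_tags = bioes_encode(sent, gold)
        onehot = np.zeros((sent.n, 5))
        from spanrel.corpus import BIOES_TAGS
        for i, t in enumerate(gold_tags):
            onehot[i, BIOES_TAGS.index(t)] = 1.0
        monkeypatch.setattr(training_mod, "predict_sp", lambda h, head: onehot)
        pipeline_mentions, _ = infer_sentence(model, sent)
        conditional_mentions = infer_conditional(model, sent, gold, "gold_sp")
        assert [(m.span, m.type_label) for m in pipeline_mentions] == \
               [(m.span, m.type_label) for m in conditional_mentions]

    def test_unknown_condition_rejected(self):
        c = _corpus()
        with pytest.raises(ValueError, match="condition"):
            infer_conditional(_model(c), c.sentences[0], c.mentions[0], "gold_et")


class TestRunSchedule:
    def test_three_step_continual_emits_three_checkpoints(self):
        corpora = [_corpus(n=6, seed=s, corpus_name=f"c{s}") for s in (1, 2, 3)]
        vocab = TokenVocabulary.from_corpora(corpora)
        model = JointModel(vocab, LabelVocabulary(), seed=0)
        sched = build_schedule(corpora, "continual", seed=0)
        model, ckpts, history = run_schedule(model, sched,
                                             TrainConfig(epochs=1, seed=0))
        assert len(ckpts) == 3
        assert [h["step"] for h in history] == ["step1", "step2", "step3"]

    def test_new_relation_label_grows_bank_exactly_at_its_step(self):
        ade = _corpus(n=6, seed=1, corpus_name="ade")
        cpr = generate_corpus(SyntheticConfig(
            "cpr", ("Drug", "Protein"), ("CPR",), n_sentences=6,
            relation_probability=1.0, mention_count_dist={1: 1.0}, seed=2))
        vocab = TokenVocabulary.from_corpora([ade, cpr])
        model = JointModel(vocab, LabelVocabulary(), seed=0)
        sched = build_schedule([ade, cpr], "continual", seed=0)
        model, ckpts, _ = run_schedule(model, sched, TrainConfig(epochs=1, seed=0))
        assert ckpts[0].relation_types == ("ADE",)
        assert ckpts[1].relation_types == ("ADE", "CPR")
        assert model.re.labels == ["ADE", "CPR"]

    def test_parameter_count_never_shrinks(self):
        corpora = [
            _corpus(n=5, seed=1, corpus_name="ade"),
            generate_corpus(SyntheticConfig("cpr", ("Drug", "Protein"), ("CPR",),
                                            n_sentences=5, seed=2)),
        ]
        vocab = TokenVocabulary.from_corpora(corpora)
        model = JointModel(vocab, LabelVocabulary(), seed=0)
        counts = []
        sched = build_schedule(corpora, "continual", seed=0)
        opt = AdamW()
        cfg = TrainConfig(epochs=1, seed=0)
        # run step by step to observe the parameter count trajectory
        for step in sched.steps:
            model.expand_labels(step.corpus.entity_type_labels(),
                                step.corpus.relation_labels())
            counts.append(sum(p.data.size for p in model.parameters()))
        assert counts == sorted(counts)
        assert counts[1] > counts[0]

    def test_one_step_schedule_equals_multi_corpora_training(self):
        c = _corpus(n=8, seed=4)
        vocab = TokenVocabulary.from_corpora([c])
        sched_m = build_schedule([c], "multi_corpora", seed=0)
        sched_c = build_schedule([c], "continual", seed=0)
        outs = []
        for sched in (sched_m, sched_c):
            model = JointModel(vocab, LabelVocabulary(), seed=0)
            model, _, _ = run_schedule(model, sched, TrainConfig(epochs=1, seed=0))
            outs.append(model.state_dict())
        assert all(np.array_equal(outs[0][k], outs[1][k]) for k in outs[0])
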