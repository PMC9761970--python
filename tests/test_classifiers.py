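"""Heads, multi-head aggregation, head expansion, and the joint loss."""

import numpy as np
import pytest

from spanrel.autograd import Tensor
from spanrel.classifiers import (LossWeights, MultiHeadBank, NO_RELATION, SingleHead,
                                 SPHead, add_head, aggregate_multihead,
                                 binary_cross_entropy, cross_entropy_loss,
                                 joint_loss, multihead_bce_sum, predict_et,
                                 predict_re, predict_sp)


class TestPredictSP:
    def test_normalized_distribution_per_token(self, rng):
        head = SPHead(d=16, hidden_dim=8, seed=0)
        h = Tensor(rng.normal(size=(5, 16)))
        dist = predict_sp(h, head)
        assert dist.shape == (5, 5)
        assert np.allclose(dist.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_rows_give_identical_distributions(self, rng):
        head = SPHead(d=16, hidden_dim=8, seed=0)
        row = rng.normal(size=16)
        dist = predict_sp(Tensor(np.stack([row, row, row])), head)
        assert np.allclose(dist[0], dist[1]) and np.allclose(dist[1], dist[2])

    def test_zeroed_final_layer_is_uniform(self, rng):
        head = SPHead(d=16, hidden_dim=8, seed=0)
        head.net.fc2.weight.data[:] = 0.0
        head.net.fc2.bias.data[:] = 0.0
        dist = predict_sp(Tensor(rng.normal(size=(3, 16))), head)
        assert np.allclose(dist, 0.2)


class TestAggregateMultihead:
    @pytest.mark.parametrize("scores,theta,expected", [
        ({"A": 0.9, "B": 0.7}, 0.5, "A"),     # most-confident rule
        ({"A": 0.4, "B": 0.3}, 0.5, None),    # nothing above threshold
        ({"A": 0.8, "B": 0.8}, 0.5, "A"),     # tie -> lowest vocabulary index
        ({"A": 0.2, "B": 0.6}, 0.5, "B"),
        ({}, 0.5, None),
    ])
    def test_rules(self, scores, theta, expected):
        assert aggregate_multihead(scores, theta, list(scores)) == expected

    def test_tie_break_matches_max_with_index_scan(self, rng):
        labels = [f"L{i}" for i in range(6)]
        for _ in range(200):
            scores = {lab: float(rng.choice([0.2, 0.6, 0.6, 0.9]))
                      for lab in labels}
            got = aggregate_multihead(scores, 0.5, labels)
            # brute-force scan: first index achieving the max above-threshold score
            cands = [(lab, s) for lab, s in scores.items() if s > 0.5]
            want = None
            if cands:
                best = max(s for _, s in cands)
                want = next(lab for lab in labels if scores[lab] == best and best > 0.5)
            assert got == want

    def test_total_on_any_finite_scores(self, rng):
        for _ in range(100):
            scores = {f"L{i}": float(rng.random()) for i in range(4)}
            assert aggregate_multihead(scores, float(rng.random()),
                                       list(scores)) in (None, *scores)


class TestPredictEtRe:
    def test_multihead_unique_positive_head_wins(self, rng):
        bank = MultiHeadBank(8, 8, ["Drug", "Disease"], theta=0.5, task="ET", seed=0)
        x = Tensor(rng.normal(size=(4, 8)))
        # force Drug head positive, Disease head negative
        bank.head("Drug").fc2.weight.data[:] = 0.0
        bank.head("Drug").fc2.bias.data[:] = 5.0
        bank.head("Disease").fc2.weight.data[:] = 0.0
        bank.head("Disease").fc2.bias.data[:] = -5.0
        label, conf = predict_et(x, (1, 2), bank)
        assert label == "Drug" and conf > 0.99

    def test_et_span_sum_equals_vector_addition(self, rng):
        bank = MultiHeadBank(8, 8, ["Drug"], theta=0.5, task="ET", seed=0)
        h = Tensor(rng.normal(size=(3, 8)))
        label_direct, conf_direct = predict_et(h, (0, 1), bank)
        summed = Tensor((h.data[0] + h.data[1])[None, :])
        probs = bank.probabilities(Tensor(h.data[0] + h.data[1]))
        assert conf_direct == pytest.approx(max(probs.values()), abs=1e-12)

    def test_re_abstains_when_all_heads_below_threshold(self, rng):
        bank = MultiHeadBank(8, 8, ["ADE", "DDI"], theta=0.5, task="RE", seed=0)
        for lab in bank.labels:
            bank.head(lab).fc2.weight.data[:] = 0.0
            bank.head(lab).fc2.bias.data[:] = -4.0
        label, _ = predict_re(Tensor(rng.normal(size=8)), bank)
        assert label == NO_RELATION

    def test_re_most_confident_head_wins(self):
        bank = MultiHeadBank(4, 4, ["ADE", "DDI"], theta=0.5, task="RE", seed=0)
        bank.head("ADE").fc2.weight.data[:] = 0.0
        bank.head("ADE").fc2.bias.data[:] = np.log(0.9 / 0.1)   # sigmoid -> 0.9
        bank.head("DDI").fc2.weight.data[:] = 0.0
        bank.head("DDI").fc2.bias.data[:] = np.log(0.7 / 0.3)   # sigmoid -> 0.7
        label, conf = predict_re(Tensor(np.zeros(4)), bank)
        assert label == "ADE" and conf == pytest.approx(0.9, abs=1e-9)

    def test_single_head_null_class_argmax(self):
        head = SingleHead(4, 4, ["ADE"], seed=0, with_null_class=True)
        head.net.fc2.weight.data[:] = 0.0
        head.net.fc2.bias.data[:] = np.array([3.0, -3.0])   # null class maximal
        label, _ = predict_re(Tensor(np.zeros(4)), head)
        assert label == NO_RELATION

    def test_dimension_mismatch_rejected(self, rng):
        head = SingleHead(6, 4, ["ADE"], seed=0, with_null_class=True)
        with pytest.raises(ValueError, match="dim"):
            predict_re(Tensor(rng.normal(size=9)), head)


class TestJointLoss:
    def test_unit_components_with_default_weights(self):
        w = LossWeights()
        assert (w.sp, w.et, w.re) == (0.4, 0.25, 0.35)
        assert joint_loss(1.0, 1.0, 1.0, w) == pytest.approx(1.0, abs=1e-9)

    def test_decomposition_identity_on_random_batch(self, rng):
        w = LossWeights(0.4, 0.25, 0.35)
        bank_et = MultiHeadBank(8, 8, ["Drug", "Disease"], task="ET", seed=1)
        bank_re = MultiHeadBank(8, 8, ["ADE"], task="RE", seed=2)
        sp_head = SPHead(8, 8, seed=3)
        h = Tensor(rng.normal(size=(4, 8)))
        x = Tensor(rng.normal(size=8))
        sp_l = cross_entropy_loss(sp_head(h), np.array([0, 2, 2, 4]))
        et_l = multihead_bce_sum(bank_et, x, "Drug")
        re_l = multihead_bce_sum(bank_re, x, None)
        total = joint_loss(sp_l, et_l, re_l, w)
        assert float(total.data) == pytest.approx(
            0.4 * float(sp_l.data) + 0.25 * float(et_l.data) + 0.35 * float(re_l.data),
            abs=1e-6)

    def test_cross_entropy_matches_manual_logsumexp(self, rng):
        logits = rng.normal(size=(5, 3))
        targets = np.array([0, 2, 1, 1, 0])
        got = float(cross_entropy_loss(Tensor(logits), targets).data)
        lse = np.log(np.exp(logits).sum(axis=1))
        want = float(np.mean(lse - logits[np.arange(5), targets]))
        assert got == pytest.approx(want, abs=1e-9)

    def test_bce_matches_manual(self, rng):
        for z in rng.normal(scale=3.0, size=10):
            for y in (0.0, 1.0):
                got = float(binary_cross_entropy(Tensor(np.array(z)), y).data)
                p = 1.0 / (1.0 + np.exp(-z))
                want = -(y * np.log(p) + (1 - y) * np.log(1 - p))
                assert got == pytest.approx(want, abs=1e-9)

    def test_perfect_predictions_drive_loss_to_zero(self):
        logits = Tensor(np.array([[50.0, 0.0, 0.0], [0.0, 50.0, 0.0]]))
        assert float(cross_entropy_loss(logits, np.array([0, 1])).data) < 1e-6

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.5, 0.5)


class TestHeadExpansion:
    def test_add_head_appends_without_touching_existing(self, rng):
        bank = MultiHeadBank(8, 8, ["A", "B"], task="RE", seed=0)
        x = Tensor(rng.normal(size=(8,)))
        before = bank.probabilities(x)
        snapshots = {lab: {k: v.data.copy()
                           for k, v in bank.head(lab).named_parameters()}
                     for lab in ("A", "B")}
        add_head(bank, "C")
        assert bank.labels == ["A", "B", "C"]
        after = bank.probabilities(x)
        for lab in ("A", "B"):
            assert after[lab] == before[lab]       # bit-identical scores
            for k, v in bank.head(lab).named_parameters():
                assert np.array_equal(v.data, snapshots[lab][k])

    def test_duplicate_label_rejected(self):
        bank = MultiHeadBank(4, 4, ["A"], task="ET", seed=0)
        with pytest.raises(ValueError, match="already"):
            add_head(bank, "A")

    def test_single_head_expand_copies_trained_columns(self, rng):
        head = SingleHead(6, 4, ["Drug"], seed=0)
        x = Tensor(rng.normal(size=6))
        before = head(x).softmax(axis=-1).data.copy()
        head.expand(["Disease"])
        after = head(x).softmax(axis=-1).data
        assert head.labels == ["Drug", "Disease"]
        # old class logits preserved (probabilities renormalize over 2 classes)
        assert after.shape == (2,)
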