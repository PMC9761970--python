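"""Entity markers, prototypes, and the four pair-representation modes."""

import numpy as np
import pytest

from spanrel.autograd import Tensor
from spanrel.augmentation import (PrototypeTable, TypeEmbeddingTable,
                                  compute_prototypes, insert_entity_markers,
                                  maxpool_reduce, pair_representation, strip_markers)
from spanrel.corpus import Corpus, EntityMention, Sentence
from spanrel.encoders import TokenVocabulary, TinyTransformerEncoder
from tests.conftest import random_span_set


class TestEntityMarkers:
    def test_worked_example(self):
        sent = Sentence(("Pravastatin", "is", "associated", "with", "myotonia",
                         "in", "animals"))
        marked = insert_entity_markers(sent, [EntityMention(0, 0, "Drug", "e1"),
                                              EntityMention(4, 4, "Disease", "e2")])
        assert " ".join(marked.tokens) == (
            "[Drug_start] Pravastatin [Drug_end] is associated with "
            "[Disease_start] myotonia [Disease_end] in animals")
        assert strip_markers(marked) == sent.tokens

    def test_no_mentions_is_identity(self):
        sent = Sentence(("a", "b", "c"))
        marked = insert_entity_markers(sent, [])
        assert marked.tokens == sent.tokens
        assert marked.start_marker_pos == {}

    def test_adjacent_single_token_mentions(self):
        sent = Sentence(("cadaprine", "lunomycin", "given"))
        marked = insert_entity_markers(sent, [EntityMention(0, 0, "Drug", "a"),
                                              EntityMention(1, 1, "Drug", "b")])
        assert len(marked) == sent.n + 4
        assert strip_markers(marked) == sent.tokens

    def test_start_marker_positions_point_at_markers(self):
        sent = Sentence(tuple("abcdef"))
        marked = insert_entity_markers(sent, [EntityMention(1, 2, "Drug", "m1"),
                                              EntityMention(4, 4, "Disease", "m2")])
        for mid, pos in marked.start_marker_pos.items():
            assert marked.tokens[pos].endswith("_start]")

    def test_round_trip_over_random_mention_sets(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            sent = Sentence(tuple(f"w{i}" for i in range(n)))
            mentions = [EntityMention(a, b, "Drug", f"m{k}")
                        for k, (a, b) in enumerate(random_span_set(rng, n))]
            marked = insert_entity_markers(sent, mentions)
            assert len(marked) == n + 2 * len(mentions)
            assert strip_markers(marked) == sent.tokens

    def test_overlap_rejected(self):
        sent = Sentence(tuple("abcd"))
        with pytest.raises(ValueError, match="overlap"):
            insert_entity_markers(sent, [EntityMention(0, 2, "Drug", "x"),
                                         EntityMention(1, 3, "Drug", "y")])


class TestPrototypes:
    def test_maxpool_chunked_reduction(self):
        vec = np.arange(100.0)
        pooled = maxpool_reduce(vec, 50)
        assert pooled.shape == (50,)
        assert np.array_equal(pooled, np.arange(1.0, 100.0, 2.0))

    def test_two_token_mean_oracle(self):
        tokens = ("velastatin", "and", "cadaprine")
        sent = Sentence(tokens, sentence_id="s0")
        corpus = Corpus("c", [sent],
                        [[EntityMention(0, 0, "Drug", "T1"),
                          EntityMention(2, 2, "Drug", "T2")]], [[]])
        enc = TinyTransformerEncoder(TokenVocabulary(tokens), d=64, seed=4)
        table = compute_prototypes(corpus, enc)
        h = enc(list(tokens)).data
        p1, p2 = maxpool_reduce(h[0], 50), maxpool_reduce(h[2], 50)
        assert np.allclose(table.lookup("Drug"), (p1 + p2) / 2.0)

    def test_single_token_prototype_is_its_pooled_vector(self):
        tokens = ("morinitis", "observed")
        corpus = Corpus("c", [Sentence(tokens)],
                        [[EntityMention(0, 0, "Disease", "T1")]], [[]])
        enc = TinyTransformerEncoder(TokenVocabulary(tokens), d=64, seed=4)
        table = compute_prototypes(corpus, enc)
        assert np.allclose(table.lookup("Disease"),
                           maxpool_reduce(enc(list(tokens)).data[0], 50))

    def test_missing_type_rejected(self):
        tokens = ("a", "b")
        corpus = Corpus("c", [Sentence(tokens)], [[]], [[]])
        enc = TinyTransformerEncoder(TokenVocabulary(tokens), d=64, seed=0)
        with pytest.raises(ValueError, match="Protein"):
            compute_prototypes(corpus, enc, entity_types=["Protein"])


class TestPairRepresentation:
    def _states(self, rng, n=6, d=8):
        return Tensor(rng.normal(size=(n, d)))

    def test_vanilla_single_token_spans_concatenate_rows(self, rng):
        h = self._states(rng)
        v = pair_representation("vanilla", h, EntityMention(1, 1, "Drug", "a"),
                                EntityMention(3, 3, "Disease", "b"))
        assert np.allclose(v.vector.data, np.concatenate([h.data[1], h.data[3]]))

    def test_vanilla_multi_token_spans_sum(self, rng):
        h = self._states(rng)
        v = pair_representation("vanilla", h, EntityMention(0, 2, "Drug", "a"),
                                EntityMention(4, 5, "Disease", "b"))
        oracle = np.concatenate([h.data[0:3].sum(axis=0), h.data[4:6].sum(axis=0)])
        assert np.allclose(v.vector.data, oracle)

    def test_type_embedding_matches_independent_concatenation(self, rng):
        h = self._states(rng)
        table = TypeEmbeddingTable(["Drug", "Disease"], dim=5, seed=1)
        v = pair_representation("type_embedding", h,
                                EntityMention(0, 1, "Drug", "a"),
                                EntityMention(3, 4, "Disease", "b"),
                                aux=table, type_labels=("Drug", "Disease"))
        oracle = np.concatenate([h.data[0:2].sum(axis=0),
                                 table.lookup("Drug").data,
                                 h.data[3:5].sum(axis=0),
                                 table.lookup("Disease").data])
        assert np.allclose(v.vector.data, oracle)
        assert v.dim == 2 * 8 + 2 * 5

    def test_prototype_mode_uses_frozen_vectors(self, rng):
        h = self._states(rng)
        table = PrototypeTable(vectors={"Drug": np.ones(5), "Disease": np.zeros(5)},
                               dim=5)
        v = pair_representation("prototype", h, EntityMention(0, 0, "Drug", "a"),
                                EntityMention(2, 2, "Disease", "b"),
                                aux=table, type_labels=("Drug", "Disease"))
        assert np.allclose(v.vector.data[8:13], np.ones(5))
        assert np.allclose(v.vector.data[21:26], np.zeros(5))

    def test_entity_marker_mode_picks_start_marker_rows(self, rng):
        h = self._states(rng, n=10, d=8)
        marker_map = {"a": 0, "b": 5}
        v = pair_representation("entity_marker", h,
                                EntityMention(1, 1, "Drug", "a"),
                                EntityMention(6, 6, "Disease", "b"),
                                aux=marker_map)
        assert np.allclose(v.vector.data, np.concatenate([h.data[0], h.data[5]]))
        assert v.dim == 16

    def test_swap_permutes_halves_exactly(self, rng):
        h = self._states(rng)
        mj, mk = EntityMention(0, 1, "Drug", "a"), EntityMention(3, 4, "Disease", "b")
        v_jk = pair_representation("vanilla", h, mj, mk).vector.data
        v_kj = pair_representation("vanilla", h, mk, mj).vector.data
        half = len(v_jk) // 2
        assert np.array_equal(v_jk[:half], v_kj[half:])
        assert np.array_equal(v_jk[half:], v_kj[:half])

    def test_missing_aux_rejected(self, rng):
        h = self._states(rng)
        with pytest.raises(ValueError, match="aux|Table|map"):
            pair_representation("type_embedding", h,
                                EntityMention(0, 0, "Drug", "a"),
                                EntityMention(1, 1, "Disease", "b"),
                                type_labels=("Drug", "Disease"))

    def test_span_outside_states_rejected(self, rng):
        h = self._states(rng, n=3)
        with pytest.raises(ValueError, match="outside"):
            pair_representation("vanilla", h, EntityMention(0, 0, "Drug", "a"),
                                EntityMention(2, 5, "Disease", "b"))
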