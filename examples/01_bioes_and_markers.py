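"""Span encoding and entity-marker rewriting on two classic sentences.

Prints the BIOES tag sequence for an adverse-drug-event sentence and the
marker-augmented form the relation encoder consumes.
"""

from spanrel import bioes_decode, bioes_encode, insert_entity_markers, strip_markers
from spanrel.corpus import EntityMention, Sentence

sent = Sentence(("Two", "cases", "of", "mequitazine", "induced",
                 "photosensitivity", "reactions"))
mentions = [EntityMention(3, 3, "Drug", "T1"),
            EntityMention(5, 6, "Disease", "T2")]

tags = bioes_encode(sent, mentions)
print("tokens:", " ".join(sent.tokens))
print("BIOES :", " ".join(tags.tags))
# S marks the single-token drug; B..E bracket the two-token disease.
print("decoded spans:", bioes_decode(tags), "(round-trips the gold spans)")

sent2 = Sentence(("Pravastatin", "is", "associated", "with", "myotonia",
                  "in", "animals"))
marked = insert_entity_markers(sent2, [EntityMention(0, 0, "Drug", "e1"),
                                       EntityMention(4, 4, "Disease", "e2")])
print("\nmarked :", " ".join(marked.tokens))
print("start-marker positions:", marked.start_marker_pos)
print("stripped == original:", strip_markers(marked) == sent2.tokens)
# The relation classifier reads the hidden states at the two start markers,
# so span AND type information reach it through the input sequence itself.
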