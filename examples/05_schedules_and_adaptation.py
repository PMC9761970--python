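"""The three learning paradigms and corpus-adaptation evaluation.

Builds three corpora in the classic configuration — adverse drug events
(Drug/Disease), drug-drug interactions (Drug only) and chemical-protein
reactions (Drug/Protein) — shows how each paradigm arranges them into
training steps, and scores a model on a "foreign" corpus from a simulated
different annotation effort.
"""

from spanrel import generate_corpus
from spanrel.synthetic import (SyntheticConfig, build_schedule,
                               generate_foreign_corpus, split_subsets)

ade = generate_corpus(SyntheticConfig("ade", ("Drug", "Disease"), ("ADE",),
                                      n_sentences=30, seed=1))
ddi = generate_corpus(SyntheticConfig("ddi", ("Drug",), ("DDI",),
                                      n_sentences=20, seed=2))
cpr = generate_corpus(SyntheticConfig("cpr", ("Drug", "Protein"), ("CPR",),
                                      n_sentences=10, seed=3))

for paradigm in ("continual", "multi_corpora", "continual_multi_corpora"):
    sched = build_schedule([ade, ddi, cpr], paradigm, seed=0)
    print(f"{paradigm}:")
    for step in sched.steps:
        parts = " + ".join(f"{name}({n})" for name, n in step.sources)
        print(f"  {step.name}: {parts}")
# continual feeds whole corpora in sequence; multi_corpora pools everything;
# continual_multi_corpora splits earlier corpora (ADE into 3, DDI into 2)
# so later steps replay their remaining parts alongside the new corpus.

split = split_subsets(ade, 3, seed=0)
print("\nADE split sizes:", split.part_sizes, "(near-equal, remainder first)")

foreign = generate_foreign_corpus(
    SyntheticConfig("ade", ("Drug", "Disease"), ("ADE",), n_sentences=20, seed=1),
    lexicon_overlap=0.5, type_remap_fraction=0.2)
print(f"\nforeign corpus: {len(foreign)} sentences, "
      f"half the surface lexicon replaced, 20% of Drug mentions re-typed")
print("first foreign sentence:", " ".join(foreign.sentences[0].tokens))
# A trained model is scored on such a corpus with
# spanrel.corpus_adaptation_eval(model, foreign) — the cross-corpus
# generalization protocol.
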