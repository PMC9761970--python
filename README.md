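# spanrel

Joint biomedical entity and relation extraction with continually
expandable label vocabularies.

Biomedical corpora each annotate their own slice of the world: an
adverse-drug-event corpus marks drugs, diseases and ADE relations; a
drug–drug-interaction corpus marks drugs and DDI relations; a
chemical–protein corpus marks chemicals, proteins and CPR relations.  A
model that should serve a growing knowledge graph has to learn from all of
them — including corpora that arrive *after* training started — without
retraining from scratch and without forgetting earlier label sets.

`spanrel` implements a joint extraction network built for that setting:

* **Span detection (SP)** — a token-level tagger over the BIOES alphabet
  (Beginning/Inside/Outside/End/Single), typed separately from
  entity typing so each task has a small label space:
  `ŷᵢ^SP = T^SP(hᵢ^NER)`.
* **Entity typing (ET)** — a classifier on the span-summed encoder states,
  `ŷ^ET = T^ET(Σᵢ hᵢ^NER)`.
* **Relation extraction (RE)** — a classifier over a joined pair vector
  `v^RE` built by one of four augmentation modes; the default is **entity
  markers**: the sentence is rewritten as
  `[Drug_start] Pravastatin [Drug_end] is associated with
  [Disease_start] myotonia [Disease_end] …`, and `v^RE` concatenates the
  hidden states at the two start markers.
* **Two encoders** (NER and RE branches) with *hard*, *soft*
  (cross-attention fusion `softmax(H^RE H^NERᵀ/√d)·H^NER ⊙ H^RE`) or *no*
  parameter sharing; the default is no sharing.
* **Expandable multi-head classifiers** — one binary head per entity type
  and per relation label.  New corpora append new heads; existing heads
  are never touched, and prediction takes the most confident head above a
  threshold θ.
* **Training schedules** — sequential continual learning, pooled
  multi-corpora learning, and *continual multi-corpora* learning, where
  corpus *i* of *k* is split into *k−i+1* equal parts and later steps
  replay the remaining parts of earlier corpora alongside the new one.
* **Propagation-aware evaluation** — micro-F1 for SP (token level, O
  excluded), ET (exact span+type match) and RE (exact pair+label match),
  plus gold-conditioned ET⁺/RE⁺ scores that isolate each stage's own
  errors, pooled multi-corpus scoring, and corpus-adaptation evaluation on
  a held-out foreign corpus.

Training minimizes the weighted joint loss
`L = α^SP L^SP + α^ET L^ET + α^RE L^RE` (defaults 0.4/0.25/0.35), with
per-head binary cross-entropy summed over heads in the multi-head form.
The encoder is a small word-level transformer (d = 64, 2 layers) with its
own reverse-mode autodiff engine and AdamW optimizer (lr 5e-4, batch 8),
so everything trains on one CPU in minutes.  A synthetic-corpus generator
emulates the ADE/DDI/CPR structure (disjoint type lexicons, cue
connectives carrying relation presence, optional type-label noise) so
every component is testable without downloads.

## Worked example

```python
from spanrel import bioes_encode, insert_entity_markers
from spanrel.corpus import EntityMention, Sentence

sent = Sentence(("Two", "cases", "of", "mequitazine", "induced",
                 "photosensitivity", "reactions"))
mentions = [EntityMention(3, 3, "Drug", "T1"),
            EntityMention(5, 6, "Disease", "T2")]
print(" ".join(bioes_encode(sent, mentions).tags))
# O O O S O B E   <- single-token drug = S, two-token disease = B E
```

An end-to-end scaled-down run (`python examples/03_train_and_evaluate.py`,
150 train / 40 validation / 40 test synthetic sentences, ≤12 epochs)
prints:

```
selected epoch 11 (validation RE micro-F1 0.561)
SP   P=0.942 R=0.922 F1=0.932
ET   P=0.968 R=0.860 F1=0.911
RE   P=0.667 R=0.553 F1=0.605
ET+  P=0.971 R=0.944 F1=0.957
RE+  P=0.750 R=0.830 F1=0.788
```

At this reduced scale relation extraction is still data-limited; the
full-scale run in `scripts/acceptance.py` (500 training sentences, up to
30 epochs) reaches micro-F1 above 0.9 on all three tasks.

SP/ET/RE are pipeline scores — each stage consumes the previous stage's
predictions, so span errors propagate downstream.  ET⁺ and RE⁺ re-score
typing and relations with gold upstream annotations; the gap between RE
and RE⁺ is the error propagated from span detection and typing.  The other
scripts in `examples/` demonstrate corpus generation, the three schedules,
and the forgetting experiment; the `spanrel` CLI (`generate`, `train`,
`evaluate`, `report`) wraps the same library calls for shell use.

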