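# Methods

## The model

`spanrel` extracts typed entity mentions and binary relations from
pre-tokenized sentences with three cooperating tasks trained jointly:

* **Span detection (SP).** Every token gets one tag from the BIOES
  alphabet (Beginning / Inside / Outside / End / Single).  The alphabet
  represents exactly the sets of non-overlapping, non-nested spans;
  overlapping gold annotations are rejected at load time rather than
  silently truncated.  Decoding is conservative: only well-formed
  segments (a lone `S`, or `B I* E`) produce spans, and malformed
  fragments yield nothing — the decoder never fabricates boundaries that
  the relation stage would then consume.
* **Entity typing (ET).** A classifier applied to the sum (not mean —
  span length is itself informative) of the NER-branch hidden states over
  a span.  Supervision covers gold mention spans only; the span-existence
  signal lives entirely in SP.
* **Relation extraction (RE).** A classifier over a joined pair vector
  built from the RE-branch hidden states for every unordered pair of
  mentions in a sentence.  Pairs without a gold relation are trained as
  explicit negatives (all heads negative in the multi-head form, a
  dedicated NO_RELATION class in the single-head form).  Relations are
  stored and matched as unordered pairs.

The total loss is `α_SP·L_SP + α_ET·L_ET + α_RE·L_RE` with defaults
(0.4, 0.25, 0.35).  In the multi-head form the ET and RE components are
sums of per-head binary cross-entropies (summed over heads, not
averaged); within a sentence, per-mention and per-pair terms are averaged
so sentences with many mentions do not dominate a batch.

At inference the stages run as a pipeline: predicted tags are decoded to
spans, spans are typed, and pair vectors are built from the *predicted*
spans and types (during training, from gold).  The gold-conditioned
variants ET⁺ (typing on gold spans) and RE⁺ (relations on gold spans and
types) replace upstream stages to isolate each stage's own errors.

## Encoders and parameter sharing

Both branches use a small word-level transformer: learned token
embeddings, fixed sinusoidal positions, two pre-norm self-attention
blocks (d = 64, 4 heads, FFN width 128), a final layer norm.  The
encoder is word-level, so no sub-token pooling is needed.  Three sharing
modes couple the branches:

* `hard` — one encoder object serves both branches (a single parameter
  set, verified by the test suite through gradient coupling);
* `none` — two disjoint encoders (the default; parameter-noise injection
  into one branch provably never moves the other);
* `soft` — two encoders, with every RE layer's output replaced by its
  cross-attention fusion with the NER encoder's final-layer states:
  `fused = softmax(H_re · H_nerᵀ / √d) · H_ner ⊙ H_re`.  The trailing
  product is elementwise; a matrix product of two n×d factors would be
  dimensionally inconsistent.  Whether the fusion replaces or augments
  the RE stream is a genuinely open design point; this implementation
  replaces it.

Entity-marker tokens (`[Drug_start]`, `[Drug_end]`, …) live outside the
word-embedding matrix in per-marker parameter slots.  This makes marker
registration for types learned in later steps purely additive: no
existing embedding row is ever reallocated, which is what the
continual-learning contract requires.  Marker mode is rejected in
combination with hard sharing at construction time: the NER branch must
see the raw sentence while the RE branch sees the marked one, which a
single shared input stream cannot provide.

## Pair-representation modes

* `vanilla` — `[Σ h over span_j ; Σ h over span_k]`, dimension 2d.
* `type_embedding` — vanilla interleaved with learned 50-d type
  embeddings (2d + 100); gold types during training, predicted at
  inference.
* `prototype` — vanilla interleaved with frozen 50-d type prototypes.  A
  prototype is the mean, over all mention tokens of a type in the
  training corpus, of a max-pooled reduction of the *untrained* base
  encoder's token vector.  The d→50 reduction partitions the vector into
  50 contiguous chunks and takes each chunk's maximum — the simplest
  deterministic max-based reduction; the exact mechanics are an
  interpretation choice.  The table is computed once before training and
  is bit-frozen thereafter (property-tested).
* `entity_marker` (default) — the hidden states at the two start markers
  (2d).  Start markers only; end markers exist in the input but are not
  read out.

## Expandable classifiers

The multi-head form keeps one two-layer binary head (sigmoid output) per
label, ordered like the label vocabulary.  Appending a head never mutates
existing heads (asserted bit-exactly).  Prediction takes the most
confident head strictly above θ = 0.5 (configurable), ties broken toward
the lowest vocabulary index; no head above θ means "no type" for ET
(the span is dropped — an untyped mention cannot be scored under the
exact span+type rule) and NO_RELATION for RE.  The single-head baseline
is a standard multi-class softmax; it can only grow by reallocating its
output projection (old columns are copied, but the optimizer state for
that layer restarts), which is precisely the structural weakness the
multi-head form avoids.

## Training schedules and continual learning

A schedule is an ordered list of steps, each a bag of corpus subsets
pooled and shuffled:

* `continual` — one step per corpus, in order;
* `multi_corpora` — a single pooled step;
* `continual_multi_corpora` — corpus *i* of *k* is split into *k−i+1*
  near-equal random parts and part *t−i+1* joins step *t*.  For three
  corpora this is the classic 3/2/1 instance (ADE split in three, DDI in
  two, CPR whole); the general rule is the natural extension and each
  subset is used exactly once.

Step *t+1* starts from the parameters selected at step *t*; the optimizer
(AdamW, lr 5e-4, weight decay 0.01, batch 8) carries its moments across
steps.  Labels first seen at a step expand the vocabulary, add heads,
markers and type embeddings before training begins.  Within a step the
epoch with the best validation RE micro-F1 is selected (ties keep the
earlier epoch), with early stopping after 5 epochs without improvement —
but patience only counts once the metric has ever been nonzero, because
stopping during the initial flat phase would freeze an untrained model.
The epoch cap defaults to 30.  Five-repetition averaging is realized as
seeds `seed..seed+4` with mean reporting.

## Scoring rules

* **SP** — token-level micro-F1 over the four positive tags; O is not a
  positive class (counting it would collapse micro-F1 into token accuracy
  and mask boundary errors).  The choice is switchable in principle but
  is the package default.
* **ET / united NER** — exact one-to-one (span, type) matching per
  sentence; an unmatched prediction is one FP, an unmatched gold mention
  one FN, so a wrong type on a correct span costs both.
* **RE** — exact matching of (entity, entity, label) triples with
  unordered pairs; each entity must match span *and* type.
* **Combined** — TP/FP/FN pooled across corpora before the single
  precision/recall ratio (micro pooling, never an average of F1s).
* **Corpus adaptation** — the full pipeline scored on a corpus that never
  appears in training, reported separately from within-corpora results.

All matchers are verified exactly against an independent brute-force
matcher on hundreds of randomized cases.

## Synthetic data

The generator emulates the structure of drug/disease/protein IE corpora:
each corpus has its own subset of the global entity types, one or more
relation labels with fixed admissible type pairs (ADE: Drug–Disease,
DDI: Drug–Drug, CPR: Drug–Protein), 0–k mentions per type per sentence,
and relations between admissible co-occurring pairs.

Design choices, fixed once:

* Per-type surface lexicons (40 pseudo-word entries by default, ~30%
  two-token) are disjoint across types by construction, so typing is
  learnable from surface form.  Lexicons are governed by a `lexicon_seed`
  separate from the sentence-sampling seed: train/validation/test splits
  of one corpus family share lexicons, i.e. they sample the same
  population.
* Relation presence is signalled lexically.  With probability
  `relation_probability` (default 0.7) a sentence is "relational" for a
  label: every admissible pair in it is annotated and a relation-specific
  cue connective appears in the sentence; otherwise a neutral connective
  appears.  Every active cue is guaranteed to surface, so the mapping
  from token sequence to gold relations is deterministic — the RE task is
  learnable in principle, exactly like trigger words carry relations in
  real prose.
* Label noise flips mention *types* within the corpus's type set (spans
  stay correct), from a dedicated random stream so the noise setting
  never shifts sentence assembly.  This emulates annotation-guideline
  deviations between corpora.
* The foreign-corpus variant (for corpus-adaptation evaluation) keeps a
  configurable fraction of the lexicon (default 50%), draws the rest
  fresh, uses different sentence openers, and re-types a configurable
  fraction of mentions — a simulated different annotation effort.

What passing tests on this data do and do not show: the generator's
sentences are short templated token sequences with unambiguous lexical
cues; success demonstrates that the architecture, losses, schedules and
scorers are correctly wired and that the pipeline can learn a learnable
extraction task end-to-end.  It does not demonstrate performance on real
biomedical prose, whose entity boundaries, trigger ambiguity and genre
variation are far harder; the real-corpus setting additionally relies on
a pretrained biomedical language model, which this package does not
bundle.

## Numerics

The neural stack (reverse-mode autodiff, transformer layers, AdamW) is
implemented in-house on numpy in float64; gradients are verified against
central finite differences.  Training is deterministic given the seed:
all randomness flows through seeded `numpy` generators, and identical
seeds reproduce parameter trajectories bit-for-bit.  Softmax and
log-softmax use max-shifting; binary cross-entropy uses the
`softplus(z) − y·z` form with an overflow-safe softplus.  Degenerate
inputs are rejected loudly (empty sentences, empty batches, non-finite
losses, spans outside hidden states).

## Problem sizes used by the bundled experiments

Chosen as the package's own study conditions:

* **End-to-end learnability** — one noise-free corpus family with three
  entity types and two relation labels; 500 train / 100 validation /
  100 test sentences, ≤30 epochs.  The pipeline reaches micro-F1 ≥ 0.9
  on SP, ET and RE.
* **Forgetting direction** — two corpora with disjoint relation labels
  (Drug/Disease + ADE vs. Drug/Protein + CPR), 120 train / 40 test
  sentences each, one mention per type per sentence, 12 epochs per step,
  no validation selection; sequential continual training is compared with
  the interleaved continual multi-corpora schedule over 5 seeds (3 in the
  acceptance script).
* **Corpus adaptation** — a 100-sentence foreign corpus with 50% lexicon
  overlap and 20% of Drug mentions re-typed.

## Known limitations

* Only the tiny word-level encoder is provided; there is no pretrained
  biomedical language model, so absolute scores on real corpora are out
  of reach by design.
* One SP tag per token: discontinuous, nested or overlapping mentions and
  cross-sentence relations are unsupported.
* Multi-head confidences are raw sigmoid outputs; no calibration is
  attempted, and the cross-head comparison inherits that.
* The single-head baseline loses optimizer state for its output layer on
  expansion (see above).
* Sequence length is limited in practice by the dense n×n attention;
  sentence-level inputs are assumed.
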