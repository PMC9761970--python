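"""Synthetic annotated corpora shaped like drug/disease/protein IE datasets.

Real corpora of this kind (adverse-drug-event, drug–drug-interaction and
chemical–protein corpora) share a structure: each corpus annotates its own
subset of the global entity types {Drug, Disease, Protein} and one or a few
relation labels that hold between typed mention pairs co-occurring in a
sentence.  The generator emulates exactly that structure:

* each entity type has a disjoint surface lexicon of pseudo-words (1–2
  tokens), so typing is learnable from surface form;
* relation presence is signalled lexically — a related sentence carries a
  relation-specific cue connective, an unrelated one a neutral connective —
  mirroring how trigger words carry relations in real text;
* with probability ``relation_probability`` a sentence is "relational" for a
  given label: every admissible typed pair in it is then annotated with that
  relation;
* label noise flips a fraction of mention TYPE labels within the corpus's
  type set (spans stay correct), emulating annotation-guideline deviations
  between corpora.

The module also builds the three training schedules (sequential continual,
pooled multi-corpora, and the interleaved continual multi-corpora schedule
where corpus *i* of *k* is split into *k−i+1* equal parts and part
*t−i+1* joins step *t*).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, EntityMention, RelationInstance, Sentence

__all__ = [
    "SyntheticConfig", "TemplateSet", "SubsetSplit", "TrainingSchedule",
    "ScheduleStep", "generate_corpus", "generate_foreign_corpus",
    "split_subsets", "build_schedule", "default_lexicon",
    "ADMISSIBLE_PAIRS", "GLOBAL_ENTITY_TYPES",
]

GLOBAL_ENTITY_TYPES = ("Drug", "Disease", "Protein")

# which unordered type pair each relation label may hold between
ADMISSIBLE_PAIRS: dict[str, frozenset] = {
    "ADE": frozenset({"Drug", "Disease"}),
    "DDI": frozenset({"Drug"}),          # Drug–Drug: both ends the same type
    "CPR": frozenset({"Drug", "Protein"}),
}

_SUFFIXES = {
    "Drug": ("statin", "azine", "prine", "mycin", "olol", "idine"),
    "Disease": ("itis", "osis", "pathy", "emia", "algia", "oma"),
    "Protein": ("kinase", "ase", "receptor", "globin", "zyme", "ferase"),
}
_STEMS = ("vela", "mori", "cada", "luno", "tera", "pexi", "ralo", "sinu",
          "quive", "zana", "helio", "dromo", "fenta", "gyra", "bruti", "occo",
          "pleni", "xara", "nodi", "vestra")
_MODIFIERS = {
    "Drug": ("oral", "generic"),
    "Disease": ("acute", "chronic"),
    "Protein": ("alpha", "hepatic"),
}

_FILLERS = ("the", "of", "in", "patients", "after", "treatment", "with",
            "a", "was", "observed", "reported", "during", "therapy",
            "following", "cases", "two", "study", "showed", "severe")
_OPENERS = (("we", "report"), ("a", "case", "of"), ("this", "study", "examined"),
            ("clinicians", "noted"))
_CUES = {
    "ADE": ("induced", "caused", "provoked"),
    "DDI": ("potentiated", "antagonized", "augmented"),
    "CPR": ("activated", "inhibited", "phosphorylated"),
}
_NEUTRAL = ("and", "plus", "alongside", "versus")


def default_lexicon(entity_type: str, size: int, rng: np.random.Generator,
                    offset: int = 0) -> list[tuple[str, ...]]:
    """Deterministic pseudo-word lexicon for one type; disjoint across types
    by construction (type-specific suffixes)."""
    suffixes = _SUFFIXES[entity_type]
    surfaces: list[tuple[str, ...]] = []
    i = offset
    while len(surfaces) < size:
        stem = _STEMS[i % len(_STEMS)]
        suf = suffixes[(i // len(_STEMS)) % len(suffixes)]
        word = f"{stem}{suf}" if i < len(_STEMS) * len(_SUFFIXES[entity_type]) \
            else f"{stem}{i}{suf}"
        # ~30% of entries are two-token surfaces (modifier + head)
        if rng.random() < 0.3:
            mod = _MODIFIERS[entity_type][int(rng.integers(len(_MODIFIERS[entity_type])))]
            surfaces.append((mod, word))
        else:
            surfaces.append((word,))
        i += 1
    return surfaces


@dataclass(frozen=True)
class TemplateSet:
    """Surface inventory the generator assembles sentences from."""
    fillers: tuple[str, ...] = _FILLERS
    openers: tuple[tuple[str, ...], ...] = _OPENERS
    cue_words: dict = field(default_factory=lambda: {k: v for k, v in _CUES.items()})
    neutral_words: tuple[str, ...] = _NEUTRAL


@dataclass
class SyntheticConfig:
    corpus_name: str
    entity_type_set: tuple[str, ...]
    relation_labels: tuple[str, ...]          # usually one label per corpus
    n_sentences: int = 100
    lexicon_size: int = 40
    mention_count_dist: dict = field(
        default_factory=lambda: {0: 0.25, 1: 0.6, 2: 0.15})
    relation_probability: float = 0.7
    label_noise_rate: float = 0.0
    templates: TemplateSet = field(default_factory=TemplateSet)
    seed: int = 0
    # surface lexicons belong to the corpus FAMILY, not the sample: train,
    # validation and test splits drawn with different `seed`s share lexicons
    # as long as they share `lexicon_seed`
    lexicon_seed: int = 0

    def __post_init__(self):
        self.entity_type_set = tuple(self.entity_type_set)
        self.relation_labels = (tuple(self.relation_labels)
                                if not isinstance(self.relation_labels, str)
                                else (self.relation_labels,))
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be >= 1")
        if not 0.0 <= self.relation_probability <= 1.0:
            raise ValueError("relation_probability must be in [0,1]")
        if not 0.0 <= self.label_noise_rate <= 1.0:
            raise ValueError("label_noise_rate must be in [0,1]")
        if abs(sum(self.mention_count_dist.values()) - 1.0) > 1e-9:
            raise ValueError("mention_count_dist must sum to 1")
        for lab in self.relation_labels:
            if lab not in ADMISSIBLE_PAIRS:
                raise ValueError(f"unknown relation label {lab!r}")
            need = ADMISSIBLE_PAIRS[lab]
            if not need <= set(self.entity_type_set):
                raise ValueError(
                    f"relation {lab} needs entity types {sorted(need)} in the corpus")


def _admissible(label: str, type_a: str, type_b: str) -> bool:
    need = ADMISSIBLE_PAIRS[label]
    if len(need) == 1:
        (t,) = need
        return type_a == t and type_b == t
    return {type_a, type_b} == set(need)


def generate_corpus(config: SyntheticConfig,
                    lexicons: dict[str, list[tuple[str, ...]]] | None = None) -> Corpus:
    """Build a deterministic synthetic corpus from ``config``.

    ``lexicons`` overrides the default per-type surface lexicons (used by the
    foreign-corpus variant to shift lexical overlap).
    """
    rng = np.random.default_rng(config.seed)
    # separate stream so the noise setting never shifts sentence assembly
    noise_rng = np.random.default_rng(config.seed + 999)
    tpl = config.templates
    if lexicons is None:
        lex_rng = np.random.default_rng(config.lexicon_seed + 10007)
        lexicons = {t: default_lexicon(t, config.lexicon_size, lex_rng)
                    for t in config.entity_type_set}
    for t in config.entity_type_set:
        if not lexicons.get(t):
            raise ValueError(f"empty lexicon for required entity type {t!r}")

    counts = sorted(config.mention_count_dist.items())
    count_vals = np.array([c for c, _ in counts])
    count_probs = np.array([p for _, p in counts])

    sentences, all_mentions, all_relations = [], [], []
    t_counter = 0
    for si in range(config.n_sentences):
        # -- choose mentions ------------------------------------------------
        slots: list[str] = []
        for etype in config.entity_type_set:
            k = int(rng.choice(count_vals, p=count_probs))
            slots.extend([etype] * k)
        rng.shuffle(slots)

        # -- relational decision per label (sentence-level cue) -------------
        relational = {lab: bool(rng.random() < config.relation_probability)
                      for lab in config.relation_labels}

        # -- assemble tokens -------------------------------------------------
        tokens: list[str] = list(tpl.openers[int(rng.integers(len(tpl.openers)))])
        mention_records: list[tuple[int, int, str]] = []   # start, end, type
        connectives: list[str] = [
            tpl.cue_words[lab][int(rng.integers(len(tpl.cue_words[lab])))]
            for lab in config.relation_labels if relational[lab]]
        if not connectives:
            connectives = [tpl.neutral_words[int(rng.integers(len(tpl.neutral_words)))]]
        emitted: set[str] = set()
        for j, etype in enumerate(slots):
            surface = lexicons[etype][int(rng.integers(len(lexicons[etype])))]
            start = len(tokens)
            tokens.extend(surface)
            mention_records.append((start, len(tokens) - 1, etype))
            if j < len(slots) - 1:
                # connective segment between mentions carries the cue(s)
                conn = connectives[j % len(connectives)]
                tokens.append(conn)
                emitted.add(conn)
            else:
                tokens.append(tpl.fillers[int(rng.integers(len(tpl.fillers)))])
        # every active cue must surface, or identical token sequences could
        # carry different gold relations (unlearnable noise)
        for conn in connectives:
            if conn not in emitted:
                tokens.append(conn)
        tokens.append(tpl.fillers[int(rng.integers(len(tpl.fillers)))])

        # -- label noise: flip mention types within the corpus type set ------
        noisy_records = []
        for (start, end, etype) in mention_records:
            flip = noise_rng.random() < config.label_noise_rate
            if flip and len(config.entity_type_set) > 1:
                others = [t for t in config.entity_type_set if t != etype]
                etype = others[int(noise_rng.integers(len(others)))]
            noisy_records.append((start, end, etype))

        mentions = []
        for (start, end, etype) in noisy_records:
            t_counter += 1
            mentions.append(EntityMention(start, end, etype, f"T{t_counter}"))

        # -- relations over admissible co-occurring pairs (true types) -------
        relations = []
        for a in range(len(mentions)):
            for b in range(a + 1, len(mentions)):
                ta = mention_records[a][2]   # relation generation uses the
                tb = mention_records[b][2]   # pre-noise (true) types
                for lab in config.relation_labels:
                    if relational[lab] and _admissible(lab, ta, tb):
                        first, second = sorted((mentions[a], mentions[b]),
                                               key=lambda m: m.start)
                        relations.append(RelationInstance(
                            first.mention_id, second.mention_id, lab))
        sentences.append(Sentence(tuple(tokens), corpus_name=config.corpus_name,
                                  sentence_id=f"s{si}"))
        all_mentions.append(mentions)
        all_relations.append(relations)

    return Corpus(name=config.corpus_name, sentences=sentences,
                  mentions=all_mentions, relations=all_relations)


def generate_foreign_corpus(config: SyntheticConfig, *, lexicon_overlap: float = 0.5,
                            type_remap_fraction: float = 0.0,
                            type_remap: dict[str, str] | None = None,
                            seed_offset: int = 77) -> Corpus:
    """A held-out "foreign" corpus for corpus-adaptation evaluation.

    Emulates a corpus from a different annotation effort: only a fraction of
    each surface lexicon overlaps the base corpus, sentences are built from
    a different seed stream, and a ``type_remap_fraction`` of mentions of the
    remapped types are relabelled (guideline deviation).
    """
    if not 0.0 <= lexicon_overlap <= 1.0:
        raise ValueError("lexicon_overlap must be in [0,1]")
    if not 0.0 <= type_remap_fraction <= 1.0:
        raise ValueError("type_remap_fraction must be in [0,1]")
    rng = np.random.default_rng(config.seed + seed_offset)
    base_lex_rng = np.random.default_rng(config.lexicon_seed + 10007)
    lexicons = {}
    for t in config.entity_type_set:
        base = default_lexicon(t, config.lexicon_size, base_lex_rng)
        n_keep = int(round(lexicon_overlap * len(base)))
        fresh = default_lexicon(t, len(base) - n_keep,
                                np.random.default_rng(config.seed + seed_offset + 13),
                                offset=len(_STEMS) * len(_SUFFIXES[t]) // 2)
        lexicons[t] = base[:n_keep] + fresh

    foreign_cfg = SyntheticConfig(
        corpus_name=config.corpus_name + "_foreign",
        entity_type_set=config.entity_type_set,
        relation_labels=config.relation_labels,
        n_sentences=config.n_sentences,
        lexicon_size=config.lexicon_size,
        mention_count_dist=dict(config.mention_count_dist),
        relation_probability=config.relation_probability,
        label_noise_rate=0.0,
        templates=TemplateSet(openers=(("records", "indicate"), ("notably",),
                                       ("per", "chart", "review"))),
        seed=config.seed + seed_offset,
    )
    corpus = generate_corpus(foreign_cfg, lexicons=lexicons)

    if type_remap_fraction > 0.0:
        remap = type_remap or {}
        if not remap:
            ts = list(config.entity_type_set)
            remap = {ts[0]: ts[1 % len(ts)]}
        new_mentions = []
        for ments in corpus.mentions:
            row = []
            for m in ments:
                if m.type_label in remap and rng.random() < type_remap_fraction:
                    row.append(EntityMention(m.start, m.end, remap[m.type_label],
                                             m.mention_id))
                else:
                    row.append(m)
            new_mentions.append(row)
        corpus = Corpus(name=corpus.name, sentences=list(corpus.sentences),
                        mentions=new_mentions, relations=list(corpus.relations))
    return corpus


# ---------------------------------------------------------------------------
# subset splits and training schedules
# ---------------------------------------------------------------------------

@dataclass
class SubsetSplit:
    parent_name: str
    parts: list[Corpus]

    @property
    def part_sizes(self) -> tuple[int, ...]:
        return tuple(len(p) for p in self.parts)


def split_subsets(corpus: Corpus, k: int, seed: int = 0) -> SubsetSplit:
    """Random near-equal partition: permute sentences, cut into k contiguous
    parts, remainder going to the earliest parts (sizes differ by at most 1)."""
    n = len(corpus)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = np.random.default_rng(seed).permutation(n)
    base, rem = divmod(n, k)
    parts = []
    pos = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        idx = order[pos:pos + size]
        pos += size
        parts.append(Corpus(
            name=corpus.name if k == 1 else f"{corpus.name}_sub{i + 1}",
            sentences=[corpus.sentences[j] for j in idx],
            mentions=[corpus.mentions[j] for j in idx],
            relations=[corpus.relations[j] for j in idx]))
    return SubsetSplit(parent_name=corpus.name, parts=parts)


@dataclass
class ScheduleStep:
    """One training step: a bag of corpus subsets merged into a single pool."""
    name: str
    corpus: Corpus                       # merged, shuffled pool
    sources: list[tuple[str, int]]       # (subset name, n_sentences) provenance


@dataclass
class TrainingSchedule:
    paradigm: str
    steps: list[ScheduleStep]

    def __len__(self):
        return len(self.steps)


def _merge(name: str, corpora: list[Corpus], rng: np.random.Generator | None) -> Corpus:
    sentences, mentions, relations = [], [], []
    for c in corpora:
        sentences.extend(c.sentences)
        mentions.extend(c.mentions)
        relations.extend(c.relations)
    if rng is not None:
        order = rng.permutation(len(sentences))
        sentences = [sentences[i] for i in order]
        mentions = [mentions[i] for i in order]
        relations = [relations[i] for i in order]
    return Corpus(name=name, sentences=sentences, mentions=mentions,
                  relations=relations)


PARADIGMS = ("continual", "multi_corpora", "continual_multi_corpora")


def build_schedule(corpora: list[Corpus], paradigm: str, seed: int = 0) -> TrainingSchedule:
    """Realize one of the three learning paradigms over ordered corpora.

    * ``continual`` — one step per corpus, in order (sequential pipeline).
    * ``multi_corpora`` — a single step pooling all corpora, shuffled.
    * ``continual_multi_corpora`` — k steps; corpus ``i`` is split into
      ``k−i+1`` equal parts and its part ``t−i+1`` joins step ``t``, so each
      later step mixes the remaining parts of earlier corpora with the newly
      introduced one (each subset is used exactly once).
    """
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}")
    if not corpora:
        raise ValueError("at least one corpus is required")
    rng = np.random.default_rng(seed)
    if paradigm == "continual" or len(corpora) == 1:
        steps = [ScheduleStep(name=f"step{i + 1}", corpus=c,
                              sources=[(c.name, len(c))])
                 for i, c in enumerate(corpora)]
        return TrainingSchedule(paradigm=paradigm, steps=steps)
    if paradigm == "multi_corpora":
        merged = _merge("step1", list(corpora), rng)
        return TrainingSchedule(paradigm=paradigm, steps=[
            ScheduleStep(name="step1", corpus=merged,
                         sources=[(c.name, len(c)) for c in corpora])])
    # continual_multi_corpora
    k = len(corpora)
    if k < 2:
        raise ValueError("continual_multi_corpora needs at least two corpora")
    splits = [split_subsets(c, k - i, seed=int(rng.integers(2 ** 31)))
              for i, c in enumerate(corpora)]
    steps = []
    for t in range(k):
        bag = []
        for i in range(t + 1):
            bag.append(splits[i].parts[t - i])
        merged = _merge(f"step{t + 1}", bag, rng)
        steps.append(ScheduleStep(
            name=f"step{t + 1}", corpus=merged,
            sources=[(b.name, len(b)) for b in bag]))
    return TrainingSchedule(paradigm=paradigm, steps=steps)
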