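"""Plain-text standoff reader/writer for annotated corpora.

A corpus on disk is a pair of files sharing a path prefix:

* ``<prefix>.txt`` — one pre-tokenized sentence per line, space-separated
  tokens.
* ``<prefix>.ann`` — annotation records, one per line:

  * ``T<id>\\t<TYPE> <start_tok> <end_tok>\\t<surface>`` — an entity mention.
    ``start_tok``/``end_tok`` are DOCUMENT-GLOBAL token indices (cumulative
    over the ``.txt`` lines), 0-based, inclusive on both ends.  This is a
    token-index dialect of the BRAT standoff format, not character offsets.
  * ``R<id>\\t<LABEL> Arg1:T<i> Arg2:T<j>`` — a binary relation between two
    mentions of the same sentence.

Lines starting with ``#`` are comments; the writer emits a header
documenting the dialect.
"""

from __future__ import annotations

import re
from pathlib import Path

from .corpus import Corpus, CorpusError, EntityMention, RelationInstance, Sentence

__all__ = ["read_corpus", "write_corpus", "StandoffError"]

_HEADER = (
    "# token-index standoff dialect\n"
    "# T<id>\\t<TYPE> <start_tok> <end_tok>\\t<surface>   (document-global token\n"
    "#   indices over the .txt lines, 0-based, inclusive on both ends)\n"
    "# R<id>\\t<LABEL> Arg1:T<i> Arg2:T<j>\n"
)

_T_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_R_RE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)$")


class StandoffError(CorpusError):
    """Malformed standoff record; message carries file, line and reason."""


def _paths(path) -> tuple[Path, Path, str]:
    p = Path(path)
    if p.suffix in (".txt", ".ann"):
        p = p.with_suffix("")
    return p.with_suffix(".txt"), p.with_suffix(".ann"), p.name


def read_corpus(path) -> Corpus:
    """Load a ``.txt``/``.ann`` pair (``path`` may be either file or the prefix)."""
    txt_path, ann_path, name = _paths(path)
    sentences: list[Sentence] = []
    offsets: list[int] = []   # global token offset of each sentence
    total = 0
    with open(txt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            toks = line.split(" ")
            sentences.append(Sentence(tuple(toks), corpus_name=name,
                                      sentence_id=f"s{len(sentences)}"))
            offsets.append(total)
            total += len(toks)

    mentions: list[list[EntityMention]] = [[] for _ in sentences]
    relations: list[list[RelationInstance]] = [[] for _ in sentences]
    mention_sentence: dict[str, int] = {}

    def sent_of(global_idx: int, where: str) -> int:
        for si in range(len(sentences) - 1, -1, -1):
            if offsets[si] <= global_idx:
                return si
        raise StandoffError(f"{ann_path}:{where}: token index {global_idx} out of range")

    if ann_path.exists():
        with open(ann_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                if line.startswith("T"):
                    m = _T_RE.match(line)
                    if not m:
                        raise StandoffError(f"{ann_path}:{lineno}: malformed T record: {line!r}")
                    tid, tlabel, start, end = m.group(1), m.group(2), int(m.group(3)), int(m.group(4))
                    if tid in mention_sentence:
                        raise StandoffError(f"{ann_path}:{lineno}: duplicate id {tid}")
                    si = sent_of(start, str(lineno))
                    local_start = start - offsets[si]
                    local_end = end - offsets[si]
                    if local_end >= sentences[si].n or local_end < local_start:
                        raise StandoffError(
                            f"{ann_path}:{lineno}: span ({start},{end}) does not fit "
                            f"sentence {si} (length {sentences[si].n})")
                    mentions[si].append(EntityMention(local_start, local_end, tlabel, tid))
                    mention_sentence[tid] = si
                elif line.startswith("R"):
                    m = _R_RE.match(line)
                    if not m:
                        raise StandoffError(f"{ann_path}:{lineno}: malformed R record: {line!r}")
                    _, rlabel, a, b = m.groups()
                    for mid in (a, b):
                        if mid not in mention_sentence:
                            raise StandoffError(
                                f"{ann_path}:{lineno}: relation references missing id {mid}")
                    if mention_sentence[a] != mention_sentence[b]:
                        raise StandoffError(
                            f"{ann_path}:{lineno}: relation crosses sentences "
                            f"({a} in s{mention_sentence[a]}, {b} in s{mention_sentence[b]})")
                    relations[mention_sentence[a]].append(RelationInstance(a, b, rlabel))
                else:
                    raise StandoffError(f"{ann_path}:{lineno}: unrecognized record: {line!r}")

    return Corpus(name=name, sentences=sentences, mentions=mentions, relations=relations)


def write_corpus(corpus: Corpus, path) -> tuple[Path, Path]:
    """Write ``<prefix>.txt`` and ``<prefix>.ann`` with deterministic ordering.

    Records are ordered by sentence, then mention start, then relation
    declaration order; two writes of an equal corpus are byte-identical.
    """
    txt_path, ann_path, _ = _paths(path)
    txt_path.parent.mkdir(parents=True, exist_ok=True)

    with open(txt_path, "w", encoding="utf-8") as fh:
        for sent in corpus.sentences:
            fh.write(" ".join(sent.tokens) + "\n")

    offsets = []
    total = 0
    for sent in corpus.sentences:
        offsets.append(total)
        total += sent.n

    tid_map: dict[tuple[int, str], str] = {}
    t_lines: list[str] = []
    r_lines: list[str] = []
    t_counter = r_counter = 0
    for si, (sent, ments, rels) in enumerate(corpus.annotated()):
        for m in sorted(ments, key=lambda m: (m.start, m.end)):
            t_counter += 1
            tid = f"T{t_counter}"
            tid_map[(si, m.mention_id)] = tid
            surface = " ".join(sent.tokens[m.start:m.end + 1])
            t_lines.append(f"{tid}\t{m.type_label} {offsets[si] + m.start} "
                           f"{offsets[si] + m.end}\t{surface}")
        for r in rels:
            r_counter += 1
            r_lines.append(f"R{r_counter}\t{r.label} "
                           f"Arg1:{tid_map[(si, r.mention_a)]} "
                           f"Arg2:{tid_map[(si, r.mention_b)]}")

    with open(ann_path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER)
        for line in t_lines + r_lines:
            fh.write(line + "\n")
    return txt_path, ann_path
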