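"""Character-level tagged corpora: CoNLL-style I/O, BIO/span conversion, padding.

The tagger works on one token per unicode code point (Chinese clinical text is
labelled at the character level). Entity spans use the 0-based half-open
convention ``[start, end)`` everywhere.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Reserved padding character; never appears in real or synthetic text.
PAD_CHAR = "␀"  # ␀ SYMBOL FOR NULL

#: Chinese full stop used as the sentence delimiter in clinical records.
FULL_STOP = "。"  # 。

_BIO_RE = re.compile(r"^(O|[BI]-\S+)$")


class CorpusFormatError(ValueError):
    """Malformed corpus file (bad column count, bad tag grammar)."""


@dataclass
class TaggedSentence:
    """A sentence of characters with aligned BIO tags, segmentation labels
    (1 = token is part of an entity) and an attention mask (1 = real token,
    0 = padding)."""

    chars: list[str]
    tags: list[str]
    seg_labels: list[int] = field(default_factory=list)
    attention_mask: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seg_labels:
            self.seg_labels = bio_to_segmentation(self.tags)
        if not self.attention_mask:
            self.attention_mask = [1] * len(self.chars)
        self.validate()

    def validate(self) -> None:
        n = len(self.chars)
        if not (len(self.tags) == len(self.seg_labels) == len(self.attention_mask) == n):
            raise ValueError(
                f"misaligned sentence: chars={n} tags={len(self.tags)} "
                f"seg={len(self.seg_labels)} mask={len(self.attention_mask)}"
            )
        for t in self.tags:
            if not _BIO_RE.match(t):
                raise CorpusFormatError(f"tag {t!r} does not match the BIO grammar")
        for s, t in zip(self.seg_labels, self.tags):
            if s != (0 if t == "O" else 1):
                raise ValueError("seg_labels inconsistent with tags")

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def text(self) -> str:
        return "".join(self.chars)

    def entities(self) -> list["EntityMention"]:
        return bio_to_entities(self.tags)


@dataclass(frozen=True, order=True)
class EntityMention:
    """A typed entity span: ``chars[start:end]`` has type ``etype``."""

    etype: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")
        if len(self.surface) != self.end - self.start:
            raise ValueError("surface length does not match span width")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.etype, self.start, self.end)


@dataclass
class Corpus:
    sentences: list[TaggedSentence]
    label_inventory: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_inventory:
            seen: dict[str, None] = {}
            for s in self.sentences:
                for t in s.tags:
                    if t != "O":
                        seen.setdefault(t.split("-", 1)[1], None)
            self.label_inventory = list(seen)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)


# ---------------------------------------------------------------------------
# label-scheme conversions


def bio_to_segmentation(tags: Sequence[str]) -> list[int]:
    """Binary segmentation labels: 1 wherever the tag is not O."""
    for t in tags:
        if not _BIO_RE.match(t):
            raise CorpusFormatError(f"tag {t!r} does not match the BIO grammar")
    return [0 if t == "O" else 1 for t in tags]


def entities_to_bio(length: int, mentions: Iterable[EntityMention]) -> list[str]:
    """Render non-overlapping mentions as a BIO tag sequence of ``length``."""
    tags = ["O"] * length
    occupied = [False] * length
    for m in sorted(mentions, key=lambda m: m.start):
        if m.end > length:
            raise ValueError(f"mention {m} exceeds sentence length {length}")
        if any(occupied[m.start : m.end]):
            raise ValueError(f"overlapping mention {m}")
        for i in range(m.start, m.end):
            occupied[i] = True
            tags[i] = ("B-" if i == m.start else "I-") + m.etype
    return tags


def bio_to_entities(tags: Sequence[str]) -> list[EntityMention]:
    """Extract typed spans from BIO tags.

    A stray ``I-x`` that does not continue a ``B-x``/``I-x`` run of the same
    type opens a new mention (conlleval-style repair), so the function is
    total on anything an unconstrained decoder can emit.
    """
    mentions: list[EntityMention] = []
    start = None
    cur_type = None
    for i, t in enumerate(tags):
        if not _BIO_RE.match(t):
            raise CorpusFormatError(f"tag {t!r} does not match the BIO grammar")
        if t == "O":
            marker, etype = "O", None
        else:
            marker, etype = t.split("-", 1)
        continues = marker == "I" and cur_type == etype and start is not None
        if start is not None and not continues:
            mentions.append(EntityMention(cur_type, start, i, "?" * (i - start)))
            start, cur_type = None, None
        if marker == "B" or (marker == "I" and not continues):
            start, cur_type = i, etype
    if start is not None:
        mentions.append(EntityMention(cur_type, start, len(tags), "?" * (len(tags) - start)))
    return mentions


def sentence_entities(sentence: TaggedSentence) -> list[EntityMention]:
    """Mentions of a sentence with real surfaces filled in."""
    out = []
    for m in bio_to_entities(sentence.tags):
        out.append(EntityMention(m.etype, m.start, m.end, sentence.text[m.start : m.end]))
    return out


# ---------------------------------------------------------------------------
# file I/O (two-column CoNLL dialect: "<char>\t<tag>", blank line between
# sentences; an optional third column carries predicted tags)


def read_conll(path, use_predictions: bool = False) -> Corpus:
    """Read a 2- or 3-column file; with ``use_predictions`` the last column
    (predicted tags, when present) populates the tag field instead of the
    gold column."""
    sentences: list[TaggedSentence] = []
    chars: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        if chars:
            sentences.append(TaggedSentence(chars.copy(), tags.copy()))
            chars.clear()
            tags.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split("\t")
            if len(cols) not in (2, 3):
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(cols)}"
                )
            ch = cols[0]
            tag = cols[-1] if use_predictions else cols[1]
            if len(ch) != 1:
                raise CorpusFormatError(
                    f"{path}:{lineno}: token column must be a single character, got {ch!r}"
                )
            if not _BIO_RE.match(tag):
                raise CorpusFormatError(f"{path}:{lineno}: tag {tag!r} violates BIO grammar")
            chars.append(ch)
            tags.append(tag)
    flush()
    return Corpus(sentences)


def write_conll(corpus: Corpus, path, predictions: list[list[str]] | None = None) -> None:
    """Write the dialect ``read_conll`` accepts; with ``predictions`` a third
    column of predicted tags is added."""
    if predictions is not None and len(predictions) != len(corpus.sentences):
        raise ValueError("predictions misaligned with corpus")
    with open(path, "w", encoding="utf-8") as fh:
        for i, sent in enumerate(corpus.sentences):
            for j, (ch, tag) in enumerate(zip(sent.chars, sent.tags)):
                if predictions is not None:
                    fh.write(f"{ch}\t{tag}\t{predictions[i][j]}\n")
                else:
                    fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")


def split_sentences(text: str) -> list[str]:
    """Split after every Chinese full stop 。, keeping the delimiter; the
    concatenation of the output equals the input."""
    out: list[str] = []
    buf: list[str] = []
    for ch in text:
        buf.append(ch)
        if ch == FULL_STOP:
            out.append("".join(buf))
            buf.clear()
    if buf:
        out.append("".join(buf))
    return out


def pad_truncate(sentence: TaggedSentence, max_len: int) -> TaggedSentence:
    """Pad with ``PAD_CHAR``/O/mask-0 to exactly ``max_len``; longer sentences
    are truncated (with a warning) at ``max_len``."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    n = len(sentence)
    if n > max_len:
        logger.warning("truncating sentence of length %d to %d", n, max_len)
        return TaggedSentence(
            sentence.chars[:max_len],
            sentence.tags[:max_len],
            sentence.seg_labels[:max_len],
            sentence.attention_mask[:max_len],
        )
    pad = max_len - n
    return TaggedSentence(
        sentence.chars + [PAD_CHAR] * pad,
        sentence.tags + ["O"] * pad,
        sentence.seg_labels + [0] * pad,
        sentence.attention_mask + [0] * pad,
    )
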