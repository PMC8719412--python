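"""Synthetic corpora, gazetteers and radical tables for hermetic testing.

The generator emulates the *structure* of Chinese clinical NER data — five
entity types, an external dictionary of surface forms 2-6 characters long,
character radicals correlated with entity type, and a controlled share of
rare/unseen entities in the test split — without any linguistic content.
Characters are private-use unicode code points so synthetic text can never
collide with real text.

Key construction guarantees:

* no dictionary surface is a substring of another (so a planted mention is
  matched by exactly its own span, never an inner window);
* background characters never accidentally spell a dictionary surface
  (violating windows are locally resampled), so planted mentions are the
  unique gold standard;
* every surface assigned a training occurrence count k in {0,1,2,3} appears
  exactly k times in the training split, giving exact control over the
  rare-entity buckets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, EntityMention, TaggedSentence, entities_to_bio
from .features import EntityDictionary, RadicalTable, TypeCodeScheme

logger = logging.getLogger(__name__)

_ALPHABET_BASE = 0xE000  # private-use area

MIN_SURFACE_LEN = 2
MAX_SURFACE_LEN = 6


@dataclass
class SynthSpec:
    """Knobs of the synthetic study conditions.

    ``rare_fraction`` is the share of test mentions drawn from the rare pool
    (training occurrence count 0-3); ``dict_coverage`` the fraction of the
    surface inventory present in the emitted feature dictionary;
    ``char_affinity`` how strongly a type's surfaces prefer that type's
    character block (keeps radicals informative without separating entity
    characters from background); ``radical_enrichment`` the probability that
    a character takes its block's radical rather than a random one.
    """

    alphabet_size: int = 60
    n_types: int = 5
    dict_size: int = 80
    sentences: int = 200
    test_sentences: int = 50
    mean_sentence_length: float = 30.0
    entity_rate: float = 2.0
    rare_fraction: float = 0.3
    dict_coverage: float = 1.0
    char_affinity: float = 0.5
    radical_enrichment: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rare_fraction", "dict_coverage", "char_affinity", "radical_enrichment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("alphabet_size", "n_types", "sentences", "test_sentences"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dict_size < 0 or self.entity_rate < 0 or self.mean_sentence_length <= 0:
            raise ValueError("invalid size/rate")
        if self.n_types > 7:
            raise ValueError("a 3-bit code scheme supports at most 7 types")

    @property
    def alphabet(self) -> list[str]:
        return [chr(_ALPHABET_BASE + k) for k in range(self.alphabet_size)]

    def block_of(self, char: str) -> int:
        """The type block a character belongs to (contiguous partition)."""
        idx = ord(char) - _ALPHABET_BASE
        return min(idx * self.n_types // self.alphabet_size, self.n_types - 1)

    @property
    def type_names(self) -> list[str]:
        return [f"type{k + 1}" for k in range(self.n_types)]


def gen_dictionary(spec: SynthSpec) -> tuple[EntityDictionary, TypeCodeScheme]:
    """Surface inventory of ``dict_size`` unique, substring-free surfaces of
    length 2-6, types assigned round-robin; distinct nonzero 3-bit codes."""
    rng = np.random.default_rng(spec.seed)
    alphabet = spec.alphabet
    blocks = [[c for c in alphabet if spec.block_of(c) == k] for k in range(spec.n_types)]
    entries: dict[str, str] = {}
    surfaces: list[str] = []
    for j in range(spec.dict_size):
        k = j % spec.n_types
        placed = False
        for _ in range(2000):
            n = int(rng.integers(MIN_SURFACE_LEN, MAX_SURFACE_LEN + 1))
            chars = [
                blocks[k][rng.integers(len(blocks[k]))]
                if rng.random() < spec.char_affinity
                else alphabet[rng.integers(len(alphabet))]
                for _ in range(n)
            ]
            s = "".join(chars)
            if s in entries:
                continue
            if any(s in t or t in s for t in surfaces):
                continue
            entries[s] = spec.type_names[k]
            surfaces.append(s)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"alphabet of size {spec.alphabet_size} cannot host {spec.dict_size} "
                "substring-free surfaces"
            )
    scheme = TypeCodeScheme.for_types(spec.type_names)
    return EntityDictionary(entries, spec.type_names), scheme


def subsample_dictionary(
    full: EntityDictionary, coverage: float, seed: int
) -> EntityDictionary:
    """The feature-time gazetteer: a random ``coverage`` fraction of the full
    surface inventory (coverage 1 returns a copy of the full dictionary)."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    surfaces = sorted(full.entries)
    rng = np.random.default_rng(seed)
    keep_n = int(round(coverage * len(surfaces)))
    keep = set(rng.permutation(surfaces)[:keep_n]) if surfaces else set()
    return EntityDictionary(
        {s: t for s, t in full.entries.items() if s in keep}, list(full.type_order)
    )


def _clean_background(chars: list[str], planted: list[EntityMention], full: EntityDictionary,
                      alphabet: list[str], rng: np.random.Generator) -> None:
    """Resample background characters until no window spells a dictionary
    surface other than a planted span."""
    planted_spans = {(m.start, m.end) for m in planted}
    in_entity = [False] * len(chars)
    for m in planted:
        for i in range(m.start, m.end):
            in_entity[i] = True
    for _ in range(200):
        dirty = False
        for n in range(MIN_SURFACE_LEN, MAX_SURFACE_LEN + 1):
            for s in range(0, len(chars) - n + 1):
                if (s, s + n) in planted_spans:
                    continue
                if "".join(chars[s : s + n]) in full.entries:
                    bg = [i for i in range(s, s + n) if not in_entity[i]]
                    if not bg:
                        raise RuntimeError("adjacent planted surfaces spell a third surface")
                    for i in bg:
                        chars[i] = alphabet[rng.integers(len(alphabet))]
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("could not clean background text of accidental surfaces")


def _build_sentence(
    length: int,
    surfaces: list[str],
    full: EntityDictionary,
    alphabet: list[str],
    rng: np.random.Generator,
) -> TaggedSentence:
    """A sentence of ``length`` background chars with ``surfaces`` planted at
    random non-overlapping positions, one background char between mentions."""
    chars = [alphabet[rng.integers(len(alphabet))] for _ in range(length)]
    mentions: list[EntityMention] = []
    if surfaces:
        order = list(rng.permutation(len(surfaces)))
        total = sum(len(surfaces[i]) for i in order)
        slack = length - total - (len(surfaces) - 1)
        if slack < 0:
            raise ValueError("entities do not fit in the sentence")
        cuts = np.sort(rng.integers(0, slack + 1, size=len(surfaces)))
        pos = 0
        prev_cut = 0
        cursor = 0
        for j, i in enumerate(order):
            gap = int(cuts[j]) - prev_cut + (1 if j > 0 else 0)
            prev_cut = int(cuts[j])
            cursor += gap
            s = surfaces[i]
            chars[cursor : cursor + len(s)] = list(s)
            mentions.append(EntityMention(full.entries[s], cursor, cursor + len(s), s))
            cursor += len(s)
    _clean_background(chars, mentions, full, alphabet, rng)
    tags = entities_to_bio(length, mentions)
    return TaggedSentence(chars, tags)


def _sentence_lengths(spec: SynthSpec, count: int, rng: np.random.Generator) -> list[int]:
    lo = max(8, MAX_SURFACE_LEN + 2)
    return [max(lo, int(rng.poisson(spec.mean_sentence_length))) for _ in range(count)]


def gen_corpus(spec: SynthSpec, full: EntityDictionary) -> tuple[Corpus, Corpus]:
    """Train and test corpora with planted mentions and controlled rarity.

    Forty percent of the surface inventory forms the rare pool, cycled
    through target training counts 0/1/2/3; the rest is the common pool.
    Test mentions come from the rare pool with probability ``rare_fraction``.
    """
    if spec.entity_rate > 0 and len(full) == 0:
        raise ValueError("entity_rate > 0 requires a non-empty dictionary")
    rng = np.random.default_rng(spec.seed + 1)
    alphabet = spec.alphabet
    surfaces = sorted(full.entries)
    rng.shuffle(surfaces)
    n_rare = int(round(0.4 * len(surfaces)))
    rare_pool = surfaces[:n_rare]
    common_pool = surfaces[n_rare:] or surfaces
    target_count = {s: k % 4 for k, s in enumerate(rare_pool)}

    # --- train ---
    lengths = _sentence_lengths(spec, spec.sentences, rng)
    per_sent = [int(rng.poisson(spec.entity_rate)) if len(full) else 0 for _ in lengths]
    forced = [s for s, k in target_count.items() for _ in range(k)]
    rng.shuffle(forced)
    total = sum(per_sent)
    if len(forced) > total:
        logger.warning("rare-pool quota (%d) exceeds mention budget (%d); truncating", len(forced), total)
        forced = forced[:total]
    fills = [common_pool[rng.integers(len(common_pool))] for _ in range(total - len(forced))]
    stream = forced + fills
    rng.shuffle(stream)
    train_sents = []
    cursor = 0
    for length, k in zip(lengths, per_sent):
        chosen: list[str] = []
        budget = length
        while len(chosen) < k and cursor < len(stream):
            s = stream[cursor]
            need = len(s) + (1 if chosen else 0)
            if need > budget:
                break
            chosen.append(s)
            budget -= need
            cursor += 1
        train_sents.append(_build_sentence(length, chosen, full, alphabet, rng))
    leftovers = stream[cursor:]
    for s in leftovers:  # guarantee every forced occurrence is planted
        length = max(len(s) + 4, int(rng.poisson(spec.mean_sentence_length)))
        train_sents.append(_build_sentence(length, [s], full, alphabet, rng))
    if leftovers:
        logger.info("appended %d overflow sentences to place forced rare mentions", len(leftovers))

    # --- test ---
    lengths = _sentence_lengths(spec, spec.test_sentences, rng)
    test_sents = []
    for length in lengths:
        k = int(rng.poisson(spec.entity_rate)) if len(full) else 0
        chosen = []
        budget = length
        for _ in range(k):
            pool = rare_pool if (rare_pool and rng.random() < spec.rare_fraction) else common_pool
            s = pool[rng.integers(len(pool))]
            need = len(s) + (1 if chosen else 0)
            if need > budget:
                continue
            chosen.append(s)
            budget -= need
        test_sents.append(_build_sentence(length, chosen, full, alphabet, rng))

    inventory = list(full.type_order)
    return Corpus(train_sents, inventory), Corpus(test_sents, inventory)


def gen_radicals(spec: SynthSpec) -> RadicalTable:
    """Map the synthetic alphabet to a small radical inventory such that
    characters of the same type block share a radical with probability
    ``radical_enrichment`` (0 = independent, 1 = perfectly pure)."""
    rng = np.random.default_rng(spec.seed + 2)
    n_rad = spec.n_types + 1
    raw: dict[str, int] = {}
    for c in spec.alphabet:
        if rng.random() < spec.radical_enrichment:
            raw[c] = spec.block_of(c)
        else:
            raw[c] = int(rng.integers(n_rad))
    # compress ids so the space is contiguous, unknown id last
    used = sorted(set(raw.values()))
    remap = {r: i for i, r in enumerate(used)}
    return RadicalTable({c: remap[r] for c, r in raw.items()}, unk_radical=len(used))


def radical_purity(spec: SynthSpec, table: RadicalTable) -> float:
    """Mean over type blocks of the modal-radical fraction of the block's
    characters — 1.0 at enrichment 1, near 1/(n_types+1) at enrichment 0."""
    purities = []
    for k in range(spec.n_types):
        rads = [table.mapping[c] for c in spec.alphabet if spec.block_of(c) == k]
        if not rads:
            continue
        counts = np.bincount(rads)
        purities.append(counts.max() / len(rads))
    return float(np.mean(purities))


def write_synthetic(spec: SynthSpec, out_dir) -> dict[str, str]:
    """Materialize train/test CoNLL files, dictionary TSV (coverage applied),
    radical TSV and the 3-bit scheme JSON under ``out_dir``."""
    import json
    import os

    from .corpus import write_conll

    os.makedirs(out_dir, exist_ok=True)
    full, scheme = gen_dictionary(spec)
    train, test = gen_corpus(spec, full)
    feature_dict = subsample_dictionary(full, spec.dict_coverage, spec.seed + 3)
    radicals = gen_radicals(spec)
    paths = {
        "train": os.path.join(out_dir, "train.conll"),
        "test": os.path.join(out_dir, "test.conll"),
        "dictionary": os.path.join(out_dir, "dictionary.tsv"),
        "radicals": os.path.join(out_dir, "radicals.tsv"),
        "scheme": os.path.join(out_dir, "scheme.json"),
    }
    write_conll(train, paths["train"])
    write_conll(test, paths["test"])
    with open(paths["dictionary"], "w", encoding="utf-8") as fh:
        for s in sorted(feature_dict.entries):
            fh.write(f"{s}\t{feature_dict.entries[s]}\n")
    with open(paths["radicals"], "w", encoding="utf-8") as fh:
        for c in spec.alphabet:
            fh.write(f"{c}\trad{radicals.mapping[c]}\n")
    with open(paths["scheme"], "w", encoding="utf-8") as fh:
        json.dump({t: list(c) for t, c in scheme.codes.items()}, fh, ensure_ascii=False)
    return paths
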