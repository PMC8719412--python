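"""Per-character input features.

Three feature families are concatenated for every character position:

* a trainable character embedding (default dim 100; a pretrained table can be
  plugged in),
* a trainable radical embedding (default dim 50) looked up through an external
  character-to-radical table,
* a fixed 30-dimensional binary gazetteer code built from ten n-gram windows
  matched exactly against an external entity dictionary.

The gazetteer code uses five window sizes (2..6 characters); for each size one
window ends at position i and one starts at it, giving ten text fragments per
position. Each fragment that exactly equals a dictionary surface contributes
the 3-bit code of that surface's entity type; unmatched or out-of-bounds
fragments contribute (0, 0, 0). The concatenation of the ten 3-bit codes is
the 30-dim vector, carrying both entity-type and boundary information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

Code = tuple[int, int, int]

#: The ten (start_offset, end_offset) windows relative to position i, in fixed
#: slot order: for each n in 2..6 the left fragment x_{i-n+1}..x_i then the
#: right fragment x_i..x_{i+n-1}.
NGRAM_TEMPLATES: tuple[tuple[int, int], ...] = tuple(
    (off, off + n) for n in range(2, 7) for off in (1 - n, 0)
)

N_TEMPLATES = len(NGRAM_TEMPLATES)  # 10
DICT_FEATURE_DIM = 3 * N_TEMPLATES  # 30

#: Published 3-bit type codes for the two benchmark inventories.
CCKS2017_CODES: dict[str, Code] = {
    "disease": (0, 0, 1),
    "anatomy": (0, 1, 0),
    "symptom": (0, 1, 1),
    "exam": (1, 0, 0),
    "treatment": (1, 0, 1),
}
CCKS2018_CODES: dict[str, Code] = {
    "drug": (0, 0, 1),
    "anatomy": (0, 1, 0),
    "indep_symptom": (0, 1, 1),
    "desc_symptom": (1, 0, 0),
    "operation": (1, 0, 1),
}


@dataclass
class TypeCodeScheme:
    """Assignment of a distinct nonzero 3-bit code to every entity type;
    (0,0,0) is reserved for 'no entity here'."""

    codes: dict[str, Code]
    none_code: Code = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.none_code != (0, 0, 0):
            raise ValueError("none_code must be (0,0,0)")
        seen = set()
        for t, c in self.codes.items():
            if len(c) != 3 or any(b not in (0, 1) for b in c):
                raise ValueError(f"code for {t!r} is not a 3-bit tuple: {c}")
            if c == self.none_code:
                raise ValueError(f"type {t!r} assigned the reserved all-zero code")
            if c in seen:
                raise ValueError(f"duplicate code {c}")
            seen.add(c)

    @classmethod
    def for_types(cls, types: list[str]) -> "TypeCodeScheme":
        """Assign the 3-bit codes 1..7 (binary) to up to 7 types in order."""
        if len(types) > 7:
            raise ValueError("a 3-bit scheme can encode at most 7 types")
        codes = {
            t: ((k >> 2) & 1, (k >> 1) & 1, k & 1)
            for k, t in enumerate(types, start=1)
        }
        return cls(codes)


@dataclass
class EntityDictionary:
    """Exact-match gazetteer: surface string -> entity type.

    ``type_order`` fixes the priority used when one surface is claimed by
    several types (highest priority first)."""

    entries: dict[str, str]
    type_order: list[str]

    def __post_init__(self) -> None:
        for s, t in self.entries.items():
            if not s:
                raise ValueError("empty surface string in dictionary")
            if t not in self.type_order:
                raise ValueError(f"type {t!r} of {s!r} missing from type_order")

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, surface: str) -> str | None:
        return self.entries.get(surface)


@dataclass
class RadicalTable:
    """Character -> radical-id map over a contiguous 0-based id space; unknown
    characters map to the reserved ``unk_radical`` id."""

    mapping: dict[str, int]
    unk_radical: int

    def __post_init__(self) -> None:
        ids = set(self.mapping.values()) | {self.unk_radical}
        if ids != set(range(len(ids))):
            raise ValueError("radical ids must form a contiguous 0-based space")

    @property
    def n_radicals(self) -> int:
        """Size of the radical id space, unknown id included."""
        return len(set(self.mapping.values()) | {self.unk_radical})


@dataclass
class FeatureConfig:
    char_dim: int = 100
    radical_dim: int = 50
    dict_dim: int = DICT_FEATURE_DIM

    def __post_init__(self) -> None:
        if self.char_dim <= 0 or self.radical_dim <= 0:
            raise ValueError("embedding dims must be positive")
        if self.dict_dim != DICT_FEATURE_DIM:
            raise ValueError(f"dict_dim is fixed at {DICT_FEATURE_DIM}")

    @property
    def input_dim(self) -> int:
        return self.char_dim + self.radical_dim + self.dict_dim


# ---------------------------------------------------------------------------
# loaders


def load_dictionary(path, type_order: list[str]) -> EntityDictionary:
    """Read a two-column TSV ``surface<TAB>type``; duplicate surfaces with
    conflicting types are resolved by ``type_order`` priority (logged)."""
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            surface, etype = cols
            if etype not in type_order:
                raise ValueError(f"{path}:{lineno}: unknown entity type {etype!r}")
            if surface in entries and entries[surface] != etype:
                keep = min(entries[surface], etype, key=type_order.index)
                logger.warning(
                    "surface %r claimed by %r and %r; keeping %r by priority",
                    surface, entries[surface], etype, keep,
                )
                entries[surface] = keep
            else:
                entries[surface] = etype
    return EntityDictionary(entries, list(type_order))


def load_radicals(path) -> RadicalTable:
    """Read a two-column TSV ``char<TAB>radical`` and index the radicals in
    first-appearance order; the last id is reserved for unknown characters."""
    raw: dict[str, str] = {}
    radical_ids: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            ch, rad = cols
            raw[ch] = rad
            radical_ids.setdefault(rad, len(radical_ids))
    unk = len(radical_ids)
    return RadicalTable({ch: radical_ids[r] for ch, r in raw.items()}, unk_radical=unk)


# ---------------------------------------------------------------------------
# encoding


def fragments_at(chars, i: int) -> list[str | None]:
    """The ten n-gram fragments around position ``i`` in fixed slot order;
    a window crossing the sentence boundary yields None."""
    n = len(chars)
    if not 0 <= i < n:
        raise IndexError(f"position {i} out of range for sentence of length {n}")
    text = "".join(chars)
    out: list[str | None] = []
    for a, b in NGRAM_TEMPLATES:
        lo, hi = i + a, i + b
        out.append(text[lo:hi] if lo >= 0 and hi <= n else None)
    return out


def encode_position(chars, i: int, gazetteer: EntityDictionary, scheme: TypeCodeScheme) -> np.ndarray:
    """The 30-dim binary gazetteer code for position ``i``: ten 3-bit slots,
    one per n-gram fragment, each the code of the exactly matching dictionary
    type or (0,0,0)."""
    vec = np.zeros(DICT_FEATURE_DIM, dtype=np.float64)
    for slot, frag in enumerate(fragments_at(chars, i)):
        if frag is None:
            continue
        etype = gazetteer.lookup(frag)
        if etype is None:
            continue
        vec[3 * slot : 3 * slot + 3] = scheme.codes[etype]
    return vec


def encode_sentence_dict(chars, gazetteer: EntityDictionary, scheme: TypeCodeScheme) -> np.ndarray:
    """Row i is ``encode_position(chars, i, ...)``; shape (len, 30)."""
    if len(chars) == 0:
        raise ValueError("empty sentence")
    return np.stack([encode_position(chars, i, gazetteer, scheme) for i in range(len(chars))])


def radical_of(char: str, table: RadicalTable) -> int:
    """Radical id of ``char``, or the reserved unknown id; total on unicode."""
    return table.mapping.get(char, table.unk_radical)


def init_embedding(vocab_size: int, dim: int, rng_seed: int) -> np.ndarray:
    """Random embedding table with entries i.i.d. uniform on
    [-sqrt(3/dim), +sqrt(3/dim)] — variance 1/dim — reproducible by seed."""
    if vocab_size <= 0 or dim <= 0:
        raise ValueError("vocab_size and dim must be positive")
    bound = np.sqrt(3.0 / dim)
    rng = np.random.default_rng(rng_seed)
    return rng.uniform(-bound, bound, size=(vocab_size, dim))


def assemble_input(
    char_ids: np.ndarray,
    radical_ids: np.ndarray,
    dict_features: np.ndarray,
    char_embeddings: np.ndarray,
    radical_embeddings: np.ndarray,
) -> np.ndarray:
    """Concatenate per position: character embedding ⊕ radical embedding ⊕
    30-dim gazetteer code. Shape (len, char_dim + radical_dim + 30)."""
    n = dict_features.shape[0]
    if len(char_ids) != n or len(radical_ids) != n:
        raise ValueError("feature blocks have mismatched lengths")
    return np.concatenate(
        [char_embeddings[char_ids], radical_embeddings[radical_ids], dict_features], axis=1
    )
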