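"""Entity-level scoring with exact span+type matching.

A predicted mention counts as a true positive iff its (type, start, end)
triple equals a gold mention in the same sentence.  F is the harmonic mean
2*P*R/(P+R).  Cells with an empty denominator are reported as 0.

The rare-entity report stratifies test-set recall by how often each gold
mention's (surface, type) pair occurs in the *training* set: buckets 0
(unseen), 1, 2 and 3; mentions occurring four or more times are outside the
report.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .corpus import Corpus, EntityMention, sentence_entities

logger = logging.getLogger(__name__)

MentionSets = list[list[EntityMention]]

RARE_BUCKETS = (0, 1, 2, 3)


@dataclass
class PRF:
    precision: float
    recall: float
    fmeasure: float
    tp: int
    fp: int
    fn: int

    @property
    def support(self) -> int:
        return self.tp + self.fn


@dataclass
class EvalReport:
    overall: PRF
    per_type: dict[str, PRF]
    macro_precision: float
    macro_recall: float
    macro_fmeasure: float
    rare_recall: dict[int, float] = field(default_factory=dict)
    rare_support: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        def cell(p: PRF) -> dict:
            return {
                "precision": p.precision,
                "recall": p.recall,
                "fmeasure": p.fmeasure,
                "support": p.support,
            }

        return {
            "overall": cell(self.overall),
            "per_type": {t: cell(p) for t, p in self.per_type.items()},
            "macro_average": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "fmeasure": self.macro_fmeasure,
            },
            "rare_recall": {str(k): v for k, v in self.rare_recall.items()},
            "rare_support": {str(k): v for k, v in self.rare_support.items()},
        }


def fmeasure(precision: float, recall: float) -> float:
    """Harmonic mean 2*R*P/(R+P); 0 when both are 0."""
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def _prf(tp: int, fp: int, fn: int) -> PRF:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    if tp + fp == 0 or tp + fn == 0:
        logger.debug("empty denominator in P/R; reporting 0")
    return PRF(p, r, fmeasure(p, r), tp, fp, fn)


def corpus_mentions(corpus: Corpus) -> MentionSets:
    return [sentence_entities(s) for s in corpus]


def entity_prf(gold: MentionSets, pred: MentionSets) -> EvalReport:
    """Exact-match entity-level precision/recall/F, overall and per type.

    Overall numbers are micro-averaged; the macro average over types is also
    reported.
    """
    if len(gold) != len(pred):
        raise ValueError(f"gold has {len(gold)} sentences, pred has {len(pred)}")
    tp: Counter[str] = Counter()
    fp: Counter[str] = Counter()
    fn: Counter[str] = Counter()
    types: dict[str, None] = {}
    for g_sent, p_sent in zip(gold, pred):
        g_keys = {m.key for m in g_sent}
        p_keys = {m.key for m in p_sent}
        for m in g_sent:
            types.setdefault(m.etype, None)
        for m in p_sent:
            types.setdefault(m.etype, None)
        for k in p_keys:
            (tp if k in g_keys else fp)[k[0]] += 1
        for k in g_keys - p_keys:
            fn[k[0]] += 1
    per_type = {t: _prf(tp[t], fp[t], fn[t]) for t in types}
    overall = _prf(sum(tp.values()), sum(fp.values()), sum(fn.values()))
    if per_type:
        mp = sum(c.precision for c in per_type.values()) / len(per_type)
        mr = sum(c.recall for c in per_type.values()) / len(per_type)
        mf = sum(c.fmeasure for c in per_type.values()) / len(per_type)
    else:
        mp = mr = mf = 0.0
    return EvalReport(overall, per_type, mp, mr, mf)


def occurrence_counts(train: Corpus) -> dict[tuple[str, str], int]:
    """Gold-mention counts per (surface, type) across the training corpus."""
    counts: Counter[tuple[str, str]] = Counter()
    for sent in train:
        for m in sentence_entities(sent):
            counts[(m.surface, m.etype)] += 1
    return dict(counts)


def stratified_rare_recall(
    counts: dict[tuple[str, str], int], gold: MentionSets, pred: MentionSets
) -> tuple[dict[int, float], dict[int, int]]:
    """Exact-match recall of test gold mentions bucketed by training
    occurrence count (0/1/2/3; counts >= 4 are excluded).

    Returns (recall per non-empty bucket, support per bucket).
    """
    if len(gold) != len(pred):
        raise ValueError("gold and pred must be aligned by sentence")
    hit: Counter[int] = Counter()
    total: Counter[int] = Counter()
    for g_sent, p_sent in zip(gold, pred):
        p_keys = {m.key for m in p_sent}
        for m in g_sent:
            c = counts.get((m.surface, m.etype), 0)
            if c not in RARE_BUCKETS:
                continue
            total[c] += 1
            if m.key in p_keys:
                hit[c] += 1
    recall = {b: hit[b] / total[b] for b in RARE_BUCKETS if total[b]}
    support = {b: total[b] for b in RARE_BUCKETS}
    return recall, support


def evaluate(train: Corpus, gold: Corpus, pred: Corpus) -> EvalReport:
    """Full report: overall + per-type P/R/F and rare-entity recall, with
    rarity determined against ``train``."""
    g = corpus_mentions(gold)
    p = corpus_mentions(pred)
    report = entity_prf(g, p)
    counts = occurrence_counts(train)
    report.rare_recall, report.rare_support = stratified_rare_recall(counts, g, p)
    return report
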