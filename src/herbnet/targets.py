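"""Target fishing: score-filtered predictions merged with curated lookups,
plus target-disease annotation.

Compound-target edges arrive from two kinds of sources: a dual-classifier
prediction model emitting per-edge SVM and random-forest scores, and curated
edge lists exported from interaction databases. Predictions are kept when
both scores are strictly above their cutoffs (SVM > 0.8, RF > 0.7 by
default); all sources are then unioned into one edge per (compound, target)
pair with the contributing source tags as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

from .errors import InputError, VocabularyError
from .io import InteractionRecord, normalize_id

__all__ = [
    "TargetPrediction",
    "DiseaseAnnotation",
    "DEFAULT_DISEASE_VOCAB",
    "filter_predictions",
    "merge_target_sources",
    "map_targets_to_diseases",
]

# the eight disease classes used for the target-disease network
DEFAULT_DISEASE_VOCAB = (
    "obesity",
    "cardiovascular disease",
    "diabetes",
    "fatty liver",
    "gastrointestinal disease",
    "osteoarthritis",
    "inflammation",
    "cancer",
)


@dataclass(frozen=True)
class TargetPrediction:
    compound_id: str
    target_id: str
    svm_score: float
    rf_score: float
    source: str = "prediction"

    def __post_init__(self) -> None:
        for name, s in (("svm_score", self.svm_score), ("rf_score", self.rf_score)):
            if s is None or not math.isfinite(s):
                raise InputError(
                    f"prediction ({self.compound_id!r}, {self.target_id!r}): missing or "
                    f"non-finite {name}"
                )


@dataclass(frozen=True)
class DiseaseAnnotation:
    target_id: str
    disease_id: str
    evidence: str = ""


def filter_predictions(
    preds: Sequence[TargetPrediction],
    svm_min: float = 0.8,
    rf_min: float = 0.7,
    *,
    strict: bool = True,
) -> list[TargetPrediction]:
    """Keep predictions whose SVM and RF scores both clear their cutoffs.

    The default reading is strict (score must be larger than the cutoff);
    ``strict=False`` switches to inclusive comparison. Input order is
    preserved; the output is always a subset of the input.
    """
    if strict:
        return [p for p in preds if p.svm_score > svm_min and p.rf_score > rf_min]
    return [p for p in preds if p.svm_score >= svm_min and p.rf_score >= rf_min]


def merge_target_sources(
    prediction_edges: Sequence[TargetPrediction],
    curated_edges: Iterable[Sequence[InteractionRecord]] = (),
) -> list[InteractionRecord]:
    """Union compound-target edges across prediction and curated sources.

    One edge per (compound, target) pair; evidence is the set of contributing
    source tags. Deterministic output ordering by (compound_id, target_id),
    so merging sources in any permutation yields the same result.
    """
    merged: dict[tuple[str, str], set[str]] = {}
    scores: dict[tuple[str, str], dict[str, float]] = {}
    for p in prediction_edges:
        key = (normalize_id(p.compound_id), normalize_id(p.target_id))
        merged.setdefault(key, set()).add(p.source)
        scores.setdefault(key, {}).update({"svm": p.svm_score, "rf": p.rf_score})
    for source_list in curated_edges:
        for rec in source_list:
            if rec.kind != "compound-target":
                raise InputError(f"curated edge has kind {rec.kind!r}, expected compound-target")
            key = (normalize_id(rec.left_id), normalize_id(rec.right_id))
            merged.setdefault(key, set()).update(rec.evidence or {"curated"})
            if rec.scores:
                scores.setdefault(key, {}).update(rec.scores)
    return [
        InteractionRecord(
            left_id=c,
            right_id=t,
            kind="compound-target",
            evidence=frozenset(merged[(c, t)]),
            scores=scores.get((c, t)) or None,
        )
        for c, t in sorted(merged)
    ]


def map_targets_to_diseases(
    targets: Iterable[str],
    annotations: Sequence[DiseaseAnnotation],
    vocabulary: Sequence[str] = DEFAULT_DISEASE_VOCAB,
) -> list[InteractionRecord]:
    """Emit target-disease edges for targets present in the input set.

    Duplicate annotation rows collapse to a single edge with unioned evidence.
    Disease labels outside the declared vocabulary are an error.
    """
    vocab = {normalize_id(d) for d in vocabulary}
    target_set = {normalize_id(t) for t in targets}
    merged: dict[tuple[str, str], set[str]] = {}
    for ann in annotations:
        d = normalize_id(ann.disease_id)
        if d not in vocab:
            raise VocabularyError(
                f"disease {ann.disease_id!r} not in vocabulary {sorted(vocab)}"
            )
        t = normalize_id(ann.target_id)
        if t not in target_set:
            continue
        ev = {ann.evidence} if ann.evidence else set()
        merged.setdefault((t, d), set()).update(ev)
    return [
        InteractionRecord(
            left_id=t, right_id=d, kind="target-disease", evidence=frozenset(merged[(t, d)])
        )
        for t, d in sorted(merged)
    ]
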