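"""Confusion quantities, INF and F1 scores, and model ranking.

Two operating modes:

* threshold mode — each model's interaction set is compared with the
  discrete consensus subset (interactions seen in at least n models),
  giving crisp TP/FP/FN counts;
* conditionally weighted (fuzzy) mode — interactions are fuzzy-set members
  with membership p = frequency; a consensus interaction present in a model
  adds p to TPsum and 1-p to FPsum, one absent from the model adds p to
  FNsum.

Both modes feed the same two formulas:

    INF = sqrt( TP/(TP+FP) * TP/(TP+FN) )
    F1  = 2*TP / (2*TP + FP + FN)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from .annotation import ModelInteractionSet
from .consensus import AnalysisConfig, ConsensusMultiset, in_scope, threshold_consensus

__all__ = [
    "ConfusionCounts",
    "ConfusionSums",
    "ScoreReport",
    "Ranking",
    "crisp_confusion",
    "fuzzy_confusion",
    "inf_score",
    "f1_score",
    "rank_models",
    "write_ranking_csv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class ConfusionSums:
    tp: float
    fp: float
    fn: float

    def __post_init__(self):
        vals = (self.tp, self.fp, self.fn)
        if any(not math.isfinite(v) for v in vals) or min(vals) < 0:
            raise ValueError("confusion sums must be finite and non-negative")


Confusion = Union[ConfusionCounts, ConfusionSums]


@dataclass(frozen=True)
class ScoreReport:
    model_id: str
    inf: float
    f1: float
    mode: str
    confusion: Confusion


@dataclass
class Ranking:
    metric: str  # "INF" or "F1"
    order: list[tuple[str, float]]  # (model_id, primary score), best first


def crisp_confusion(
    model: ModelInteractionSet, consensus: set[tuple], scope: str = "pairs_and_stacking"
) -> ConfusionCounts:
    """TP/FP/FN between a model's key set and the consensus subset."""
    mkeys = {k for k in model.keys() if in_scope(k[0], scope)}
    ckeys = {k for k in consensus if in_scope(k[0], scope)}
    tp = len(mkeys & ckeys)
    return ConfusionCounts(tp, len(mkeys) - tp, len(ckeys) - tp)


def fuzzy_confusion(
    model: ModelInteractionSet,
    cm: ConsensusMultiset,
    scope: str = "pairs_and_stacking",
) -> ConfusionSums:
    """Fuzzy TPsum/FPsum/FNsum of a model against the consensus multiset.

    Constraint overrides: a required entry scores with membership 1.0; an
    x-forbidden entry is no consensus member at all, and a model containing
    it pays a full false positive.  Model interactions unknown to the
    multiset (possible only for models outside the ensemble) likewise count
    as full false positives (the p -> 0 limit of the membership rule).
    """
    tp = fp = fn = 0.0
    seen = set()
    for k, e in cm.entries.items():
        if not in_scope(e.interaction.kind, scope):
            continue
        present = k in model
        if present:
            seen.add(k)
        if e.constraint_flag == "x_forbidden":
            if present:
                fp += 1.0
            continue
        p = e.effective_membership
        if present:
            tp += p
            fp += 1.0 - p
        else:
            fn += p
    for k in model.keys():
        if k not in seen and k not in cm.entries and in_scope(k[0], scope):
            fp += 1.0
    return ConfusionSums(tp, fp, fn)


def inf_score(c: Confusion) -> float:
    """Geometric mean of precision and recall (Interaction Network Fidelity)."""
    if c.tp == 0:
        return 1.0 if c.fp == 0 and c.fn == 0 else 0.0
    return math.sqrt((c.tp / (c.tp + c.fp)) * (c.tp / (c.tp + c.fn)))


def f1_score(c: Confusion) -> float:
    """Harmonic mean of precision and recall."""
    if c.tp == 0:
        return 1.0 if c.fp == 0 and c.fn == 0 else 0.0
    return 2 * c.tp / (2 * c.tp + c.fp + c.fn)


def score_model(
    model: ModelInteractionSet,
    cm: ConsensusMultiset,
    cfg: AnalysisConfig,
    consensus_keys: set[tuple] | None = None,
) -> ScoreReport:
    if cfg.mode == "threshold":
        if consensus_keys is None:
            consensus_keys = threshold_consensus(cm, cfg.confidence_level)
        conf: Confusion = crisp_confusion(model, consensus_keys, cfg.scope)
    else:
        conf = fuzzy_confusion(model, cm, cfg.scope)
    return ScoreReport(
        model.model_id, inf_score(conf), f1_score(conf), cfg.mode, conf
    )


def rank_models(
    sets: Sequence[ModelInteractionSet],
    cm: ConsensusMultiset,
    cfg: AnalysisConfig,
) -> tuple[Ranking, list[ScoreReport]]:
    """Score every model and sort by the primary metric (descending,
    ties broken lexicographically by model id)."""
    if not sets:
        raise ValueError("cannot rank an empty ensemble")
    cfg.validate(cm.n_models)
    consensus_keys = (
        threshold_consensus(cm, cfg.confidence_level)
        if cfg.mode == "threshold"
        else None
    )
    reports = [score_model(m, cm, cfg, consensus_keys) for m in sets]
    key = (lambda r: r.inf) if cfg.metric == "INF" else (lambda r: r.f1)
    ordered = sorted(reports, key=lambda r: (-key(r), r.model_id))
    ranking = Ranking(cfg.metric, [(r.model_id, key(r)) for r in ordered])
    return ranking, reports


def write_ranking_csv(
    ranking: Ranking, reports: Sequence[ScoreReport], cfg: AnalysisConfig,
    path: str | Path,
) -> None:
    import csv

    by_id = {r.model_id: r for r in reports}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["rank", "model_id", "INF", "F1", "TP", "FP", "FN", "mode", "scope"]
        )
        for rank, (mid, _) in enumerate(ranking.order, start=1):
            r = by_id[mid]
            c = r.confusion
            fmt = (
                (lambda v: f"{v:d}")
                if isinstance(c, ConfusionCounts)
                else (lambda v: f"{v:.6f}")
            )
            writer.writerow(
                [
                    rank, mid, f"{r.inf:.6f}", f"{r.f1:.6f}",
                    fmt(c.tp), fmt(c.fp), fmt(c.fn), cfg.mode, cfg.scope,
                ]
            )
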