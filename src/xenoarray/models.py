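"""Rule models predicting cross-species hybridization from best BLAST hits.

A rule model is a union of clauses over the best cross-species hit's
alignment length (``Align``) and mismatch count (``mis``); each clause is an
interval ``align_lo < Align <= align_hi`` with a strict mismatch ceiling
``mis < mismatch_max``.  One model additionally gates on the hit score.
All bounds are encoded exactly as printed in the source rule sets: lower
bounds strict, upper bounds inclusive, mismatch bounds strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import AlignmentHit, PredictionSet, ValidationError

INF = math.inf


@dataclass(frozen=True)
class RuleClause:
    """``align_lo < Align <= align_hi  and  mis < mismatch_max``."""

    align_lo: float
    align_hi: float
    mismatch_max: int

    def __post_init__(self) -> None:
        if not self.align_lo < self.align_hi:
            raise ValidationError(f"clause needs align_lo < align_hi, got {self}")
        if self.mismatch_max < 0:
            raise ValidationError(f"negative mismatch bound in {self}")

    def contains(self, align_length: int, mismatches: int) -> bool:
        return self.align_lo < align_length <= self.align_hi and mismatches < self.mismatch_max


@dataclass(frozen=True)
class CshRuleModel:
    """A named union of :class:`RuleClause`, optionally score-gated.

    A probe is predicted cross-hybridizing iff its best cross-species hit
    satisfies ANY clause and, when ``score_min`` is set, ``score > score_min``.
    """

    name: str
    clauses: tuple[RuleClause, ...]
    score_min: Optional[float] = None

    def __post_init__(self) -> None:
        spans = sorted((c.align_lo, c.align_hi) for c in self.clauses)
        for (lo1, hi1), (lo2, _hi2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValidationError(f"model {self.name}: overlapping align ranges")

    @property
    def requires_score(self) -> bool:
        return self.score_min is not None


def builtin_models() -> dict[str, CshRuleModel]:
    """The six published rule sets, keyed by canonical lowercase name."""
    c = RuleClause
    return {
        "model1": CshRuleModel("model1", (
            c(18, 20, 5), c(20, 30, 6), c(30, 40, 7), c(40, 50, 8), c(50, INF, 9),
        )),
        "model2": CshRuleModel("model2", (
            c(15, 30, 2), c(30, 40, 3), c(40, 50, 5), c(50, INF, 7),
        )),
        "model3": CshRuleModel("model3", (c(50, INF, 6),)),
        "model4": CshRuleModel("model4", (c(58, INF, 6),), score_min=70.0),
        "model1-1": CshRuleModel("model1-1", (
            c(18, 20, 6), c(20, 30, 7), c(30, 40, 8), c(40, 45, 9), c(45, 50, 10),
            c(50, INF, 11),
        )),
        "model1-2": CshRuleModel("model1-2", (
            c(30, 40, 8), c(40, 45, 9), c(45, 50, 10), c(50, INF, 11),
        )),
    }


def apply_rule_model(model: CshRuleModel, hit: AlignmentHit) -> bool:
    """True iff the hit satisfies any clause (and the score gate, if any)."""
    if model.requires_score:
        if hit.score is None:
            raise ValidationError(
                f"model {model.name} requires a hit score but none is available"
            )
        if not hit.score > model.score_min:
            return False
    return any(cl.contains(hit.align_length, hit.mismatches) for cl in model.clauses)


def satisfied_clause(model: CshRuleModel, hit: AlignmentHit) -> Optional[int]:
    """Index of the first satisfied clause, or None."""
    if model.requires_score:
        if hit.score is None:
            raise ValidationError(
                f"model {model.name} requires a hit score but none is available"
            )
        if not hit.score > model.score_min:
            return None
    for idx, cl in enumerate(model.clauses):
        if cl.contains(hit.align_length, hit.mismatches):
            return idx
    return None


def apply_rule_model_frame(model: CshRuleModel, hits: pd.DataFrame) -> np.ndarray:
    """Vectorized model application over a frame with columns
    ``align_length``, ``mismatches`` and (when the model needs it) ``score``."""
    align = hits["align_length"].to_numpy()
    mis = hits["mismatches"].to_numpy()
    pred = np.zeros(len(hits), dtype=bool)
    for cl in model.clauses:
        pred |= (align > cl.align_lo) & (align <= cl.align_hi) & (mis < cl.mismatch_max)
    if model.requires_score:
        if "score" not in hits.columns:
            raise ValidationError(f"model {model.name} requires a score column")
        pred &= hits["score"].to_numpy() > model.score_min
    return pred


def predict_csh(
    probes: Iterable,
    best_hits: Mapping[str, AlignmentHit],
    model: CshRuleModel,
) -> PredictionSet:
    """Classify each probe from its best cross-species hit.

    Probes absent from ``best_hits`` (no cross-species alignment at all) are
    never predicted cross-hybridizing.  The result is order-independent.
    """
    universe = []
    for p in probes:
        universe.append(p.probe_id if hasattr(p, "probe_id") else str(p))
    if len(set(universe)) != len(universe):
        raise ValidationError("duplicate probe ids in prediction universe")
    predicted = set()
    clause_index: dict[str, int] = {}
    for pid in universe:
        hit = best_hits.get(pid)
        if hit is None:
            continue
        if hit.probe_id != pid:
            raise ValidationError(f"best hit for {pid} carries probe_id {hit.probe_id}")
        idx = satisfied_clause(model, hit)
        if idx is not None:
            predicted.add(pid)
            clause_index[pid] = idx
    return PredictionSet(model.name, frozenset(predicted), frozenset(universe), clause_index)
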