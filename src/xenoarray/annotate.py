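"""Scoring rule models against gold standards and annotating probes.

True positives are probes both biologically labelled (gold standard) and
rule-predicted cross-hybridizing; precision is taken over the prediction,
recall over the gold standard, and the two are combined by the F-score
``F = 2 * precision * recall / (precision + recall)`` (0 when both are 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .goldstandard import build_gold_standard
from .models import CshRuleModel, predict_csh
from .types import (
    EvaluationResult,
    GoldStandardLabeling,
    GoldStandardSpec,
    PredictionSet,
    ValidationError,
)


def f_score(precision: float, recall: float) -> float:
    """Harmonic-mean F; defined 0 when precision + recall == 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate(prediction: PredictionSet, gold: GoldStandardLabeling) -> EvaluationResult:
    """Confusion counts of a prediction against a gold standard over one
    shared probe universe."""
    universe = frozenset(gold.eligible_probes)
    if prediction.universe != universe:
        diff = len(prediction.universe ^ universe)
        raise ValidationError(
            f"prediction and gold-standard universes differ by {diff} probes"
        )
    pred = prediction.predicted
    gs = gold.csh_probes
    tp = len(pred & gs)
    fp = len(pred - gs)
    fn = len(gs - pred)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvaluationResult(
        prediction.model_name, gold.spec.label, tp, fp, fn,
        precision, recall, f_score(precision, recall),
    )


@dataclass
class GridSearchResult:
    table: pd.DataFrame  # one row per (model, gs_label) with counts and scores
    selected_model: str
    selected_gs: str
    selected: EvaluationResult


def evaluate_grid(
    models: Mapping[str, CshRuleModel],
    gold_standards: Mapping[str, GoldStandardLabeling],
    best_hits,
    recall_band: float = 0.01,
) -> GridSearchResult:
    """Evaluate every (model, gold standard) pair and select a configuration.

    Selection maximizes F; among configurations within ``recall_band``
    absolute F of the maximum, the highest recall wins (ties break
    lexicographically on model name then GS label, making the result
    independent of input ordering).
    """
    if not models or not gold_standards:
        raise ValidationError("need at least one model and one gold standard")
    rows = []
    results: dict[tuple[str, str], EvaluationResult] = {}
    for gs_label in sorted(gold_standards):
        gold = gold_standards[gs_label]
        if not gold.eligible_probes:
            raise ValidationError(f"gold standard {gs_label} has an empty probe universe")
        for name in sorted(models):
            pred = predict_csh(sorted(gold.eligible_probes), best_hits, models[name])
            pred = PredictionSet(name, pred.predicted, pred.universe, pred.clause_index)
            res = evaluate(pred, gold)
            results[(name, gs_label)] = res
            rows.append(
                {
                    "model": name, "gold_standard": gs_label,
                    "tp": res.tp, "fp": res.fp, "fn": res.fn,
                    "precision": res.precision, "recall": res.recall,
                    "f_score": res.f_score,
                }
            )
    table = pd.DataFrame(rows)
    best_f = table["f_score"].max()
    band = table[table["f_score"] >= best_f - recall_band]
    band = band.sort_values(
        ["recall", "f_score", "model", "gold_standard"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    top = band.iloc[0]
    sel = results[(top["model"], top["gold_standard"])]
    return GridSearchResult(
        table.sort_values("f_score", ascending=False).reset_index(drop=True),
        top["model"], top["gold_standard"], sel,
    )


def grid_search(
    models: Mapping[str, CshRuleModel],
    gs_kinds: Sequence[str],
    x_grid: Sequence[float],
    matrix_correct,
    matrix_erroneous,
    eligible,
    best_hits,
    recall_band: float = 0.01,
) -> GridSearchResult:
    """Build gold standards for every (kind, x) and run :func:`evaluate_grid`."""
    if not x_grid:
        raise ValidationError("x_grid must not be empty")
    gold_standards = {}
    for kind in gs_kinds:
        for x in x_grid:
            spec = GoldStandardSpec(kind, x)
            gold_standards[spec.label] = build_gold_standard(
                spec, matrix_correct, matrix_erroneous, eligible
            )
    return evaluate_grid(models, gold_standards, best_hits, recall_band)


@dataclass
class CshAnnotation:
    """Per-probe cross-hybridization propensity annotation.

    ``table`` is indexed by probe id with columns ``csh_level`` (1 = most
    CSH-prone decile, 10 = least), ``csh_flag_top5`` and one boolean column
    per supplied rule-model prediction.
    """

    table: pd.DataFrame

    def retained(self, level_cutoff) -> frozenset:
        return mask_csh(self, level_cutoff)

    def levels_up_to(self, k: int) -> frozenset:
        return frozenset(self.table.index[self.table["csh_level"] <= k])


def annotate_deciles(
    statistic: pd.Series,
    predictions: Mapping[str, PredictionSet] | None = None,
    top_flag_fraction: float = 0.05,
) -> CshAnnotation:
    """Stratify probes into ten levels by their gold-standard statistic.

    Probes are ranked descending (ties broken by probe id ascending, so the
    assignment is deterministic and order-independent); a probe at rank r of
    n gets level ``k = min{k : r <= floor(k*n/10)}``, making the union of
    levels 1..k exactly the top floor(k/10 * n) set.  ``csh_flag_top5``
    marks the top ``top_flag_fraction`` (default 5%).
    """
    if statistic.isna().any():
        bad = statistic.index[statistic.isna()].tolist()
        raise ValidationError(f"missing statistic for eligible probes: {bad[:5]}")
    order = statistic.to_frame("stat").reset_index(names="probe_id")
    order = order.sort_values(["stat", "probe_id"], ascending=[False, True], kind="mergesort")
    n = len(order)
    ranks = np.arange(1, n + 1)
    boundaries = np.floor(np.arange(1, 11) * n / 10).astype(int)
    levels = np.searchsorted(boundaries, ranks, side="left") + 1
    table = pd.DataFrame(
        {
            "csh_level": levels,
            "csh_flag_top5": ranks <= math.floor(top_flag_fraction * n),
        },
        index=pd.Index(order["probe_id"], name="probe_id"),
    ).sort_index()
    if predictions:
        for name, pred in predictions.items():
            col = f"pred_{name.replace('-', '_')}"
            table[col] = table.index.isin(pred.predicted)
    return CshAnnotation(table)


def mask_csh(annotation: CshAnnotation, level_cutoff) -> frozenset:
    """Probes retained after masking the most CSH-prone levels.

    ``level_cutoff="top5"`` masks only the top-5% flag; an integer k masks
    levels 1..k (0 retains everything, 10 nothing).
    """
    table = annotation.table
    if level_cutoff == "top5":
        return frozenset(table.index[~table["csh_flag_top5"]])
    k = int(level_cutoff)
    if not 0 <= k <= 10:
        raise ValidationError("level_cutoff must be 'top5' or an integer 0..10")
    return frozenset(table.index[table["csh_level"] > k])


def enrichment_hypergeometric(
    query_set: Iterable,
    background_set: Iterable,
    category_map: Mapping[str, Iterable],
    max_category_size: int = 500,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH-FDR correction.

    Categories with more than ``max_category_size`` members in the background
    are excluded.  This is a plain (not GO-graph-conditional) test.
    """
    query = frozenset(query_set)
    background = frozenset(background_set)
    if not background:
        raise ValidationError("background set must not be empty")
    if not query <= background:
        raise ValidationError("query set must be a subset of the background")
    rows = []
    for cat in sorted(category_map):
        members = frozenset(category_map[cat]) & background
        if not members or len(members) > max_category_size:
            continue
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, len(background), len(members), len(query)))
        rows.append({"category": cat, "n_category": len(members), "n_overlap": k, "p": p})
    out = pd.DataFrame(rows, columns=["category", "n_category", "n_overlap", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out
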