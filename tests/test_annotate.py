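"""F-score evaluation, grid search, decile annotation and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xenoarray.annotate import (
    annotate_deciles,
    enrichment_hypergeometric,
    evaluate,
    evaluate_grid,
    f_score,
    mask_csh,
)
from xenoarray.goldstandard import build_gold_standard
from xenoarray.models import builtin_models, predict_csh
from xenoarray.types import (
    AlignmentHit,
    ExpressionMatrix,
    GoldStandardLabeling,
    GoldStandardSpec,
    PredictionSet,
    ValidationError,
)


def make_gold(csh, eligible, x=0.5):
    eligible = frozenset(eligible)
    stat = pd.Series({p: (2.0 if p in csh else 1.0) for p in eligible})
    return GoldStandardLabeling(GoldStandardSpec("GS2", x), frozenset(csh), eligible, stat)


def make_pred(predicted, universe, name="m"):
    return PredictionSet(name, frozenset(predicted), frozenset(universe))


class TestEvaluate:
    def test_perfect_prediction(self):
        universe = {f"p{i}" for i in range(10)}
        csh = {"p0", "p1", "p2"}
        res = evaluate(make_pred(csh, universe), make_gold(csh, universe))
        assert (res.precision, res.recall, res.f_score) == (1.0, 1.0, 1.0)

    def test_disjoint_prediction(self):
        universe = {f"p{i}" for i in range(10)}
        res = evaluate(make_pred({"p0"}, universe), make_gold({"p1"}, universe))
        assert res.f_score == 0.0

    def test_counts(self):
        universe = {f"p{i}" for i in range(8)}
        res = evaluate(
            make_pred({"p0", "p1", "p2"}, universe), make_gold({"p1", "p2", "p3", "p4"}, universe)
        )
        assert (res.tp, res.fp, res.fn) == (2, 1, 2)

    def test_published_precision_recall_pair(self):
        # independent hand computation: 2*0.13*0.256 / (0.13+0.256)
        expect = (2 * 0.13 * 0.256) / (0.13 + 0.256)
        assert abs(f_score(0.13, 0.256) - expect) < 1e-12
        assert f_score(0.13, 0.256) == pytest.approx(0.17243523316062177, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    def test_harmonic_mean_identity(self, p, r):
        assert f_score(p, r) == pytest.approx(2.0 / (1.0 / p + 1.0 / r), rel=1e-12)

    def test_universe_mismatch_reports_difference(self):
        with pytest.raises(ValidationError, match="3"):
            evaluate(make_pred(set(), {"p0", "p1"}), make_gold(set(), {"p0", "x1", "x2"}))


def synth_hits(n, rng):
    hits = {}
    for i in range(n):
        a = int(rng.integers(1, 61))
        m = int(rng.integers(0, min(a, 13)))
        hits[f"p{i}"] = AlignmentHit(f"p{i}", "t", a, m, float(2 * a))
    return hits


class TestEvaluateGrid:
    def test_single_configuration_selected(self, rng):
        hits = synth_hits(50, rng)
        gold = make_gold({"p0"}, set(hits))
        models = {"model3": builtin_models()["model3"]}
        res = evaluate_grid(models, {"only": gold}, hits)
        assert (res.selected_model, res.selected_gs) == ("model3", "only")

    def test_exact_model_region_recovers_f1(self, rng):
        hits = synth_hits(400, rng)
        m11 = builtin_models()["model1-1"]
        truth = predict_csh(sorted(hits), hits, m11).predicted
        gold = make_gold(truth, set(hits))
        res = evaluate_grid(builtin_models(), {"gs": gold}, hits)
        assert res.selected_model == "model1-1"
        assert res.selected.f_score == 1.0

    def test_selection_order_invariant(self, rng):
        hits = synth_hits(200, rng)
        truth = predict_csh(sorted(hits), hits, builtin_models()["model1"]).predicted
        gold = make_gold(truth, set(hits))
        models = builtin_models()
        forward = evaluate_grid(dict(models), {"gs": gold}, hits)
        backward = evaluate_grid(dict(reversed(list(models.items()))), {"gs": gold}, hits)
        assert (forward.selected_model, forward.selected_gs) == (
            backward.selected_model, backward.selected_gs
        )

    def test_grid_search_from_matrices(self, rng):
        # end-to-end: gold standards built from matrices for every (kind, x)
        from xenoarray.annotate import grid_search
        from tests.test_goldstandard import gs_fixture

        index = [f"p{i}" for i in range(60)]
        corr, err = gs_fixture(list(rng.lognormal(2, 1, 60)),
                               list(rng.lognormal(2, 1, 60)), index)
        hits = synth_hits(60, rng)
        hits = {pid: AlignmentHit(pid, "t", h.align_length, h.mismatches, h.score)
                for pid, h in zip(index, hits.values())}
        res = grid_search(builtin_models(), ["GS2", "GS3"], [0.1, 0.3],
                          corr, err, index, hits)
        assert len(res.table) == 6 * 4
        assert res.selected_gs in {f"{k}.{x:g}" for k in ("GS2", "GS3") for x in (0.1, 0.3)}
        assert res.selected_model in builtin_models()

    def test_empty_universe_rejected(self):
        gold = GoldStandardLabeling(
            GoldStandardSpec("GS2", 0.5), frozenset(), frozenset(), pd.Series(dtype=float)
        )
        with pytest.raises(ValidationError, match="empty"):
            evaluate_grid(builtin_models(), {"gs": gold}, {})


class TestAnnotateDeciles:
    def test_twenty_probes_two_per_level(self, rng):
        stat = pd.Series(rng.permutation(20).astype(float), index=[f"p{i:02d}" for i in range(20)])
        annot = annotate_deciles(stat)
        counts = annot.table["csh_level"].value_counts()
        assert sorted(counts.index) == list(range(1, 11))
        assert (counts == 2).all()

    def test_top_probe_level_one_and_flagged(self):
        stat = pd.Series(np.arange(40, 0, -1, dtype=float), index=[f"p{i:02d}" for i in range(40)])
        annot = annotate_deciles(stat)
        assert annot.table.loc["p00", "csh_level"] == 1
        assert bool(annot.table.loc["p00", "csh_flag_top5"])
        assert annot.table["csh_flag_top5"].sum() == 2  # floor(0.05 * 40)

    def test_top5_implies_level_one(self, rng):
        stat = pd.Series(rng.lognormal(0, 1, 173), index=[f"p{i:03d}" for i in range(173)])
        annot = annotate_deciles(stat)
        flagged = annot.table[annot.table["csh_flag_top5"]]
        assert (flagged["csh_level"] == 1).all()

    def test_all_equal_statistics_assigned_by_probe_id(self):
        stat = pd.Series(1.0, index=[f"p{i}" for i in range(10)])
        annot = annotate_deciles(stat)
        # deterministic tie policy: probe id ascending fills level 1 first
        assert annot.table.loc["p0", "csh_level"] == 1
        assert annot.table.loc["p9", "csh_level"] == 10

    def test_missing_statistic_rejected(self):
        stat = pd.Series([1.0, np.nan], index=["p0", "p1"])
        with pytest.raises(ValidationError, match="p1"):
            annotate_deciles(stat)

    def test_levels_union_matches_gold_standard_top_k(self, rng):
        # cross-module consistency: union of levels 1..k == independent
        # top-(k*10%) construction at x = k/10
        index = [f"p{i:03d}" for i in range(137)]
        err_vals = list(rng.lognormal(2, 1, len(index)))
        meta = {
            "err": {"exposed_species": "A", "mix_fraction_a": np.nan, "channel": "single",
                    "replicate": 1},
            "corr": {"exposed_species": "B", "mix_fraction_a": np.nan, "channel": "single",
                     "replicate": 1},
        }
        err = ExpressionMatrix(pd.DataFrame({"err": err_vals}, index=index),
                               pd.DataFrame.from_dict(meta, orient="index").loc[["err"]])
        corr = ExpressionMatrix(pd.DataFrame({"corr": [1.0] * len(index)}, index=index),
                                pd.DataFrame.from_dict(meta, orient="index").loc[["corr"]])
        full = build_gold_standard(GoldStandardSpec("GS2", 1.0), corr, err, index)
        annot = annotate_deciles(full.statistic)
        for k in range(1, 11):
            gold = build_gold_standard(GoldStandardSpec("GS2", k / 10), corr, err, index)
            assert annot.levels_up_to(k) == gold.csh_probes, k


class TestMaskCsh:
    @pytest.fixture()
    def annotation(self, rng):
        stat = pd.Series(rng.permutation(100).astype(float),
                         index=[f"p{i:03d}" for i in range(100)])
        return annotate_deciles(stat)

    def test_drop_first_level(self, annotation):
        assert len(mask_csh(annotation, 1)) == 90

    def test_cutoff_zero_retains_all(self, annotation):
        assert len(mask_csh(annotation, 0)) == 100

    def test_cutoff_ten_retains_none(self, annotation):
        assert mask_csh(annotation, 10) == frozenset()

    def test_top5_mask(self, annotation):
        retained = mask_csh(annotation, "top5")
        assert len(retained) == 95
        assert retained == frozenset(
            annotation.table.index[~annotation.table["csh_flag_top5"]]
        )


def hypergeom_enumeration(N, K, n, k):
    """Exact upper-tail by direct combinatorial summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestEnrichment:
    def test_query_equals_background_gives_p_one(self):
        background = {f"g{i}" for i in range(30)}
        cats = {"c1": {f"g{i}" for i in range(5)}, "c2": {f"g{i}" for i in range(10, 14)}}
        table = enrichment_hypergeometric(background, background, cats)
        assert np.allclose(table["p"], 1.0)

    def test_matches_enumeration_oracle(self):
        background = [f"g{i}" for i in range(20)]
        query = background[:10]
        cats = {"exact": set(query), "half": set(background[5:15]), "off": set(background[12:18])}
        table = enrichment_hypergeometric(query, background, cats).set_index("category")
        for name, members in cats.items():
            k = len(members & set(query))
            expect = hypergeom_enumeration(20, len(members), 10, k)
            assert table.loc[name, "p"] == pytest.approx(expect, rel=1e-9)

    def test_oversized_category_excluded(self):
        background = {f"g{i}" for i in range(50)}
        cats = {"big": set(background), "small": {f"g{i}" for i in range(3)}}
        table = enrichment_hypergeometric({"g0", "g1"}, background, cats, max_category_size=10)
        assert list(table["category"]) == ["small"]

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError, match="background"):
            enrichment_hypergeometric(set(), set(), {})

    def test_fdr_monotone_in_p(self, rng):
        background = [f"g{i}" for i in range(40)]
        query = background[:12]
        cats = {f"c{j}": set(rng.choice(background, size=8, replace=False)) for j in range(6)}
        table = enrichment_hypergeometric(query, background, cats).sort_values("p")
        assert (table["fdr"].to_numpy() >= table["p"].to_numpy() - 1e-12).all()
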