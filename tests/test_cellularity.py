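"""SSP selection, housekeeping pairing and the cellularity index."""

import math

import numpy as np
import pandas as pd
import pytest

from xenoarray.cellularity import (
    HomologPair,
    SspCriteria,
    cellularity_index,
    optimize_ssp_threshold,
    pair_housekeeping,
    select_ssp,
)
from xenoarray.simulate import SimulationConfig, simulate_dual_species, simulate_validation_experiment
from xenoarray.types import ExpressionMatrix, HomologTable, ValidationError


def pure_matrix(values: pd.DataFrame, n_a=1, n_b=1):
    """Matrix with pure-A then pure-B exposure columns."""
    meta = {}
    for i, col in enumerate(values.columns):
        species = "A" if i < n_a else "B"
        meta[col] = {"exposed_species": species, "mix_fraction_a": np.nan,
                     "channel": "single", "replicate": i + 1}
    return ExpressionMatrix(values, pd.DataFrame.from_dict(meta, orient="index"))


def hk_fixture(n_decoys=50):
    """13 clean housekeeping pairs plus per-species decoy probes with high
    cross-exposure signal (so the quantile cutoff sits above the HK probes)."""
    rows, species, genes = {}, {}, {}
    for i in range(13):
        for sp, other_col in (("A", "expB"), ("B", "expA")):
            pid = f"hk{sp}{i:02d}"
            own = 100.0 + i
            rows[pid] = {"expA": own if sp == "A" else 0.5,
                         "expB": own if sp == "B" else 0.5}
            species[pid] = sp
            genes[pid] = f"g{sp}{i:02d}"
    for j in range(n_decoys):
        for sp in ("A", "B"):
            pid = f"dec{sp}{j:02d}"
            rows[pid] = {"expA": 50.0, "expB": 50.0}  # cross-hybridizing decoys
            species[pid] = sp
            genes[pid] = f"dg{sp}{j:02d}"
    values = pd.DataFrame(rows).T[["expA", "expB"]]
    matrix = pure_matrix(values)
    homologs = HomologTable(pd.DataFrame(
        {"gene_a": [f"gA{i:02d}" for i in range(13)],
         "gene_b": [f"gB{i:02d}" for i in range(13)],
         "housekeeping": True}
    ))
    return matrix, pd.Series(species), pd.Series(genes), homologs


class TestSelectSsp:
    def test_criterion1_boundary(self):
        values = pd.DataFrame(
            {"a1": [0.9, 5.0, 100.0], "b1": [0.2, 0.2, 90.0]},
            index=["pA_weak", "pA_good", "pB_good"],
        )
        m = pure_matrix(values)
        species = pd.Series({"pA_weak": "A", "pA_good": "A", "pB_good": "B"})
        sets = select_ssp(m, species, SspCriteria(0.99))
        assert "pA_weak" not in sets["A"]
        assert "pA_good" in sets["A"]

    def test_zero_cross_affinity_probes_retained_on_simulated_data(self):
        # construction: 60% of genes are perfect homologs (strong CSH), the
        # cross-clean minority all fall below the median cross expression
        cfg = SimulationConfig(n_genes=30, transcript_length=200, homolog_fraction=0.6,
                               divergence=0.0, noise_sd=0.05, seed=21)
        ds = simulate_dual_species(cfg)
        m = simulate_validation_experiment(ds, 3, seed=1)
        sets = select_ssp(m, ds.probe_species(), SspCriteria(0.5))
        for p in ds.probes:
            if ds.max_cross_affinity_zero(p.probe_id):
                assert p.probe_id in sets[p.species]

    def test_tightening_x_never_adds_probes(self):
        matrix, species, _, _ = hk_fixture()
        loose = select_ssp(matrix, species, SspCriteria(0.5))
        tight = select_ssp(matrix, species, SspCriteria(0.1))
        assert tight["A"] <= loose["A"] and tight["B"] <= loose["B"]

    def test_flagged_and_predicted_probes_excluded(self):
        matrix, species, _, _ = hk_fixture()
        sets = select_ssp(matrix, species, SspCriteria(0.5),
                          csh_flagged={"hkA00"}, predicted_csh={"hkA01"})
        assert "hkA00" not in sets["A"] and "hkA01" not in sets["A"]

    def test_missing_pure_exposure_rejected(self):
        values = pd.DataFrame({"a1": [5.0]}, index=["p0"])
        m = pure_matrix(values, n_a=1, n_b=0)
        with pytest.raises(ValidationError, match="pure"):
            select_ssp(m, pd.Series({"p0": "A"}), SspCriteria(0.5))


class TestPairHousekeeping:
    def test_thirteen_pairs_formed(self):
        matrix, species, genes, homologs = hk_fixture()
        sets = select_ssp(matrix, species, SspCriteria(0.5))
        pairs = pair_housekeeping(sets, homologs, genes, species, matrix)
        assert len(pairs) == 13
        assert all(p.probe_a.startswith("hkA") and p.probe_b.startswith("hkB") for p in pairs)

    def test_gene_with_one_sided_ssp_skipped(self):
        matrix, species, genes, homologs = hk_fixture()
        sets = select_ssp(matrix, species, SspCriteria(0.5))
        sets = {"A": sets["A"] - {"hkA00"}, "B": sets["B"]}
        pairs = pair_housekeeping(sets, homologs, genes, species, matrix)
        assert len(pairs) == 12
        assert not any(p.gene_a == "gA00" for p in pairs)

    def test_highest_mean_expression_probe_chosen(self):
        values = pd.DataFrame(
            {"a1": [5.0, 7.0, 100.0], "b1": [0.2, 0.2, 90.0]},
            index=["pA_lo", "pA_hi", "pB"],
        )
        matrix = pure_matrix(values)
        species = pd.Series({"pA_lo": "A", "pA_hi": "A", "pB": "B"})
        genes = pd.Series({"pA_lo": "gA", "pA_hi": "gA", "pB": "gB"})
        homologs = HomologTable(pd.DataFrame(
            {"gene_a": ["gA"], "gene_b": ["gB"], "housekeeping": [True]}
        ))
        sets = {"A": frozenset({"pA_lo", "pA_hi"}), "B": frozenset({"pB"})}
        (pair,) = pair_housekeeping(sets, homologs, genes, species, matrix)
        assert pair.probe_a == "pA_hi"

    def test_no_pairs_is_an_error(self):
        matrix, species, genes, homologs = hk_fixture()
        with pytest.raises(ValidationError, match="relax"):
            pair_housekeeping({"A": frozenset(), "B": frozenset()},
                              homologs, genes, species, matrix)


def mixture_matrix(rows: dict, n_samples=1):
    meta = {
        f"m{i}": {"exposed_species": "mixed", "mix_fraction_a": 0.5,
                  "channel": "single", "replicate": i + 1}
        for i in range(n_samples)
    }
    values = pd.DataFrame({f"m{i}": rows for i in range(n_samples)})
    return ExpressionMatrix(values, pd.DataFrame.from_dict(meta, orient="index"))


class TestCellularityIndex:
    PAIRS = [
        HomologPair("g1", "h1", "pa1", "pb1"),
        HomologPair("g2", "h2", "pa2", "pb2"),
        HomologPair("g3", "h3", "pa3", "pb3"),
    ]

    def test_hand_computed_ratios(self):
        m = mixture_matrix(pd.Series(
            {"pa1": 100.0, "pb1": 10.0, "pa2": 80.0, "pb2": 8.0, "pa3": 60.0, "pb3": 6.0}
        ))
        est = cellularity_index(m, self.PAIRS)
        assert np.allclose(est.pair_table["ratio"], 10.0)
        assert est.median_ratio == pytest.approx(10.0)
        assert est.median_log2_ratio == pytest.approx(math.log2(10), abs=1e-9)
        assert est.log2_variance == pytest.approx(0.0, abs=1e-12)

    def test_species_swap_inverts_ratios(self):
        rows = pd.Series(
            {"pa1": 100.0, "pb1": 10.0, "pa2": 50.0, "pb2": 8.0, "pa3": 60.0, "pb3": 6.0}
        )
        m = mixture_matrix(rows)
        est = cellularity_index(m, self.PAIRS)
        swapped = [HomologPair(p.gene_b, p.gene_a, p.probe_b, p.probe_a) for p in self.PAIRS]
        est_sw = cellularity_index(m, swapped)
        assert est_sw.median_ratio == pytest.approx(1.0 / est.median_ratio)
        assert est_sw.median_log2_ratio == pytest.approx(-est.median_log2_ratio)

    def test_equal_mixture_symmetric_pairs_give_unit_ratio(self):
        cfg = SimulationConfig(n_genes=20, transcript_length=200, homolog_fraction=1.0,
                               divergence=0.5, noise_sd=0.0, seed=9)
        ds = simulate_dual_species(cfg)
        from xenoarray.simulate import simulate_exposure

        m = simulate_exposure(ds, 0.5, n_replicates=1, seed=0)
        pairs = [
            HomologPair(r["gene_a"], r["gene_b"],
                        f"pA{r['gene_a'][2:]}_0", f"pB{r['gene_b'][2:]}_0")
            for _, r in ds.homologs.housekeeping_pairs().iterrows()
            if ds.max_cross_affinity_zero(f"pA{r['gene_a'][2:]}_0")
            and ds.max_cross_affinity_zero(f"pB{r['gene_b'][2:]}_0")
        ]
        est = cellularity_index(m, pairs)
        assert est.median_ratio == pytest.approx(1.0)
        assert est.median_log2_ratio == pytest.approx(0.0, abs=1e-9)

    def test_mixed_exposure_conditions_rejected(self):
        values = pd.DataFrame({"a1": [1.0], "b1": [2.0]}, index=["p0"])
        m = pure_matrix(values)
        with pytest.raises(ValidationError, match="condition"):
            cellularity_index(m, self.PAIRS[:1])

    def test_no_pairs_rejected(self):
        m = mixture_matrix(pd.Series({"pa1": 1.0}))
        with pytest.raises(ValidationError, match="pair"):
            cellularity_index(m, [])


class TestOptimizeSspThreshold:
    def _fixture(self):
        """Loose x admits a contaminated pair (probe_b cross-hybridizes,
        inflating its mixture expression and skewing the ratio)."""
        rows, species, genes = {}, {}, {}
        mix_rows = {}
        for i in range(4):
            pa, pb = f"pA{i}", f"pB{i}"
            rows[pa] = {"expA": 100.0, "expB": 0.3}
            rows[pb] = {"expA": 0.3, "expB": 100.0}
            mix_rows[pa], mix_rows[pb] = 50.0, 50.0
            species[pa], species[pb] = "A", "B"
            genes[pa], genes[pb] = f"gA{i}", f"gB{i}"
        # contaminated pair: pB4 binds species-A RNA too
        rows["pA4"] = {"expA": 100.0, "expB": 0.3}
        rows["pB4"] = {"expA": 40.0, "expB": 100.0}
        mix_rows["pA4"], mix_rows["pB4"] = 50.0, 70.0  # inflated denominator
        species["pA4"], species["pB4"] = "A", "B"
        genes["pA4"], genes["pB4"] = "gA4", "gB4"
        # decoys pushing the quantile cutoffs
        for j in range(10):
            for sp in ("A", "B"):
                pid = f"dec{sp}{j}"
                rows[pid] = {"expA": 500.0, "expB": 500.0}
                mix_rows[pid] = 500.0
                species[pid], genes[pid] = sp, f"dg{sp}{j}"
        pure = pure_matrix(pd.DataFrame(rows).T[["expA", "expB"]])
        mix = mixture_matrix(pd.Series(mix_rows))
        homologs = HomologTable(pd.DataFrame(
            {"gene_a": [f"gA{i}" for i in range(5)],
             "gene_b": [f"gB{i}" for i in range(5)],
             "housekeeping": True}
        ))
        return pure, mix, pd.Series(species), pd.Series(genes), homologs

    def test_contaminated_pair_drives_stricter_threshold(self):
        pure, mix, species, genes, homologs = self._fixture()
        # at x=0.25 the quantile cutoff sits between the clean cross signal
        # (0.3) and the contaminant's (40); at x=0.4 the contaminant slips in
        diag = optimize_ssp_threshold(pure, mix, species, genes, homologs, [0.25, 0.4])
        table = diag.table.set_index("x")
        assert table.loc[0.4, "n_pairs"] == 5
        assert table.loc[0.25, "n_pairs"] == 4
        assert table.loc[0.25, "log2_variance"] < table.loc[0.4, "log2_variance"]
        assert diag.chosen_x == 0.25

    def test_single_candidate_chosen(self):
        pure, mix, species, genes, homologs = self._fixture()
        diag = optimize_ssp_threshold(pure, mix, species, genes, homologs, [0.25])
        assert diag.chosen_x == 0.25

    def test_identical_ssp_sets_tie_breaks_to_smaller_x(self):
        pure, mix, species, genes, homologs = self._fixture()
        # both cutoffs lie between the clean probes and the contaminant
        diag = optimize_ssp_threshold(pure, mix, species, genes, homologs, [0.2, 0.25])
        assert diag.chosen_x == 0.2

    def test_no_threshold_with_pairs_is_error(self):
        pure, mix, species, genes, _ = self._fixture()
        orphan = HomologTable(pd.DataFrame(
            {"gene_a": ["gX"], "gene_b": ["gY"], "housekeeping": [True]}
        ))
        with pytest.raises(ValidationError, match="threshold"):
            optimize_ssp_threshold(pure, mix, species, genes, orphan, [0.25, 0.4])
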