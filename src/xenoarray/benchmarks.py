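"""Seeded synthetic benchmark studies exercising the whole pipeline.

Each study generates data with the simulator, runs the relevant pipeline
stages, and returns tidy result tables.  They are shared between the test
suite and the reproduction script so both measure the same quantities the
same way.  Problem sizes are desk-scale by design; the methods note states
the sizes used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import annotate_deciles, evaluate_grid
from .cellularity import SspCriteria, cellularity_index, pair_housekeeping, select_ssp
from .align import best_hits_for_probes
from .goldstandard import build_gold_standard, total_signal_scale
from .models import builtin_models, predict_csh
from .simulate import (
    SimulationConfig,
    SyntheticDataset,
    simulate_dual_species,
    simulate_exposure,
    simulate_validation_experiment,
)
from .types import (
    AlignmentHit,
    ExpressionMatrix,
    GoldStandardLabeling,
    GoldStandardSpec,
)


# ---------------------------------------------------------------------------
# Rule-model recovery


def model_recovery_run(seed: int, n_probes: int = 5000, label_noise: float = 0.05) -> str:
    """One seeded run: synthetic best hits with ground-truth CSH defined by
    the model1-1 region plus symmetric label noise; returns the model the
    grid search selects."""
    rng = np.random.default_rng(seed)
    m11 = builtin_models()["model1-1"]
    hits = {}
    for i in range(n_probes):
        align = int(rng.integers(1, 61))
        mis = int(min(rng.integers(0, 13), align))
        hits[f"p{i}"] = AlignmentHit(f"p{i}", "t", align, mis, float(2 * align))
    truth = predict_csh(sorted(hits), hits, m11).predicted
    flip = rng.random(n_probes) < label_noise
    labelled = {
        pid for i, pid in enumerate(sorted(hits))
        if (pid in truth) != bool(flip[i])
    }
    gold = GoldStandardLabeling(
        GoldStandardSpec("GS2", 0.5),
        frozenset(labelled),
        frozenset(hits),
        pd.Series({p: float(p in labelled) for p in hits}),
    )
    result = evaluate_grid(builtin_models(), {"noisy_truth": gold}, hits)
    return result.selected_model


def model_recovery_study(seeds=range(1, 21), n_probes: int = 5000,
                         label_noise: float = 0.05) -> pd.DataFrame:
    rows = [
        {"seed": s, "selected_model": model_recovery_run(s, n_probes, label_noise)}
        for s in seeds
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shared pipeline pieces on simulated data


def split_pure(pure: ExpressionMatrix, probe_species: pd.Series, species: str):
    """(correct, erroneous, eligible) matrices for one probe species."""
    other = "A" if species == "B" else "B"
    probes = list(probe_species.index[probe_species == species])
    sub = pure.subset_probes(probes)
    correct = sub.subset_samples(sub.samples_where(exposed_species=species))
    erroneous = sub.subset_samples(sub.samples_where(exposed_species=other))
    return correct, erroneous, frozenset(probes)


def annotation_top_flags(dataset: SyntheticDataset, pure: ExpressionMatrix,
                         gs_kind: str = "GS3") -> frozenset:
    """Biologically flagged probes: top-5% of the per-species gold-standard
    statistic, exactly as the annotation stage produces them."""
    probe_species = dataset.probe_species()
    flagged = set()
    for species in ("A", "B"):
        correct, erroneous, eligible = split_pure(pure, probe_species, species)
        gold = build_gold_standard(GoldStandardSpec(gs_kind, 1.0), correct, erroneous, eligible)
        annot = annotate_deciles(gold.statistic)
        flagged |= set(annot.table.index[annot.table["csh_flag_top5"]])
    return frozenset(flagged)


def rule_model_predictions(dataset: SyntheticDataset, model_name: str = "model1-1") -> frozenset:
    """Cross-species best hits via the internal aligner, classified by the
    rule model in force."""
    model = builtin_models()[model_name]
    predicted = set()
    for species, other in (("A", "B"), ("B", "A")):
        hits = best_hits_for_probes(dataset.probes_of(species), dataset.transcripts_of(other))
        pred = predict_csh([p.probe_id for p in dataset.probes_of(species)], hits, model)
        predicted |= set(pred.predicted)
    return frozenset(predicted)


# ---------------------------------------------------------------------------
# Cellularity mixture recovery


def cellularity_mixture_study(
    fractions=tuple(np.round(np.arange(0.1, 0.95, 0.1), 2)),
    seeds=range(1, 11),
    n_replicates: int = 3,
    ssp_x: float = 0.9,
    n_genes: int = 60,
) -> pd.DataFrame:
    """Median log2 cellularity index across known mixture fractions.

    Per seed: one dataset (two probes per gene so each housekeeping gene
    offers an alternative SSP), pure exposures driving SSP selection with
    the annotation's top-5% flags as the CSH reference, then the index on
    each mixture.
    """
    rows = []
    for s in seeds:
        cfg = SimulationConfig(n_genes=n_genes, transcript_length=300,
                               probes_per_gene=2, seed=1000 + s)
        ds = simulate_dual_species(cfg)
        pure = simulate_validation_experiment(ds, n_replicates, seed=2000 + s)
        flags = annotation_top_flags(ds, pure)
        ssp = select_ssp(pure, ds.probe_species(), SspCriteria(ssp_x), flags)
        pairs = pair_housekeeping(ssp, ds.homologs, ds.probe_gene(),
                                  ds.probe_species(), pure)
        for k, frac in enumerate(fractions):
            mix = simulate_exposure(ds, float(frac), n_replicates, seed=3000 + 100 * s + k)
            est = cellularity_index(total_signal_scale(mix), pairs)
            rows.append({"seed": s, "fraction_a": float(frac), "n_pairs": est.n_pairs,
                         "median_log2_ratio": est.median_log2_ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SSP purity


def ssp_purity_study(seeds=range(1, 11), x: float = 0.05) -> pd.DataFrame:
    """Contamination of the four-criteria SSP set on data with ~10% strong
    cross-hybridizers (one in ten genes is a perfect homolog)."""
    rows = []
    for s in seeds:
        cfg = SimulationConfig(n_genes=100, transcript_length=300,
                               homolog_fraction=0.1, divergence=0.0, seed=4000 + s)
        ds = simulate_dual_species(cfg)
        pure = simulate_validation_experiment(ds, 3, seed=5000 + s)
        flags = annotation_top_flags(ds, pure)
        predicted = rule_model_predictions(ds)
        ssp = select_ssp(pure, ds.probe_species(), SspCriteria(x), flags, predicted)
        selected = ssp["A"] | ssp["B"]
        rows.append({
            "seed": s,
            "n_ssp": len(selected),
            "n_contaminated": len(selected & ds.true_csh),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pure-exposure separation


def pure_exposure_separation_study(seeds=range(1, 6), ssp_x: float = 0.9) -> pd.DataFrame:
    """Housekeeping-pair expression ratios under single-species exposure,
    emulating the six-array validation design."""
    rows = []
    for s in seeds:
        cfg = SimulationConfig(n_genes=60, transcript_length=300,
                               probes_per_gene=2, seed=6000 + s)
        ds = simulate_dual_species(cfg)
        pure = simulate_validation_experiment(ds, 3, seed=7000 + s)
        flags = annotation_top_flags(ds, pure)
        ssp = select_ssp(pure, ds.probe_species(), SspCriteria(ssp_x), flags)
        pairs = pair_housekeeping(ssp, ds.homologs, ds.probe_gene(),
                                  ds.probe_species(), pure)
        scaled = total_signal_scale(pure)
        only_a = scaled.subset_samples(scaled.samples_where(exposed_species="A"))
        only_b = scaled.subset_samples(scaled.samples_where(exposed_species="B"))
        est_a = cellularity_index(only_a, pairs)
        est_b = cellularity_index(only_b, pairs)
        rows.append({
            "seed": s,
            "n_pairs": est_a.n_pairs,
            "median_ratio_human_side": est_a.median_ratio,
            "median_ratio_mouse_side": 1.0 / est_b.median_ratio,
        })
    return pd.DataFrame(rows)
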