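"""End-to-end orchestration: simulate -> predict -> gold-standard ->
optimize -> annotate -> SSP -> cellularity, with a content-hash manifest.

All randomness flows from the single configured seed; identical config and
seed yield byte-identical artifacts and therefore identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import io as xio
from .align import best_hits_for_probes
from .annotate import annotate_deciles, evaluate_grid
from .cellularity import SspCriteria, cellularity_index, pair_housekeeping, select_ssp
from .goldstandard import build_gold_standard, total_signal_scale
from .models import builtin_models
from .simulate import (
    SimulationConfig,
    ground_truth_frame,
    simulate_dual_species,
    simulate_exposure,
    simulate_validation_experiment,
)
from .types import GoldStandardSpec, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulation": {"n_genes": 40, "transcript_length": 300},
    "n_replicates": 3,
    "gs_kind": "GS3",
    "x_grid": [0.05, 0.1, 0.2],
    "models": ["model1", "model2", "model3", "model1-1", "model1-2"],
    "annotation_x": 0.05,
    "ssp_x": 0.9,
    "mixture_fraction_a": 0.5,
}


@dataclass
class StageError(RuntimeError):
    stage: str
    cause: Exception

    def __str__(self) -> str:
        return f"stage {self.stage!r} failed: {self.cause}"


@dataclass
class RunResult:
    manifest_path: Path
    artifacts: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    failed_stage: Optional[str] = None


def load_config(path=None, overrides: Optional[dict] = None) -> dict:
    import yaml

    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if key == "simulation" and isinstance(value, dict):
                config["simulation"].update(value)
            else:
                config[key] = value
    for key, value in (overrides or {}).items():
        if value is not None:
            config[key] = value
    return config


def validate_config(config: dict) -> None:
    """Fail fast, before any stage runs."""
    for key in ("matrix_path", "meta_path", "blast_path"):
        path = config.get(key)
        if path is not None and not Path(path).exists():
            raise ValidationError(f"configured path does not exist: {key}={path}")
    SimulationConfig(seed=int(config.get("seed", 0)), **config.get("simulation", {}))
    known = set(builtin_models())
    unknown = set(config.get("models", [])) - known
    if unknown:
        raise ValidationError(f"unknown models {sorted(unknown)}; choose from {sorted(known)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_end_to_end(config: dict, out_dir) -> RunResult:
    """Run the whole synthetic-demo pipeline and write a manifest."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    artifacts: dict[str, str] = {}
    manifest_path = out / "manifest.json"

    def record(path: Path) -> None:
        artifacts[path.name] = _sha256(path)

    def write_manifest(failed: Optional[str] = None) -> None:
        payload = {"config": config, "artifacts": artifacts}
        if failed:
            payload["failed_stage"] = failed
        manifest_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    stage = "simulate"
    try:
        sim_cfg = SimulationConfig(seed=seed, **config.get("simulation", {}))
        dataset = simulate_dual_species(sim_cfg)
        xio.write_probe_fasta(dataset.probes, out / "probes.fasta")
        xio.write_transcript_fasta(dataset.transcripts, out / "transcripts.fasta")
        ground_truth_frame(dataset).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        xio.write_homolog_tsv(dataset.homologs, out / "homologs.tsv")
        for name in ("probes.fasta", "transcripts.fasta", "ground_truth.tsv", "homologs.tsv"):
            record(out / name)

        n_rep = int(config.get("n_replicates", 3))
        pure = simulate_validation_experiment(dataset, n_rep, seed=seed + 10)
        mix = simulate_exposure(
            dataset, float(config.get("mixture_fraction_a", 0.5)), n_rep, seed=seed + 20
        )
        xio.write_expression_tsv(pure, out / "expression_pure.tsv", out / "samples_pure.tsv")
        xio.write_expression_tsv(mix, out / "expression_mix.tsv", out / "samples_mix.tsv")
        for name in ("expression_pure.tsv", "samples_pure.tsv",
                     "expression_mix.tsv", "samples_mix.tsv"):
            record(out / name)

        stage = "predict"
        models = {name: builtin_models()[name] for name in config["models"]}
        best_hits = {}
        for species, other in (("A", "B"), ("B", "A")):
            best_hits.update(
                best_hits_for_probes(dataset.probes_of(species), dataset.transcripts_of(other))
            )
        hit_rows = [
            {
                "probe_id": h.probe_id, "subject_id": h.subject_id,
                "align_length": h.align_length, "mismatches": h.mismatches,
                "score": h.score,
            }
            for h in best_hits.values()
        ]
        hit_cols = ["probe_id", "subject_id", "align_length", "mismatches", "score"]
        pd.DataFrame(hit_rows, columns=hit_cols).sort_values("probe_id").to_csv(
            out / "best_hits.tsv", sep="\t", index=False
        )
        record(out / "best_hits.tsv")

        stage = "gold-standard"
        probe_species = dataset.probe_species()
        gs_kind = config.get("gs_kind", "GS3")
        per_species_gs = {}
        for species, other in (("A", "B"), ("B", "A")):
            probes_s = [p.probe_id for p in dataset.probes_of(species)]
            correct = pure.subset_probes(probes_s).subset_samples(
                pure.samples_where(exposed_species=species)
            )
            erroneous = pure.subset_probes(probes_s).subset_samples(
                pure.samples_where(exposed_species=other)
            )
            per_species_gs[species] = (correct, erroneous, frozenset(probes_s))

        stage = "optimize"
        grid_tables = []
        selected = {}
        for species, (correct, erroneous, eligible) in per_species_gs.items():
            gold_standards = {}
            for x in config["x_grid"]:
                spec = GoldStandardSpec(gs_kind, float(x))
                gold_standards[spec.label] = build_gold_standard(
                    spec, correct, erroneous, eligible
                )
            res = evaluate_grid(models, gold_standards, best_hits)
            tbl = res.table.assign(species=species)
            grid_tables.append(tbl)
            selected[species] = {"model": res.selected_model, "gold_standard": res.selected_gs}
        pd.concat(grid_tables).to_csv(out / "grid_search.tsv", sep="\t", index=False)
        (out / "selected.json").write_text(json.dumps(selected, indent=2, sort_keys=True))
        record(out / "grid_search.tsv")
        record(out / "selected.json")

        stage = "annotate"
        all_models = builtin_models()
        annot_parts = []
        annotation_x = float(config.get("annotation_x", 0.05))
        for species, (correct, erroneous, eligible) in per_species_gs.items():
            spec = GoldStandardSpec(gs_kind, annotation_x)
            gold = build_gold_standard(spec, correct, erroneous, eligible)
            preds = {
                name: predict_for(all_models[name], best_hits, gold.eligible_probes)
                for name in ("model1-1", "model1-2")
            }
            annot = annotate_deciles(gold.statistic, preds)
            annot_parts.append(annot.table)
        annot_table = pd.concat(annot_parts)
        annot_out = annot_table.reset_index()
        annot_out["species"] = annot_out["probe_id"].map(probe_species)
        annot_out["designer"] = "commercial"
        csh_flagged = frozenset(annot_table.index[annot_table["csh_flag_top5"]])

        stage = "ssp"
        criteria = SspCriteria(float(config.get("ssp_x", 0.9)))
        predicted = frozenset(
            annot_table.index[annot_table["pred_model1_1"]]
        )
        ssp_sets = select_ssp(pure, probe_species, criteria, csh_flagged, predicted)
        annot_out["ssp_flag"] = annot_out["probe_id"].isin(ssp_sets["A"] | ssp_sets["B"])
        xio.write_annotation_tsv(annot_out, out / "annotation.tsv")
        record(out / "annotation.tsv")

        stage = "cellularity"
        pairs = pair_housekeeping(
            ssp_sets, dataset.homologs, dataset.probe_gene(), probe_species, pure
        )
        est = cellularity_index(total_signal_scale(mix), pairs)
        report = {
            "n_pairs": est.n_pairs,
            "median_ratio": est.median_ratio,
            "median_log2_ratio": est.median_log2_ratio,
            "log2_variance": est.log2_variance,
            "true_mixture_fraction_a": float(config.get("mixture_fraction_a", 0.5)),
        }
        est.pair_table.to_csv(out / "cellularity_pairs.tsv", sep="\t", index=False)
        (out / "cellularity.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        record(out / "cellularity_pairs.tsv")
        record(out / "cellularity.json")
    except Exception as exc:
        write_manifest(failed=stage)
        raise StageError(stage, exc) from exc

    write_manifest()
    return RunResult(manifest_path, artifacts)


def predict_for(model, best_hits, universe):
    from .models import predict_csh

    return predict_csh(sorted(universe), best_hits, model)
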