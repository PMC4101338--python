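"""Species-specific probe selection and the stroma/cancer cellularity index.

In a xenograft, cancer transcripts are human (species A) and stromal
transcripts are mouse (species B).  Under the assumption that homologous
housekeeping genes are expressed at comparable per-cell levels in both
species, the median ratio of species-A SSP expression to species-B SSP
expression over homologous housekeeping pairs proxies the A:B mRNA
proportion — the in-silico cellularity index.

Ratios are computed on per-array total-signal-scaled *linear* intensities:
per-species variance-stabilized normalization would cancel exactly the
mixture signal the index is meant to measure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .goldstandard import LINEAR_FLOOR, replicate_mean
from .types import (
    CellularityEstimate,
    ExpressionMatrix,
    HomologTable,
    PredictionSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Housekeeping gene panel with validated species-specific probes on both
#: sides (human symbols; the mouse homologs share the symbol up to case).
DEFAULT_HOUSEKEEPING_GENES = (
    "RNASEH1", "PMPCB", "SFRS8", "PRDX6", "TRAPPC4", "MATR3", "NIPA2",
    "MRPL49", "NOL7", "VPS26A", "HNRPDL", "RPL39", "OSBP",
)


@dataclass(frozen=True)
class SspCriteria:
    """Parameters of the four species-specificity criteria.

    ``x`` is the quantile threshold of criterion 2: a probe's mean
    cross-species-exposure expression must fall below the x-quantile of all
    same-species probes' cross-species expressions ("SSP x").
    """

    x: float
    expression_floor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.x < 1.0:
            raise ValidationError("SSP threshold x must lie strictly in (0, 1)")


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    probe_a: str
    probe_b: str
    housekeeping: bool = True


def select_ssp(
    matrix: ExpressionMatrix,
    probe_species: pd.Series,
    criteria: SspCriteria,
    csh_flagged: Iterable = (),
    predicted_csh: Iterable = (),
) -> dict[str, frozenset]:
    """Select species-specific probes per species from pure-exposure arrays.

    A probe is retained iff it
      1. is positively expressed (> ``expression_floor``, linear) in every
         sample exposed to its own species' RNA,
      2. has mean wrong-species-exposure expression below the x-quantile of
         all same-species probes' wrong-species expressions,
      3. is not biologically flagged cross-hybridizing (``csh_flagged``), and
      4. is not rule-model predicted cross-hybridizing (``predicted_csh``).
    """
    if matrix.scale != "linear":
        raise ValidationError("select_ssp expects a linear-scale matrix")
    probe_species = probe_species.reindex(matrix.probe_ids)
    if probe_species.isna().any():
        raise ValidationError("every probe in the matrix needs a species assignment")
    csh_flagged = frozenset(csh_flagged)
    predicted_csh = frozenset(predicted_csh)
    out: dict[str, frozenset] = {}
    for species, other in (("A", "B"), ("B", "A")):
        own_samples = matrix.samples_where(exposed_species=species)
        cross_samples = matrix.samples_where(exposed_species=other)
        if not own_samples or not cross_samples:
            raise ValidationError(
                f"matrix lacks pure-{species} or pure-{other} exposure samples"
            )
        block = matrix.values.loc[probe_species == species]
        positively_expressed = (block[own_samples] > criteria.expression_floor).all(axis=1)
        cross_expr = block[cross_samples].mean(axis=1)
        cutoff = cross_expr.quantile(criteria.x)
        below_quantile = cross_expr <= cutoff
        keep = positively_expressed & below_quantile
        keep &= ~block.index.isin(csh_flagged)
        keep &= ~block.index.isin(predicted_csh)
        out[species] = frozenset(block.index[keep])
    return out


def pair_housekeeping(
    ssp_sets: Mapping[str, frozenset],
    homolog_table: HomologTable,
    probe_gene: pd.Series,
    probe_species: pd.Series,
    matrix: ExpressionMatrix,
    hk_genes: Optional[Sequence[str]] = None,
) -> list[HomologPair]:
    """One probe pair per homologous housekeeping gene with an SSP available
    in BOTH species; per gene and species the SSP with the highest mean
    intended-species expression is chosen.

    ``hk_genes`` restricts the panel by species-A gene id; by default the
    table's housekeeping flag is used.
    """
    pairs_df = homolog_table.housekeeping_pairs()
    if hk_genes is not None:
        pairs_df = homolog_table.pairs[homolog_table.pairs["gene_a"].isin(set(hk_genes))]
    chosen: list[HomologPair] = []
    for _, row in pairs_df.iterrows():
        pa = _best_probe_for_gene(row["gene_a"], "A", ssp_sets, probe_gene, probe_species, matrix)
        pb = _best_probe_for_gene(row["gene_b"], "B", ssp_sets, probe_gene, probe_species, matrix)
        if pa is None or pb is None:
            continue
        chosen.append(HomologPair(row["gene_a"], row["gene_b"], pa, pb,
                                  bool(row.get("housekeeping", True))))
    if not chosen:
        raise ValidationError(
            "no homologous housekeeping gene has species-specific probes in "
            "both species; consider relaxing the SSP threshold x"
        )
    return chosen


def _best_probe_for_gene(gene, species, ssp_sets, probe_gene, probe_species, matrix):
    candidates = [
        pid for pid in ssp_sets.get(species, frozenset())
        if probe_gene.get(pid) == gene and probe_species.get(pid) == species
    ]
    if not candidates:
        return None
    own = matrix.samples_where(exposed_species=species)
    if own:
        means = matrix.values.loc[candidates, own].mean(axis=1)
    else:  # mixture-only matrix: fall back to overall mean
        means = matrix.values.loc[candidates].mean(axis=1)
    # argmax with deterministic probe-id tie-break
    return means.sort_index().sort_values(ascending=False, kind="mergesort").index[0]


def cellularity_index(
    matrix: ExpressionMatrix, pairs: Sequence[HomologPair]
) -> CellularityEstimate:
    """Per-pair species-A/species-B expression ratios and their median.

    ``matrix`` must be linear-scale, background-subtracted and total-signal
    scaled (NOT per-species normalized), holding the replicates of a single
    exposure condition; replicates are averaged.  Pairs whose denominator
    stays at the clamp floor in all replicates are dropped (logged).
    """
    if matrix.scale != "linear":
        raise ValidationError("cellularity_index expects a linear-scale matrix")
    if not pairs:
        raise ValidationError("need at least one homolog pair")
    groups = matrix.sample_meta[["exposed_species", "mix_fraction_a", "channel"]]
    if len(groups.drop_duplicates()) > 1:
        raise ValidationError(
            "matrix mixes exposure conditions; subset to one condition first"
        )
    mean = replicate_mean(matrix).values.iloc[:, 0]
    rows = []
    n_dropped = 0
    for pr in pairs:
        num = float(mean.get(pr.probe_a, float("nan")))
        den = float(mean.get(pr.probe_b, float("nan")))
        if not (np.isfinite(num) and np.isfinite(den)) or den <= 0:
            n_dropped += 1
            continue
        num = max(num, LINEAR_FLOOR)
        den = max(den, LINEAR_FLOOR)
        ratio = num / den
        rows.append(
            {
                "gene_a": pr.gene_a, "gene_b": pr.gene_b,
                "probe_a": pr.probe_a, "probe_b": pr.probe_b,
                "expr_a": num, "expr_b": den,
                "ratio": ratio, "log2_ratio": math.log2(ratio),
            }
        )
    if not rows:
        raise ValidationError("all homolog pairs dropped; no usable denominators")
    if n_dropped:
        logger.info("cellularity_index: dropped %d pairs with unusable denominators", n_dropped)
    table = pd.DataFrame(rows)
    log2r = table["log2_ratio"].to_numpy()
    return CellularityEstimate(
        pair_table=table,
        median_ratio=float(table["ratio"].median()),
        median_log2_ratio=float(np.median(log2r)),
        log2_variance=float(np.var(log2r, ddof=1)) if len(log2r) > 1 else 0.0,
        n_pairs=len(table),
        n_dropped=n_dropped,
    )


@dataclass
class ThresholdDiagnostics:
    table: pd.DataFrame  # per candidate x: n_ssp_a, n_ssp_b, n_pairs, log2_variance, ...
    chosen_x: float
    estimate: CellularityEstimate
    pairs: list


def optimize_ssp_threshold(
    pure_matrix: ExpressionMatrix,
    ratio_matrix: ExpressionMatrix,
    probe_species: pd.Series,
    probe_gene: pd.Series,
    homolog_table: HomologTable,
    candidate_x: Sequence[float],
    csh_flagged: Iterable = (),
    predicted_csh: Iterable = (),
    hk_genes: Optional[Sequence[str]] = None,
) -> ThresholdDiagnostics:
    """Choose the SSP threshold x minimizing the variance of per-pair log2
    ratios (ties and near-degenerate candidates resolve to the smaller x).

    ``pure_matrix`` provides the pure-species exposures that drive SSP
    selection; ``ratio_matrix`` (one exposure condition) provides the
    expressions the index is computed from.
    """
    if len(candidate_x) < 1:
        raise ValidationError("need at least one candidate threshold")
    rows = []
    best = None
    for x in sorted(set(float(v) for v in candidate_x)):
        try:
            ssp = select_ssp(pure_matrix, probe_species, SspCriteria(x),
                             csh_flagged, predicted_csh)
            pairs = pair_housekeeping(ssp, homolog_table, probe_gene, probe_species,
                                      pure_matrix, hk_genes)
            est = cellularity_index(ratio_matrix, pairs)
        except ValidationError as exc:
            rows.append({"x": x, "n_ssp_a": 0, "n_ssp_b": 0, "n_pairs": 0,
                         "log2_variance": float("nan"), "median_log2_ratio": float("nan"),
                         "note": str(exc)})
            continue
        rows.append(
            {
                "x": x, "n_ssp_a": len(ssp["A"]), "n_ssp_b": len(ssp["B"]),
                "n_pairs": est.n_pairs, "log2_variance": est.log2_variance,
                "median_log2_ratio": est.median_log2_ratio, "note": "",
            }
        )
        if est.n_pairs >= 2 and (best is None or est.log2_variance < best[1]):
            best = (x, est.log2_variance, est, pairs)
    if best is None:
        raise ValidationError("no candidate threshold yields at least 2 homolog pairs")
    return ThresholdDiagnostics(pd.DataFrame(rows), best[0], best[2], best[3])
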