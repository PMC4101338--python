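"""Core domain types shared across the pipeline.

Species are abstracted as ``"A"`` and ``"B"``; in the xenograft application
A is human (cancer compartment) and B is mouse (stromal compartment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

VALID_SPECIES = ("A", "B")
VALID_DESIGNERS = ("commercial", "custom_v1", "custom_v2")
VALID_CHANNELS = ("red", "green", "single")
VALID_SCALES = ("linear", "log2")

_NT_ALPHABET = frozenset("ACGTN")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def _check_sequence(seq: str, owner: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise ValidationError(
            f"{owner}: sequence contains non-ACGTN characters {sorted(bad)}"
        )
    return seq


def _check_species(species: str, owner: str) -> str:
    if species not in VALID_SPECIES:
        raise ValidationError(f"{owner}: species must be one of {VALID_SPECIES}, got {species!r}")
    return species


@dataclass(frozen=True)
class ProbeRecord:
    """A 60-mer oligonucleotide probe with provenance and intended target."""

    probe_id: str
    species: str
    sequence: str
    target_id: str = ""
    designer: str = "commercial"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, f"probe {self.probe_id}"))
        _check_species(self.species, f"probe {self.probe_id}")
        if self.designer not in VALID_DESIGNERS:
            raise ValidationError(
                f"probe {self.probe_id}: designer must be one of {VALID_DESIGNERS}"
            )


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with its gene of origin."""

    transcript_id: str
    species: str
    sequence: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"transcript {self.transcript_id}: empty sequence")
        object.__setattr__(
            self, "sequence", _check_sequence(self.sequence, f"transcript {self.transcript_id}")
        )
        _check_species(self.species, f"transcript {self.transcript_id}")


@dataclass(frozen=True)
class AlignmentHit:
    """Best cross-species local-alignment hit for one probe.

    ``align_length`` counts alignment columns (including gap columns),
    ``mismatches`` counts substitution columns, ``score`` is the aligner's
    score (the bit score when read from BLAST tabular output).
    """

    probe_id: str
    subject_id: str
    align_length: int
    mismatches: int
    score: float
    subject_species: Optional[str] = None

    def __post_init__(self) -> None:
        if self.align_length < 0 or self.mismatches < 0:
            raise ValidationError(
                f"hit {self.probe_id}->{self.subject_id}: negative alignment fields"
            )
        if self.mismatches > self.align_length:
            raise ValidationError(
                f"hit {self.probe_id}->{self.subject_id}: mismatches "
                f"({self.mismatches}) exceed alignment length ({self.align_length})"
            )


REQUIRED_META_COLUMNS = ("exposed_species", "channel", "replicate")


class ExpressionMatrix:
    """Background-subtracted probe x sample intensities plus sample metadata.

    ``values`` is a probes-by-samples DataFrame; ``sample_meta`` is indexed by
    sample id and carries ``exposed_species`` ("A", "B" or "mixed"),
    ``mix_fraction_a`` (fraction of species-A RNA; NaN for pure exposures),
    ``channel`` ("red", "green" or "single") and ``replicate``.  ``scale``
    flags whether intensities are linear or log2 — no silent guessing.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame, scale: str = "linear"):
        if scale not in VALID_SCALES:
            raise ValidationError(f"scale must be one of {VALID_SCALES}, got {scale!r}")
        values = values.copy()
        sample_meta = sample_meta.copy()
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids in matrix: {dups[:5]}")
        missing_meta = [c for c in values.columns if c not in sample_meta.index]
        if missing_meta:
            raise ValidationError(f"sample columns without metadata: {missing_meta}")
        for col in REQUIRED_META_COLUMNS:
            if col not in sample_meta.columns:
                raise ValidationError(f"sample metadata missing required column {col!r}")
        if "mix_fraction_a" not in sample_meta.columns:
            sample_meta["mix_fraction_a"] = np.nan
        bad_exposure = set(sample_meta["exposed_species"]) - {"A", "B", "mixed"}
        if bad_exposure:
            raise ValidationError(f"invalid exposed_species values: {sorted(bad_exposure)}")
        bad_channel = set(sample_meta["channel"]) - set(VALID_CHANNELS)
        if bad_channel:
            raise ValidationError(f"invalid channel values: {sorted(bad_channel)}")
        if not np.issubdtype(values.to_numpy().dtype, np.number):
            raise ValidationError("expression values must be numeric")
        self.values = values.astype(float)
        self.sample_meta = sample_meta.loc[list(values.columns)]
        self.scale = scale

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches every keyword condition."""
        mask = pd.Series(True, index=self.sample_meta.index)
        for key, want in conditions.items():
            col = self.sample_meta[key]
            if key == "mix_fraction_a" and want is not None and not pd.isna(want):
                mask &= np.isclose(col.astype(float), float(want))
            else:
                mask &= col == want
        return list(self.sample_meta.index[mask])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.sample_meta.loc[sample_ids], self.scale)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.sample_meta, self.scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values, self.sample_meta, self.scale)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ExpressionMatrix({self.values.shape[0]} probes x "
            f"{self.values.shape[1]} samples, scale={self.scale})"
        )


@dataclass
class HomologTable:
    """Cross-species homologous gene pairs, optionally flagged housekeeping."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b, housekeeping (bool)

    def __post_init__(self) -> None:
        need = {"gene_a", "gene_b"}
        if not need <= set(self.pairs.columns):
            raise ValidationError(f"homolog table needs columns {sorted(need)}")
        if "housekeeping" not in self.pairs.columns:
            self.pairs = self.pairs.assign(housekeeping=False)
        dup = self.pairs.duplicated(subset=["gene_a", "gene_b"])
        if dup.any():
            raise ValidationError("duplicate homolog pairs in table")

    def housekeeping_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["housekeeping"]].reset_index(drop=True)


@dataclass
class GoldStandardSpec:
    """Which biological gold standard to build and at what top-fraction x.

    ``kind`` selects the ranking statistic; ``x`` is the "top x" fraction of
    eligible probes declared cross-hybridizing.  ``channel_floor``
    (log2) gates probe eligibility for GS4 only.
    """

    kind: str
    x: float
    channel_floor: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("GS1", "GS2", "GS3", "GS4"):
            raise ValidationError(f"unknown gold-standard kind {self.kind!r}")
        if not 0.0 <= self.x <= 1.0:
            raise ValidationError(f"x must lie in [0, 1], got {self.x}")

    @property
    def label(self) -> str:
        return f"{self.kind}.{self.x:g}"


@dataclass
class GoldStandardLabeling:
    """Probes declared biologically cross-hybridizing under a GS definition."""

    spec: GoldStandardSpec
    csh_probes: frozenset
    eligible_probes: frozenset
    statistic: pd.Series  # ranking statistic over eligible probes
    n_dropped: int = 0  # probes dropped for unusable denominators

    def __post_init__(self) -> None:
        if not self.csh_probes <= self.eligible_probes:
            raise ValidationError("csh_probes must be a subset of eligible_probes")


@dataclass
class PredictionSet:
    """Probes a rule model predicts to cross-hybridize."""

    model_name: str
    predicted: frozenset
    universe: frozenset
    clause_index: dict = field(default_factory=dict)  # probe_id -> satisfied clause

    def __post_init__(self) -> None:
        if not self.predicted <= self.universe:
            raise ValidationError("predicted probes must lie in the universe")


@dataclass
class EvaluationResult:
    """Confusion counts and F-score of one (model, gold standard) comparison."""

    model_name: str
    gs_label: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float


@dataclass
class CellularityEstimate:
    """Per-housekeeping-pair species expression ratios and their summary."""

    pair_table: pd.DataFrame  # columns: gene_a, gene_b, probe_a, probe_b, ratio, log2_ratio
    median_ratio: float
    median_log2_ratio: float
    log2_variance: float
    n_pairs: int
    n_dropped: int = 0
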