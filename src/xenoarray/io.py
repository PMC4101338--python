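"""Readers and writers for the plain-text formats the pipeline touches.

All readers validate strictly and raise :class:`~xenoarray.types.ValidationError`
(or ``ParseError`` for structural problems) rather than coercing; every
writer/reader pair is a lossless round trip.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AlignmentHit,
    ExpressionMatrix,
    HomologTable,
    ProbeRecord,
    TranscriptRecord,
    ValidationError,
)


class ParseError(ValueError):
    """Raised when a file is structurally malformed."""


# ---------------------------------------------------------------------------
# FASTA


def read_probe_fasta(path, species: str, designer: str = "commercial") -> list[ProbeRecord]:
    """Read probes from FASTA; the header token before the first whitespace
    becomes the probe id, an optional ``target=<id>`` in the description is
    honoured.  Sequences are uppercased; duplicate ids are rejected."""
    records: list[ProbeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate probe_id {rec.id!r} in {path}")
        seen.add(rec.id)
        target = ""
        for token in rec.description.split():
            if token.startswith("target="):
                target = token[len("target="):]
        records.append(
            ProbeRecord(
                probe_id=rec.id,
                species=species,
                sequence=str(rec.seq),
                target_id=target,
                designer=designer,
            )
        )
    return records


def write_probe_fasta(probes: Iterable[ProbeRecord], path) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.probe_id, description=f"target={p.target_id}")
        for p in probes
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_transcript_fasta(path, species: str) -> list[TranscriptRecord]:
    """Read transcripts from FASTA; ``gene=<id>`` in the description sets the
    gene of origin (defaults to the transcript id)."""
    out: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate transcript_id {rec.id!r} in {path}")
        seen.add(rec.id)
        gene = rec.id
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[len("gene="):]
        out.append(TranscriptRecord(rec.id, species, str(rec.seq), gene_id=gene))
    return out


def write_transcript_fasta(transcripts: Iterable[TranscriptRecord], path) -> None:
    recs = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description=f"gene={t.gene_id}")
        for t in transcripts
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(
    path,
    probe_index: Optional[Mapping[str, ProbeRecord]] = None,
    transcript_index: Optional[Mapping[str, TranscriptRecord]] = None,
) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output into best hits.

    Per (probe, subject species) only the highest-bitscore line is kept;
    ties break by larger alignment length, then lexicographic subject id.
    When ``probe_index``/``transcript_index`` are given, unknown query or
    subject ids are rejected and subject species are annotated.
    """
    best: dict[tuple[str, Optional[str]], AlignmentHit] = {}
    unknown_q: set[str] = set()
    unknown_s: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_OUTFMT6_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(_OUTFMT6_COLUMNS)} "
                    f"tab-separated columns, found {len(fields)}"
                )
            qseqid, sseqid = fields[0], fields[1]
            if probe_index is not None and qseqid not in probe_index:
                unknown_q.add(qseqid)
                continue
            if transcript_index is not None and sseqid not in transcript_index:
                unknown_s.add(sseqid)
                continue
            try:
                length = int(fields[3])
                mismatch = int(fields[4])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            subject_species = (
                transcript_index[sseqid].species if transcript_index is not None else None
            )
            hit = AlignmentHit(qseqid, sseqid, length, mismatch, bitscore, subject_species)
            key = (qseqid, subject_species)
            cur = best.get(key)
            if cur is None or _hit_sort_key(hit) > _hit_sort_key(cur):
                best[key] = hit
    if unknown_q or unknown_s:
        raise ValidationError(
            f"{path}: unknown query ids {sorted(unknown_q)[:5]}, "
            f"unknown subject ids {sorted(unknown_s)[:5]}"
        )
    return [best[k] for k in sorted(best)]


def _hit_sort_key(hit: AlignmentHit):
    # higher score wins; then longer alignment; then lexicographically
    # *smaller* subject id (encoded negatively so max() picks it)
    return (hit.score, hit.align_length, _NegStr(hit.subject_id))


class _NegStr(str):
    """String whose ordering is reversed, for descending-lex tie-breaks."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_tsv(matrix_path, meta_path) -> ExpressionMatrix:
    """Read a probe x sample intensity TSV plus a sample-metadata TSV.

    The matrix file's first column is ``probe_id``; the metadata file has one
    row per sample column and a ``scale`` column (identical in every row)
    flagging linear vs log2 intensities.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    for col in matrix.columns:
        coerced = pd.to_numeric(matrix[col], errors="coerce")
        if coerced.isna().any() and not matrix[col].isna().any():
            bad = matrix.index[coerced.isna()][0]
            raise ParseError(f"{matrix_path}: non-numeric cell at probe {bad!r}, sample {col!r}")
        matrix[col] = coerced
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if "scale" not in meta.columns:
        raise ValidationError(f"{meta_path}: metadata must carry a 'scale' column")
    scales = set(meta["scale"])
    if len(scales) != 1:
        raise ValidationError(f"{meta_path}: inconsistent scale flags {sorted(scales)}")
    scale = scales.pop()
    missing = [c for c in matrix.columns if c not in meta.index]
    if missing:
        raise ValidationError(f"{meta_path}: sample columns without metadata rows: {missing}")
    for col in ("exposed_species", "channel", "replicate"):
        if col not in meta.columns:
            raise ValidationError(f"{meta_path}: metadata missing column {col!r}")
    return ExpressionMatrix(matrix, meta.drop(columns=["scale"]), scale)


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path, meta_path) -> None:
    matrix.values.rename_axis("probe_id").to_csv(matrix_path, sep="\t", float_format="%.10g")
    meta = matrix.sample_meta.copy()
    meta["scale"] = matrix.scale
    meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Annotation tables

ANNOTATION_COLUMNS = [
    "probe_id", "species", "designer", "csh_level", "csh_flag_top5",
    "pred_model1_1", "pred_model1_2", "ssp_flag",
]


def write_annotation_tsv(annotation_table: pd.DataFrame, path) -> None:
    """Write the per-probe annotation in a deterministic column and row order.

    ``csh_level`` must lie in 1..10 (level 1 = most cross-hybridization prone
    decile); rows are sorted by probe id ascending.
    """
    table = annotation_table.copy()
    if "probe_id" not in table.columns:
        table = table.reset_index().rename(columns={table.index.name or "index": "probe_id"})
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns: {missing}")
    levels = table["csh_level"]
    if ((levels < 1) | (levels > 10)).any():
        bad = table.loc[(levels < 1) | (levels > 10), "probe_id"].tolist()
        raise ValidationError(f"csh_level outside 1..10 for probes {bad[:5]}")
    out = table[ANNOTATION_COLUMNS].sort_values("probe_id").reset_index(drop=True)
    for col in ("csh_flag_top5", "pred_model1_1", "pred_model1_2", "ssp_flag"):
        out[col] = out[col].astype(bool)
    out.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: annotation file missing columns {missing}")
    for col in ("csh_flag_top5", "pred_model1_1", "pred_model1_2", "ssp_flag"):
        table[col] = table[col].astype(bool)
    return table


# ---------------------------------------------------------------------------
# Homolog and housekeeping tables


def read_homolog_tsv(path) -> HomologTable:
    """Read (gene_a, gene_b[, housekeeping]) pairs."""
    table = pd.read_csv(path, sep="\t")
    if "housekeeping" in table.columns:
        table["housekeeping"] = table["housekeeping"].astype(bool)
    return HomologTable(table)


def write_homolog_tsv(table: HomologTable, path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene id per line (or first TSV column); '#' comments skipped."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line.split("\t")[0])
    return genes
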