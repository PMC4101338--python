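"""Window-scanning species-specific probe redesign with a probe check.

Replaces a vendor probe-design workflow with a transparent rule: enumerate
60-mer sense windows of the target transcript from the 3' end moving 5'
(arrays label the 3' end best, so the most 3' acceptable window wins), and
return the first window that passes the specificity check.  The check fails
a candidate whose best within-species off-target hit or best cross-species
hit satisfies the rule model in force, or that carries a homopolymer run
longer than 10 nt (synthesis constraint).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import best_cross_species_hit
from .models import CshRuleModel, apply_rule_model
from .types import AlignmentHit, ProbeRecord, TranscriptRecord, ValidationError

MAX_HOMOPOLYMER_RUN = 10
_HOMOPOLYMER = re.compile(r"A{11,}|C{11,}|G{11,}|T{11,}")


@dataclass(frozen=True)
class CandidateProbe:
    """A 60-mer window of a transcript proposed as a probe."""

    sequence: str
    transcript_id: str
    window_start: int  # 0-based on the transcript
    distance_to_3prime: int

    @property
    def probe_length(self) -> int:
        return len(self.sequence)


@dataclass
class ProbeCheckResult:
    passed: bool
    offending_hits: list[AlignmentHit] = field(default_factory=list)
    reason: str = ""


@dataclass
class DesignReport:
    """Outcome of a design attempt: the accepted probe or, on failure, the
    rejecting evidence for every scanned window."""

    target_id: str
    probe: Optional[CandidateProbe]
    rejected: list[tuple[CandidateProbe, ProbeCheckResult]] = field(default_factory=list)

    @property
    def succeeded(self) -> bool:
        return self.probe is not None


def probe_check(
    candidate: CandidateProbe,
    same_species_transcriptome: Sequence[TranscriptRecord],
    other_species_transcriptome: Sequence[TranscriptRecord],
    rule_model: CshRuleModel,
    intended_gene: Optional[str] = None,
) -> ProbeCheckResult:
    """Accept a candidate unless a rule-model-satisfying hit exists
    within-species (off the intended gene) or cross-species, or the sequence
    violates the homopolymer cap."""
    if _HOMOPOLYMER.search(candidate.sequence):
        return ProbeCheckResult(False, [], f"homopolymer run > {MAX_HOMOPOLYMER_RUN} nt")
    if intended_gene is None:
        gene_of = {t.transcript_id: t.gene_id for t in same_species_transcriptome}
        intended_gene = gene_of.get(candidate.transcript_id, candidate.transcript_id)
    off_targets = [
        t for t in same_species_transcriptome if t.gene_id != intended_gene
    ]
    probe = ProbeRecord(
        probe_id=f"cand_{candidate.transcript_id}_{candidate.window_start}",
        species=_species_of(candidate.transcript_id, same_species_transcriptome),
        sequence=candidate.sequence,
        target_id=candidate.transcript_id,
        designer="custom_v2",
    )
    for label, transcriptome in (("within-species", off_targets),
                                 ("cross-species", other_species_transcriptome)):
        hit = best_cross_species_hit(probe, transcriptome)
        if hit is not None and apply_rule_model(rule_model, hit):
            return ProbeCheckResult(False, [hit], f"{label} hit satisfies {rule_model.name}")
    return ProbeCheckResult(True)


def _species_of(transcript_id: str, transcriptome: Sequence[TranscriptRecord]) -> str:
    for t in transcriptome:
        if t.transcript_id == transcript_id:
            return t.species
    return "A"


def design_ssp(
    target_transcript: TranscriptRecord,
    same_species_transcriptome: Sequence[TranscriptRecord],
    other_species_transcriptome: Sequence[TranscriptRecord],
    rule_model: CshRuleModel,
    probe_length: int = 60,
    step: int = 1,
) -> DesignReport:
    """Design one species-specific probe for a target transcript.

    Windows are tried strictly from the 3' end moving 5' in ``step``-nt
    decrements; the first window passing :func:`probe_check` is returned.
    When none passes, the report lists the rejecting hit per window.
    """
    seq = target_transcript.sequence
    if len(seq) < probe_length:
        raise ValidationError(
            f"transcript {target_transcript.transcript_id} shorter than probe length"
        )
    if target_transcript.transcript_id not in {
        t.transcript_id for t in same_species_transcriptome
    }:
        raise ValidationError(
            f"target {target_transcript.transcript_id} not in its own transcriptome"
        )
    report = DesignReport(target_transcript.transcript_id, None)
    for start in range(len(seq) - probe_length, -1, -step):
        candidate = CandidateProbe(
            sequence=seq[start : start + probe_length],
            transcript_id=target_transcript.transcript_id,
            window_start=start,
            distance_to_3prime=len(seq) - (start + probe_length),
        )
        result = probe_check(
            candidate,
            same_species_transcriptome,
            other_species_transcriptome,
            rule_model,
            intended_gene=target_transcript.gene_id,
        )
        if result.passed:
            report.probe = candidate
            return report
        report.rejected.append((candidate, result))
    return report
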