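"""Synthetic dual-species hybridization data with known ground truth.

The generator emulates a two-species spotted-oligo experiment: two
transcriptomes with homologous gene pairs at controlled sequence divergence,
sense-oriented 60-mer probes taken from the 3' end of their target, and
per-array intensities under pure-species or mixed-RNA exposure with
multiplicative (log-normal) noise over an additive residual background.

Probe-transcript duplex strength is modelled as an exponential of the best
ungapped local alignment score (matches minus ``mismatch_weight`` times
mismatches), normalized so a probe's affinity to its intended target is
exactly 1.0; duplexes whose longest exact matched run is shorter than
``min_duplex`` nucleotides contribute nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .types import (
    ExpressionMatrix,
    HomologTable,
    ProbeRecord,
    TranscriptRecord,
    ValidationError,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dual-species experiment.

    Defaults model a human/mouse-like setting: most genes have a homolog,
    coding-level nucleotide divergence around 15%, one sense 60-mer probe per
    gene near the 3' end, and a 13-gene housekeeping panel shared between the
    species (homologous pairs share an abundance, mirroring the constitutive-
    expression assumption the cellularity index relies on).
    """

    n_genes: int = 120
    homolog_fraction: float = 0.8
    divergence: float = 0.15
    transcript_length: int = 400
    probes_per_gene: int = 1
    probe_length: int = 60
    affinity_slope: float = 0.25  # lambda: exponent per unit alignment score
    mismatch_weight: float = 2.0  # kappa: mismatch penalty in score units
    min_duplex: int = 18  # alpha: shortest exact run that can seed a duplex
    background: float = 0.5  # residual linear intensity after subtraction
    noise_sd: float = 0.25  # log2-scale multiplicative noise sd
    n_housekeeping: int = 13
    abundance_mean: float = 200.0  # linear-scale typical transcript abundance
    abundance_sd_log2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.homolog_fraction <= 1.0:
            raise ValidationError("homolog_fraction must lie in [0, 1]")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValidationError("divergence must lie in [0, 1]")
        if self.affinity_slope <= 0 or self.mismatch_weight <= 0:
            raise ValidationError("affinity_slope and mismatch_weight must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.min_duplex > self.probe_length:
            raise ValidationError("min_duplex cannot exceed probe_length")
        if self.transcript_length < self.probe_length * self.probes_per_gene:
            raise ValidationError("transcript too short for the requested probes")
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ValidationError("n_genes and probes_per_gene must be >= 1")

    @property
    def detection_floor(self) -> float:
        """Affinity above which a cross-species duplex counts as true CSH:
        any perfect duplex strictly longer than ``min_duplex`` exceeds it."""
        return math.exp(self.affinity_slope * (self.min_duplex - self.probe_length))


@dataclass
class SyntheticDataset:
    """Simulated transcriptomes, probes and their ground-truth duplex map."""

    config: SimulationConfig
    transcripts: list[TranscriptRecord]
    probes: list[ProbeRecord]
    abundance: dict[str, float]  # gene_id -> linear abundance (shared by homolog pairs)
    affinity: dict[str, dict[str, float]]  # probe_id -> {transcript_id: affinity}
    true_csh: frozenset
    homologs: HomologTable

    def transcripts_of(self, species: str) -> list[TranscriptRecord]:
        return [t for t in self.transcripts if t.species == species]

    def probes_of(self, species: str) -> list[ProbeRecord]:
        return [p for p in self.probes if p.species == species]

    def probe_species(self) -> pd.Series:
        return pd.Series({p.probe_id: p.species for p in self.probes})

    def probe_gene(self) -> pd.Series:
        gene_of = {t.transcript_id: t.gene_id for t in self.transcripts}
        return pd.Series({p.probe_id: gene_of[p.target_id] for p in self.probes})

    def max_cross_affinity(self, probe) -> float:
        if not hasattr(probe, "probe_id"):
            probe = next(p for p in self.probes if p.probe_id == probe)
        species_of = {t.transcript_id: t.species for t in self.transcripts}
        return max(
            (a for tid, a in self.affinity[probe.probe_id].items()
             if species_of[tid] != probe.species),
            default=0.0,
        )

    def max_cross_affinity_zero(self, probe) -> bool:
        return self.max_cross_affinity(probe) == 0.0


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _ungapped_affinity(
    probe_seq: str, transcript_seq: str, cfg: SimulationConfig
) -> float:
    """Best ungapped local alignment affinity over all offsets (same strand).

    Score = matches - kappa * mismatches (Kadane per offset); zero unless the
    longest exact matched run reaches ``min_duplex``.  Affinity is normalized
    to 1.0 for a perfect full-length duplex.
    """
    L = cfg.probe_length
    pad = "X" * (L - 1)
    padded = np.array(list(pad + transcript_seq + pad))
    windows = sliding_window_view(padded, L)  # (T + L - 1, L)
    eq = windows == np.array(list(probe_seq))
    rows = eq.shape[0]
    cur = np.zeros(rows)
    best = np.zeros(rows)
    run = np.zeros(rows)
    maxrun = np.zeros(rows)
    for c in range(L):
        s = np.where(eq[:, c], 1.0, -cfg.mismatch_weight)
        cur = np.maximum(s, cur + s)
        best = np.maximum(best, cur)
        run = np.where(eq[:, c], run + 1, 0.0)
        maxrun = np.maximum(maxrun, run)
    if maxrun.max() < cfg.min_duplex:
        return 0.0
    return math.exp(cfg.affinity_slope * (best.max() - L))


def simulate_dual_species(config: SimulationConfig) -> SyntheticDataset:
    """Generate transcriptomes, probes and the ground-truth affinity map.

    Species-A transcripts are uniform random; the first
    ``homolog_fraction * n_genes`` species-B genes are copies of their A
    partner with i.i.d. substitutions at rate ``divergence``, the rest are
    independent.  Probes are exact sense windows nearest the 3' end of their
    target.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_hom = int(math.floor(cfg.homolog_fraction * cfg.n_genes))

    transcripts: list[TranscriptRecord] = []
    pairs = []
    for i in range(cfg.n_genes):
        gene_a, gene_b = f"gA{i:04d}", f"gB{i:04d}"
        seq_a = _random_sequence(rng, cfg.transcript_length)
        transcripts.append(TranscriptRecord(f"tA{i:04d}", "A", seq_a, gene_a))
        if i < n_hom:
            seq_b = _mutate(rng, seq_a, cfg.divergence)
            pairs.append((gene_a, gene_b, i < min(cfg.n_housekeeping, n_hom)))
        else:
            seq_b = _random_sequence(rng, cfg.transcript_length)
        transcripts.append(TranscriptRecord(f"tB{i:04d}", "B", seq_b, gene_b))

    probes: list[ProbeRecord] = []
    for t in transcripts:
        for k in range(cfg.probes_per_gene):
            start = len(t.sequence) - cfg.probe_length * (k + 1)
            window = t.sequence[start : start + cfg.probe_length]
            probes.append(
                ProbeRecord(
                    probe_id=f"p{t.species}{t.gene_id[2:]}_{k}",
                    species=t.species,
                    sequence=window,
                    target_id=t.transcript_id,
                    designer="commercial",
                )
            )

    # abundance: homologous pairs share one draw (constitutive-expression
    # assumption); unpaired genes draw independently
    log2_mean = math.log2(cfg.abundance_mean)
    abundance: dict[str, float] = {}
    for i in range(cfg.n_genes):
        a = 2.0 ** rng.normal(log2_mean, cfg.abundance_sd_log2)
        abundance[f"gA{i:04d}"] = a
        if i < n_hom:
            abundance[f"gB{i:04d}"] = a
        else:
            abundance[f"gB{i:04d}"] = 2.0 ** rng.normal(log2_mean, cfg.abundance_sd_log2)

    affinity = _affinity_table(probes, transcripts, cfg)

    species_of = {t.transcript_id: t.species for t in transcripts}
    true_csh = frozenset(
        p.probe_id
        for p in probes
        if max(
            (a for tid, a in affinity[p.probe_id].items() if species_of[tid] != p.species),
            default=0.0,
        )
        > cfg.detection_floor
    )

    homologs = HomologTable(pd.DataFrame(pairs, columns=["gene_a", "gene_b", "housekeeping"]))
    return SyntheticDataset(cfg, transcripts, probes, abundance, affinity, true_csh, homologs)


def _affinity_table(
    probes: list[ProbeRecord],
    transcripts: list[TranscriptRecord],
    cfg: SimulationConfig,
) -> dict[str, dict[str, float]]:
    """Sparse probe x transcript affinities via an exact alpha-mer index.

    A duplex needs an exact matched run of at least ``min_duplex`` nt, and
    any such run contains a shared ``min_duplex``-mer on the same diagonal,
    so only k-mer-sharing pairs can have nonzero affinity.
    """
    k = cfg.min_duplex
    index: dict[str, set[int]] = {}
    for ti, t in enumerate(transcripts):
        seq = t.sequence
        for j in range(len(seq) - k + 1):
            index.setdefault(seq[j : j + k], set()).add(ti)
    table: dict[str, dict[str, float]] = {}
    for p in probes:
        candidates: set[int] = set()
        for j in range(len(p.sequence) - k + 1):
            candidates |= index.get(p.sequence[j : j + k], set())
        row: dict[str, float] = {}
        for ti in sorted(candidates):
            t = transcripts[ti]
            a = _ungapped_affinity(p.sequence, t.sequence, cfg)
            if a > 0.0:
                row[t.transcript_id] = a
        table[p.probe_id] = row
    return table


Exposure = Union[str, float]


def _exposure_fractions(exposure: Exposure) -> tuple[float, float, str, float]:
    """(fraction_A, fraction_B, exposed_species label, mix_fraction_a)."""
    if exposure == "A":
        return 1.0, 0.0, "A", float("nan")
    if exposure == "B":
        return 0.0, 1.0, "B", float("nan")
    p = float(exposure)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"mixture fraction must lie in [0, 1], got {p}")
    return p, 1.0 - p, "mixed", p


def expected_signal(dataset: SyntheticDataset, exposure: Exposure) -> pd.Series:
    """Noise-free linear signal per probe under one exposure."""
    cfg = dataset.config
    fa, fb, _, _ = _exposure_fractions(exposure)
    gene_of = {t.transcript_id: t.gene_id for t in dataset.transcripts}
    species_of = {t.transcript_id: t.species for t in dataset.transcripts}
    out = {}
    for p in dataset.probes:
        signal = cfg.background
        for tid, aff in dataset.affinity[p.probe_id].items():
            frac = fa if species_of[tid] == "A" else fb
            signal += frac * dataset.abundance[gene_of[tid]] * aff
        out[p.probe_id] = signal
    return pd.Series(out, name="signal")


def simulate_exposure(
    dataset: SyntheticDataset,
    exposure: Exposure,
    n_replicates: int = 3,
    seed: int = 0,
    channel: str = "single",
    sample_prefix: Optional[str] = None,
) -> ExpressionMatrix:
    """Simulate replicate arrays under one RNA exposure.

    Linear signal per probe is ``background + sum_t c_t * affinity``, with
    transcript concentrations ``c_t`` scaled by the species fractions of the
    exposure, times independent log-normal noise ``exp(N(0, noise_sd*ln2))``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    cfg = dataset.config
    fa, fb, exposed, mix_a = _exposure_fractions(exposure)
    base = expected_signal(dataset, exposure)
    rng = np.random.default_rng(seed)
    if sample_prefix is None:
        sample_prefix = exposed if exposed != "mixed" else f"mix{fa:g}"
    cols = {}
    meta_rows = {}
    for r in range(1, n_replicates + 1):
        noise = np.exp(rng.normal(0.0, cfg.noise_sd * math.log(2), size=len(base)))
        name = f"{sample_prefix}_r{r}"
        cols[name] = base.to_numpy() * noise
        meta_rows[name] = {
            "exposed_species": exposed,
            "mix_fraction_a": mix_a,
            "channel": channel,
            "replicate": r,
        }
    values = pd.DataFrame(cols, index=base.index)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return ExpressionMatrix(values, meta, scale="linear")


def simulate_validation_experiment(
    dataset: SyntheticDataset, n_replicates: int = 3, seed: int = 0
) -> ExpressionMatrix:
    """Six-array style single-channel design: pure-A and pure-B exposures."""
    m_a = simulate_exposure(dataset, "A", n_replicates, seed=seed)
    m_b = simulate_exposure(dataset, "B", n_replicates, seed=seed + 1)
    return concat_matrices([m_a, m_b])


def simulate_initial_experiment(
    dataset: SyntheticDataset, seed: int = 0, n_replicates: int = 1
) -> ExpressionMatrix:
    """Dual-channel design: two arrays, red channel pure-species, green
    channel an equal human/mouse pool on both."""
    parts = [
        simulate_exposure(dataset, "A", n_replicates, seed=seed, channel="red",
                          sample_prefix="arr1_red"),
        simulate_exposure(dataset, 0.5, n_replicates, seed=seed + 1, channel="green",
                          sample_prefix="arr1_green"),
        simulate_exposure(dataset, "B", n_replicates, seed=seed + 2, channel="red",
                          sample_prefix="arr2_red"),
        simulate_exposure(dataset, 0.5, n_replicates, seed=seed + 3, channel="green",
                          sample_prefix="arr2_green"),
    ]
    return concat_matrices(parts)


def concat_matrices(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    scales = {m.scale for m in matrices}
    if len(scales) != 1:
        raise ValidationError(f"cannot concatenate matrices of mixed scales {sorted(scales)}")
    values = pd.concat([m.values for m in matrices], axis=1)
    meta = pd.concat([m.sample_meta for m in matrices], axis=0)
    return ExpressionMatrix(values, meta, scales.pop())


def ground_truth_frame(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-probe ground truth: species, gene, true-CSH flag, max cross affinity."""
    rows = []
    for p in dataset.probes:
        rows.append(
            {
                "probe_id": p.probe_id,
                "species": p.species,
                "target_id": p.target_id,
                "true_csh": p.probe_id in dataset.true_csh,
                "max_cross_affinity": dataset.max_cross_affinity(p),
            }
        )
    return pd.DataFrame(rows).sort_values("probe_id").reset_index(drop=True)
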