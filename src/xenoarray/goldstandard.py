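"""Expression preprocessing and biological gold standards of cross-hybridization.

A gold standard declares the top-x fraction of eligible probes, ranked by a
statistic measured under *erroneous* exposure (RNA of the other species), as
biologically cross-hybridizing:

* GS1 — dual-channel relative ratio: (red/green under erroneous exposure)
  divided by (red/green under correct exposure);
* GS2 — absolute erroneous-exposure expression;
* GS3 — erroneous-exposure expression divided by correct-exposure expression;
* GS4 — as GS2, restricted to probes whose log2 green-channel expression
  under both exposures exceeds a floor (default 4).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GoldStandardLabeling,
    GoldStandardSpec,
    ValidationError,
)

logger = logging.getLogger(__name__)

LINEAR_FLOOR = 0.01  # clamp for background-subtracted values before ratios


class NoPooledSamplesError(ValidationError):
    """Raised when the pooled-RNA inclusion filter cannot be applied."""


def inclusion_filter(matrix: ExpressionMatrix, threshold: float = 1.0) -> frozenset:
    """Probes whose minimum intensity over all pooled-RNA samples exceeds
    ``threshold`` (default 1, linear scale, background already subtracted).

    Probes below it vary too widely between repeats to carry signal evidence.
    """
    if matrix.scale != "linear":
        raise ValidationError("inclusion_filter expects a linear-scale matrix")
    pooled = matrix.samples_where(exposed_species="mixed")
    if not pooled:
        raise NoPooledSamplesError(
            "no pooled-RNA (mixed-exposure) samples in the matrix; for "
            "single-channel designs treat all probes as eligible instead"
        )
    mins = matrix.values[pooled].min(axis=1)
    return frozenset(mins.index[mins > threshold])


def total_signal_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each array so its total signal equals the across-array mean total.

    Preserves within-array ratios; appropriate before cross-species ratio
    estimation where per-species normalization would cancel the signal.
    """
    if matrix.scale != "linear":
        raise ValidationError("total_signal_scale expects a linear-scale matrix")
    totals = matrix.values.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("array with non-positive total signal")
    factors = totals.mean() / totals
    return ExpressionMatrix(matrix.values * factors, matrix.sample_meta, "linear")


def stabilize_and_log(
    matrix: ExpressionMatrix,
    per_species: bool = False,
    probe_species: pd.Series | None = None,
) -> ExpressionMatrix:
    """Variance-stabilizing generalized-log transform to the log2 scale.

    Each array is affinely calibrated to a common location/spread (probe
    median and MAD across the block), then passed through
    ``glog2(x) = log2((x + sqrt(x^2 + c^2)) / 2)`` with ``c`` the common
    spread — an arsinh-style transform that is ~log2 for large intensities
    and tames the variance of near-background ones.  With
    ``per_species=True`` the species-A and species-B probe blocks are
    calibrated independently (controls for RNA-proportion differences, at the
    price of cancelling any between-species signal).
    """
    if matrix.scale == "log2":
        raise ValidationError("matrix is already log2; refusing to transform twice")
    values = matrix.values
    if per_species:
        if probe_species is None:
            raise ValidationError("per_species=True requires a probe_species series")
        probe_species = probe_species.reindex(values.index)
        if probe_species.isna().any():
            missing = values.index[probe_species.isna()].tolist()
            raise ValidationError(f"probes without species assignment: {missing[:5]}")
        blocks = []
        for sp in sorted(probe_species.unique()):
            block = values.loc[probe_species == sp]
            blocks.append(_glog_block(block))
        out = pd.concat(blocks).loc[values.index]
    else:
        out = _glog_block(values)
    return ExpressionMatrix(out, matrix.sample_meta, "log2")


def _glog_block(values: pd.DataFrame) -> pd.DataFrame:
    med = values.median(axis=0)
    mad = (values - med).abs().median(axis=0)
    ref_med = float(np.median(med))
    ref_mad = float(np.median(mad))
    calibrated = values.copy()
    for col in values.columns:
        if mad[col] > 0 and ref_mad > 0:
            calibrated[col] = (values[col] - med[col]) / mad[col] * ref_mad + ref_med
        else:
            calibrated[col] = values[col] - med[col] + ref_med
    c = ref_mad if ref_mad > 0 else 1.0
    arr = calibrated.to_numpy()
    glog = np.log2((arr + np.sqrt(arr * arr + c * c)) / 2.0)
    return pd.DataFrame(glog, index=values.index, columns=values.columns)


def replicate_mean(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate columns to one arithmetic mean per exposure group
    (grouping key: exposed species, mixture fraction and channel), on the
    matrix's current scale."""
    meta = matrix.sample_meta
    keys = meta.apply(
        lambda r: (
            r["exposed_species"],
            round(float(r["mix_fraction_a"]), 6) if pd.notna(r["mix_fraction_a"]) else None,
            r["channel"],
        ),
        axis=1,
    )
    cols = {}
    meta_rows = {}
    for key in sorted(set(keys), key=str):
        members = meta.index[keys == key]
        exposed, mix_a, channel = key
        name = _group_name(exposed, mix_a, channel)
        cols[name] = matrix.values[list(members)].mean(axis=1)
        meta_rows[name] = {
            "exposed_species": exposed,
            "mix_fraction_a": mix_a if mix_a is not None else float("nan"),
            "channel": channel,
            "replicate": 0,
        }
    return ExpressionMatrix(
        pd.DataFrame(cols, index=matrix.values.index),
        pd.DataFrame.from_dict(meta_rows, orient="index"),
        matrix.scale,
    )


def _group_name(exposed: str, mix_a, channel: str) -> str:
    base = exposed if exposed != "mixed" else f"mix{mix_a:g}"
    return base if channel == "single" else f"{base}_{channel}"


def _channel_column(matrix: ExpressionMatrix, channel: str) -> pd.Series:
    cols = matrix.samples_where(channel=channel)
    if not cols:
        raise ValidationError(f"matrix has no {channel!r}-channel samples")
    return matrix.values[cols].mean(axis=1)


def _single_or_red(matrix: ExpressionMatrix) -> pd.Series:
    red = matrix.samples_where(channel="red")
    if red:
        return matrix.values[red].mean(axis=1)
    return matrix.values.mean(axis=1)


def build_gold_standard(
    spec: GoldStandardSpec,
    matrix_correct: ExpressionMatrix,
    matrix_erroneous: ExpressionMatrix,
    eligible,
) -> GoldStandardLabeling:
    """Construct a gold-standard labeling at threshold ``spec.x``.

    ``matrix_correct`` holds intended-species exposure samples,
    ``matrix_erroneous`` the wrong-species exposure; replicate columns are
    averaged.  Linear values are clamped at ``LINEAR_FLOOR`` before any
    ratio; probes whose denominator is not finite are dropped from the
    eligible set (count logged and recorded).  The top
    ``floor(x * n_eligible)`` probes by (statistic desc, probe id asc) are
    labelled cross-hybridizing.
    """
    if matrix_correct.scale != "linear" or matrix_erroneous.scale != "linear":
        raise ValidationError("gold standards are built from linear-scale matrices")
    eligible = frozenset(eligible)
    missing = eligible - set(matrix_correct.probe_ids) | eligible - set(matrix_erroneous.probe_ids)
    if missing:
        raise ValidationError(f"eligible probes missing from matrices: {sorted(missing)[:5]}")

    idx = sorted(eligible)
    clamp = lambda s: s.reindex(idx).clip(lower=LINEAR_FLOOR)  # noqa: E731

    if spec.kind == "GS1":
        stat = (
            clamp(_channel_column(matrix_erroneous, "red"))
            / clamp(_channel_column(matrix_erroneous, "green"))
        ) / (
            clamp(_channel_column(matrix_correct, "red"))
            / clamp(_channel_column(matrix_correct, "green"))
        )
    elif spec.kind == "GS2":
        stat = clamp(_single_or_red(matrix_erroneous))
    elif spec.kind == "GS3":
        stat = clamp(_single_or_red(matrix_erroneous)) / clamp(_single_or_red(matrix_correct))
    elif spec.kind == "GS4":
        stat = clamp(_single_or_red(matrix_erroneous))
        green_corr = np.log2(clamp(_channel_column(matrix_correct, "green")))
        green_err = np.log2(clamp(_channel_column(matrix_erroneous, "green")))
        keep = (green_corr > spec.channel_floor) & (green_err > spec.channel_floor)
        stat = stat[keep]
        eligible = frozenset(stat.index)
    else:  # pragma: no cover - guarded by GoldStandardSpec
        raise ValidationError(f"unknown kind {spec.kind}")

    bad = ~np.isfinite(stat)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("gold standard %s: dropped %d probes with unusable ratios",
                    spec.label, n_dropped)
        stat = stat[~bad]
        eligible = frozenset(stat.index)

    order = stat.to_frame("stat").reset_index(names="probe_id")
    order = order.sort_values(["stat", "probe_id"], ascending=[False, True], kind="mergesort")
    n_top = int(math.floor(spec.x * len(eligible)))
    csh = frozenset(order["probe_id"].head(n_top))
    return GoldStandardLabeling(spec, csh, eligible, stat.sort_index(), n_dropped)
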