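"""Filtering and normalization of label-free intensity matrices.

Pipeline order is fixed as: group-validity filter -> log2 transform ->
per-sample normalization -> (optional) left-censored imputation.  The
validity filter keeps a protein only if it was quantified in at least
70 % of the samples of at least one clinical group; imputation draws
missing cells from a down-shifted normal per sample, the standard
convention for abundance-dependent (left-censored) missingness in LFQ
data.  Row Z-scoring is provided for heatmap export.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from ._rng import substream
from .core_data import IntensityMatrix, SampleSheet, ValidationError

__all__ = [
    "FilterReport",
    "filter_group_validity",
    "log2_transform",
    "normalize_median",
    "normalize_quantile",
    "impute_downshifted",
    "zscore_rows",
]


@dataclass
class FilterReport:
    """Outcome of the group-validity filter."""

    n_before: int
    n_after: int
    #: per protein, per group: fraction of samples with a quantified value
    per_protein_validity: pd.DataFrame

    def __post_init__(self) -> None:
        if self.n_after > self.n_before:
            raise ValidationError("n_after cannot exceed n_before")


def _as_fraction(x: float) -> Fraction:
    # exact decimal semantics for thresholds like 0.70 (no float boundary ties)
    return Fraction(repr(float(x)))


def filter_group_validity(
    m: IntensityMatrix, sheet: SampleSheet, min_frac: float = 0.70
) -> tuple[IntensityMatrix, FilterReport]:
    """Keep proteins quantified in >= ``min_frac`` of samples of >= 1 group.

    The comparison is performed in exact rational arithmetic
    (``present_count / group_size >= min_frac`` with the threshold taken
    at its decimal value), so a protein present in exactly 70 % of a
    group passes a 0.70 threshold regardless of float representation.
    """
    if not 0 <= min_frac <= 1:
        raise ValidationError("min_frac must be in (0, 1]")
    sheet.check_covers(m)
    group_of = sheet.group_of()
    present = m.present()
    thr = _as_fraction(min_frac)

    frac_cols: dict[str, pd.Series] = {}
    keep = pd.Series(False, index=m.values.index)
    for g in sheet.groups:
        samples = [s for s in m.sample_ids if group_of[s] == g]
        if not samples:
            raise ValidationError(f"group {g!r} has no samples in the matrix")
        n_g = len(samples)
        count = present[samples].sum(axis=1)
        frac_cols[g] = count / n_g
        # exact comparison: count / n_g >= thr  <=>  count * thr.den >= thr.num * n_g
        keep |= count * thr.denominator >= thr.numerator * n_g
    if not frac_cols:
        raise ValidationError("no group has any samples")

    filtered = m.copy_with(m.values.loc[keep])
    report = FilterReport(
        n_before=m.shape[0],
        n_after=filtered.shape[0],
        per_protein_validity=pd.DataFrame(frac_cols),
    )
    return filtered, report


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Log2-transform present values; missing cells stay missing."""
    if m.is_log2:
        raise ValidationError("matrix is already on the log2 scale")
    arr = m.values.to_numpy(dtype=float)
    bad = np.argwhere(np.isfinite(arr) & (arr <= 0))
    if len(bad):
        i, j = bad[0]
        raise ValidationError(
            f"non-positive intensity at protein {m.protein_ids[i]!r}, "
            f"sample {m.sample_ids[j]!r}"
        )
    return m.copy_with(np.log2(m.values), is_log2=True)


def normalize_median(m: IntensityMatrix) -> IntensityMatrix:
    """Shift each sample so its median equals the grand median.

    Median centering on the log2 scale is the least aggressive of the
    standard between-sample normalizations; it removes per-sample
    loading/acquisition offsets while preserving within-sample ordering.
    """
    if not m.is_log2:
        raise ValidationError("normalize on the log2 scale")
    counts = m.values.notna().sum(axis=0)
    low = counts[counts < 2]
    if len(low):
        raise ValidationError(f"samples with < 2 present values: {list(low.index)}")
    col_medians = m.values.median(axis=0)
    grand = float(np.nanmedian(m.values.to_numpy(dtype=float)))
    return m.copy_with(m.values - col_medians + grand)


def normalize_quantile(m: IntensityMatrix) -> IntensityMatrix:
    """Quantile normalization (all samples forced to the mean empirical
    distribution); available behind the config switch, complete matrices
    only."""
    if not m.is_log2:
        raise ValidationError("normalize on the log2 scale")
    if m.n_missing():
        raise ValidationError("quantile normalization requires a complete matrix")
    v = m.values
    ranked = v.rank(axis=0, method="average")
    means = pd.DataFrame(np.sort(v.to_numpy(), axis=0), columns=v.columns).mean(axis=1)
    means.index = np.arange(1, len(means) + 1, dtype=float)
    out = ranked.apply(lambda col: np.interp(col, means.index, means.to_numpy()))
    return m.copy_with(pd.DataFrame(out, index=v.index, columns=v.columns))


def impute_downshifted(
    m: IntensityMatrix, width: float = 0.3, shift: float = 1.8, seed: int = 0
) -> IntensityMatrix:
    """Impute missing cells from a per-sample down-shifted normal.

    For sample s with present-value mean mu_s and sd sigma_s, missing
    cells are drawn from N(mu_s - shift * sigma_s, (width * sigma_s)^2).
    The (shift, width) = (1.8, 0.3) defaults are the community convention
    for left-censored LFQ missingness.  Deterministic under ``seed``.
    """
    if not m.is_log2:
        raise ValidationError("impute on the log2 scale")
    if m.n_missing() == 0:
        return m
    rng = substream(seed, "impute_downshifted")
    values = m.values.copy()
    for s in m.sample_ids:
        col = values[s]
        present = col.dropna()
        n_miss = col.isna().sum()
        if n_miss == 0:
            continue
        if len(present) < 3:
            raise ValidationError(f"sample {s!r} has < 3 present values")
        mu, sd = float(present.mean()), float(present.std(ddof=1))
        draws = rng.normal(mu - shift * sd, width * sd, size=int(n_miss))
        values.loc[col.isna(), s] = draws
    return m.copy_with(values)


def zscore_rows(m: IntensityMatrix) -> IntensityMatrix:
    """Z-score each protein row (population sd); constant rows -> zeros."""
    if m.n_missing():
        raise ValidationError("Z-scoring requires a complete matrix")
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population (divide-by-n) sd
    out = np.divide(arr - mean, sd, out=np.zeros_like(arr), where=sd > 0)
    return m.copy_with(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))
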