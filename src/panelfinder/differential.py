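"""Univariate differential abundance testing with a volcano significance curve.

Two-group contrasts use Welch's unequal-variance t-test per protein on
the observed (non-imputed) log2 values; the four-group contrast uses
one-way ANOVA.  P-values are corrected by the Benjamini–Hochberg
step-up procedure, and the combined effect-size/significance gate is the
hyperbolic volcano boundary

    y = c / (x - x0)

in (|log2 fold change|, -log10 adjusted p) space, with ``x0 = 1`` the
log2 of the 2-fold-change requirement.  A point is significant when it
lies strictly above the curve and its adjusted p-value is <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

from .core_data import IntensityMatrix, SampleSheet, ValidationError

__all__ = [
    "VolcanoCurve",
    "bh_adjust",
    "welch_t_table",
    "anova_table",
    "volcano_classify",
    "posthoc_power",
    "apply_power_gate",
]

P_SIG = 0.05
FC_GATE_LOG2 = 1.0  # log2 of the required 2-fold change


@dataclass(frozen=True)
class VolcanoCurve:
    """Hyperbolic significance boundary y = c/(x - x0), defined for x > x0."""

    c: float = 0.5
    x0: float = FC_GATE_LOG2

    def __post_init__(self) -> None:
        if self.c < 0 or self.x0 < 0:
            raise ValidationError("curve parameters must be non-negative")

    def threshold(self, abs_log2_fc: np.ndarray) -> np.ndarray:
        """-log10(p) needed for significance at each |log2 FC| (inf at/below x0)."""
        x = np.asarray(abs_log2_fc, dtype=float)
        with np.errstate(divide="ignore"):
            y = np.where(x > self.x0, self.c / np.where(x > self.x0, x - self.x0, 1.0), np.inf)
        return y


def bh_adjust(p: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_values(m: IntensityMatrix, sheet: SampleSheet, group: str) -> pd.DataFrame:
    samples = [s for s in m.sample_ids if s in set(sheet.samples_in(group))]
    if not samples:
        raise ValidationError(f"group {group!r} has no samples in the matrix")
    return m.values[samples]


def welch_t_table(
    m: IntensityMatrix,
    sheet: SampleSheet,
    group_a: "str | list[str]",
    group_b: "str | list[str]",
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-protein Welch t-test between two (possibly pooled) groups.

    ``log2_fc`` is mean(A) - mean(B) on the log2 scale.  Proteins with
    fewer than ``min_per_group`` observed values in either group are
    skipped with a warning.  Returns a DataFrame indexed by protein with
    columns log2_fc, p_raw, p_adj and the rectangular-gate
    ``significant`` flag (p_adj <= 0.05 and |log2_fc| >= 1); use
    :func:`volcano_classify` for the curved gate.
    """
    if not m.is_log2:
        raise ValidationError("differential testing expects log2 intensities")
    a = _group_values(m, sheet, group_a) if isinstance(group_a, str) else pd.concat(
        [_group_values(m, sheet, g) for g in group_a], axis=1)
    b = _group_values(m, sheet, group_b) if isinstance(group_b, str) else pd.concat(
        [_group_values(m, sheet, g) for g in group_b], axis=1)

    n_a = a.notna().sum(axis=1)
    n_b = b.notna().sum(axis=1)
    testable = (n_a >= min_per_group) & (n_b >= min_per_group)
    skipped = int((~testable).sum())
    if skipped:
        warnings.warn(f"skipped {skipped} proteins with < {min_per_group} values per group")

    av = a.loc[testable].to_numpy(dtype=float)
    bv = b.loc[testable].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(av, bv, axis=1, equal_var=False, nan_policy="omit")
    log2_fc = np.nanmean(av, axis=1) - np.nanmean(bv, axis=1)
    p = np.asarray(p, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties carry no evidence
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_raw": p,
            "p_adj": bh_adjust(p),
        },
        index=a.index[testable],
    )
    out["significant"] = (out["p_adj"] <= P_SIG) & (out["log2_fc"].abs() >= FC_GATE_LOG2)
    out.index.name = "protein_id"
    return out


def anova_table(
    m: IntensityMatrix,
    sheet: SampleSheet,
    groups: "list[str] | None" = None,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """One-way ANOVA across >= 2 groups per protein, BH-corrected.

    ``log2_fc`` is not defined for a multi-group contrast and is omitted;
    ``significant`` means adjusted p <= 0.05.
    """
    if not m.is_log2:
        raise ValidationError("differential testing expects log2 intensities")
    groups = groups or sheet.groups
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    blocks = {g: _group_values(m, sheet, g) for g in groups}

    testable = pd.Series(True, index=m.values.index)
    for g, block in blocks.items():
        testable &= block.notna().sum(axis=1) >= min_per_group
    skipped = int((~testable).sum())
    if skipped:
        warnings.warn(f"skipped {skipped} proteins with < {min_per_group} values per group")

    arrays = [blocks[g].loc[testable].to_numpy(dtype=float) for g in groups]
    n_prot = int(testable.sum())
    p = np.empty(n_prot)
    stat = np.empty(n_prot)
    for i in range(n_prot):
        samples = [row[~np.isnan(row)] for row in (arr[i] for arr in arrays)]
        res = stats.f_oneway(*samples)
        stat[i], p[i] = res.statistic, res.pvalue
    p = np.where(np.isnan(p), 1.0, p)  # all-constant proteins: no evidence
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {"F": stat, "p_raw": p, "p_adj": bh_adjust(p)}, index=m.values.index[testable]
    )
    out["significant"] = out["p_adj"] <= P_SIG
    out.index.name = "protein_id"
    return out


def volcano_classify(
    table: pd.DataFrame, curve: VolcanoCurve = VolcanoCurve(), use_adjusted: bool = True
) -> pd.DataFrame:
    """Classify differential records against the hyperbolic curve.

    Adds ``curve_side`` ("above"/"below") and recomputes ``significant``
    as above-the-curve AND adjusted p <= 0.05.  A record sits above when
    |log2_fc| > x0 and -log10(p) strictly exceeds c/(|log2_fc| - x0);
    at |log2_fc| = x0 the threshold is infinite, so such records are
    below.  With c -> 0 the rule reduces to the rectangular gate with a
    strict fold-change inequality.
    """
    out = table.copy()
    pcol = "p_adj" if use_adjusted else "p_raw"
    x = out["log2_fc"].abs().to_numpy(dtype=float)
    y = -np.log10(out[pcol].to_numpy(dtype=float))
    above = (x > curve.x0) & (y > curve.threshold(x))
    out["curve_side"] = np.where(above, "above", "below")
    out["significant"] = above & (out["p_adj"].to_numpy() <= P_SIG)
    return out


def posthoc_power(
    effect_size: float, n_a: int, n_b: int, alpha: float = P_SIG
) -> float:
    """Two-sided two-sample t-test power at a standardized effect size.

    Wraps the noncentral-t power computation; ``effect_size`` is Cohen's
    d (observed mean difference over pooled sd).  At d = 0 the power
    equals alpha by construction.
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError("need at least 2 samples per group")
    power = TTestIndPower().power(
        effect_size=abs(float(effect_size)), nobs1=n_a, ratio=n_b / n_a, alpha=alpha,
        alternative="two-sided",
    )
    return float(power)


def apply_power_gate(
    table: pd.DataFrame,
    m: IntensityMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    min_power: float = 0.80,
) -> pd.DataFrame:
    """Optional 80 %-power gate on the significant set (off by default
    in the pipeline: the stated power figure plausibly describes design
    power rather than a per-protein filter).

    Computes observed Cohen's d per protein and drops from the
    significant set those whose post-hoc power falls below
    ``min_power``.  Proteins with zero pooled sd get power NaN and are
    flagged, not dropped.
    """
    a = _group_values(m, sheet, group_a).loc[table.index]
    b = _group_values(m, sheet, group_b).loc[table.index]
    out = table.copy()
    powers = np.empty(len(out))
    for i, pid in enumerate(out.index):
        xa = a.loc[pid].dropna().to_numpy(dtype=float)
        xb = b.loc[pid].dropna().to_numpy(dtype=float)
        sp2 = (
            ((len(xa) - 1) * xa.var(ddof=1) + (len(xb) - 1) * xb.var(ddof=1))
            / (len(xa) + len(xb) - 2)
        )
        if sp2 <= 0:
            powers[i] = np.nan
            continue
        d = (xa.mean() - xb.mean()) / np.sqrt(sp2)
        powers[i] = posthoc_power(d, len(xa), len(xb))
    out["power"] = powers
    out["significant"] = out["significant"] & ~(out["power"] < min_power)
    return out
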