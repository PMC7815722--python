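"""Diagnostic validation of assay panels: nonparametric group comparison
and ROC analysis.

Per analyte the per-sample value is the mean of the technical triplicate
(below-LLOQ values substituted by LLOQ/2).  Group differences use the
tie-corrected Kruskal–Wallis test with Dunn's pairwise z-tests and a
Bonferroni family correction per analyte.  Diagnostic performance uses
the empirical (Mann–Whitney) AUC with a stratified-bootstrap percentile
CI (DeLong available), the Youden-index cutoff over observed threshold
midpoints, Clopper–Pearson CIs for sensitivity and specificity, the
positive likelihood ratio, and the conventional ordinal AUC quality
bands (0.5 not discriminant, up to 0.9–1 excellent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ._rng import substream
from .core_data import AssayPanel, SampleSheet, ValidationError

__all__ = [
    "GroupComparison",
    "ROCResult",
    "kruskal_dunn",
    "roc_analysis",
    "auc_band",
    "validate_panel",
    "DEFAULT_COMPARISONS",
]

#: the study's three diagnostic contrasts: tumor vs non-tumor, then each
#: large tumor class against all other tumors
DEFAULT_COMPARISONS = (
    ("tumor_vs_nontumor", ("LGG_GT", "EMB", "other_tumor"), ("control", "post_hemorrhagic")),
    ("LGG_GT_vs_other_tumors", ("LGG_GT",), ("EMB", "other_tumor")),
    ("EMB_vs_other_tumors", ("EMB",), ("LGG_GT", "other_tumor")),
)


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    analyte: str
    statistic: float              # tie-corrected Kruskal–Wallis H
    p_value: float
    pairwise: dict[tuple[str, str], float]   # Dunn-adjusted p per pair
    group_n: dict[str, int] = field(default_factory=dict)


def _dunn_pairwise(samples: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's z-tests on mean ranks with tie correction; family-corrected
    by Bonferroni over the pairs of one analyte."""
    groups = list(samples)
    pooled = np.concatenate([samples[g] for g in groups])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in groups:
        n_g = len(samples[g])
        mean_rank[g] = float(ranks[start:start + n_g].mean())
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(groups, 2))
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / len(samples[a]) + 1.0 / len(samples[b])))
        if se == 0:
            out[(a, b)] = 1.0
            continue
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = float(min(1.0, p * len(pairs)))
    return out


def kruskal_dunn(
    panel: AssayPanel, sheet: SampleSheet, groups: "list[str] | None" = None
) -> GroupComparison:
    """Tie-corrected Kruskal–Wallis across groups with Dunn post-hocs.

    All-identical values are a defined degenerate case (H = 0, p = 1),
    not an error.
    """
    values = panel.sample_values()
    groups = groups or sheet.groups
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    samples: dict[str, np.ndarray] = {}
    for g in groups:
        ids = [s for s in sheet.samples_in(g) if s in values.index]
        if len(ids) < 2:
            raise ValidationError(f"group {g!r} has < 2 assayed samples")
        samples[g] = values.loc[ids].to_numpy(dtype=float)

    pooled = np.concatenate(list(samples.values()))
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
        pairwise = {pair: 1.0 for pair in combinations(groups, 2)}
    else:
        h, p = stats.kruskal(*samples.values())
        pairwise = _dunn_pairwise(samples)
    return GroupComparison(
        analyte=panel.analyte,
        statistic=float(h),
        p_value=float(p),
        pairwise=pairwise,
        group_n={g: len(v) for g, v in samples.items()},
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    analyte: str
    comparison: str
    auc: float
    auc_ci: tuple[float, float]
    p_value: float
    cutoff: float
    direction: str                # ">" positive class above cutoff, "<" below
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    lr_plus: float                # +inf at specificity 1
    band: str
    youden_j: float
    n_pos: int
    n_neg: int


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Empirical AUC via the Mann–Whitney rank estimator (ties count 1/2)."""
    n1, n2 = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def _youden_sweep(
    pos: np.ndarray, neg: np.ndarray, direction: str
) -> tuple[float, float, float]:
    """Best (cutoff, sensitivity, specificity) by Youden's J.

    Candidate cutoffs are the midpoints between adjacent distinct
    observed values, plus one candidate below and above the data range.
    Ties in J break toward higher specificity, then lower cutoff.
    """
    allv = np.unique(np.concatenate([pos, neg]))
    mids = (allv[:-1] + allv[1:]) / 2.0 if len(allv) > 1 else np.array([])
    span = (allv[-1] - allv[0]) or abs(allv[0]) or 1.0
    cand = np.concatenate([[allv[0] - 0.05 * span], mids, [allv[-1] + 0.05 * span]])
    best = None
    for t in cand:
        if direction == ">":
            sens = np.mean(pos > t)
            spec = np.mean(neg <= t)
        else:
            sens = np.mean(pos < t)
            spec = np.mean(neg >= t)
        j = sens + spec - 1.0
        key = (j, spec, -t)
        if best is None or key > best[0]:
            best = (key, float(t), float(sens), float(spec))
    return best[1], best[2], best[3]


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float, alpha: float = 0.05):
    """DeLong variance of the empirical AUC -> normal-theory CI."""
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / len(pos) for n in neg])
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_analysis(
    values: pd.Series,
    labels: pd.Series,
    positive_label: str = "positive",
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
    analyte: str = "",
    comparison: str = "",
) -> ROCResult:
    """Full ROC characterization of one analyte for one binary contrast.

    The AUC is the rank (Mann–Whitney) estimator, auto-oriented to
    >= 0.5: analytes lower in the positive class get direction "<"
    (positive call below the cutoff).  The p-value tests AUC = 0.5 via
    the two-sided Mann–Whitney test; the CI is a stratified bootstrap
    percentile interval (or DeLong); sensitivity and specificity at the
    Youden-optimal cutoff carry Clopper–Pearson (exact) CIs.
    """
    labels = labels.reindex(values.index)
    pos = values[labels == positive_label].to_numpy(dtype=float)
    neg = values[labels != positive_label].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be non-empty")

    auc_raw = _rank_auc(pos, neg)
    direction = ">" if auc_raw >= 0.5 else "<"
    auc = auc_raw if direction == ">" else 1.0 - auc_raw

    try:
        p_value = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    except ValueError:  # all values identical
        p_value = 1.0

    if ci_method == "delong":
        ci = _delong_ci(pos, neg, auc) if direction == ">" else tuple(
            sorted(1.0 - np.array(_delong_ci(neg, pos, 1.0 - auc))))
        ci = (float(min(ci)), float(max(ci)))
    elif ci_method == "bootstrap":
        rng = substream(seed, f"roc_boot_{analyte}_{comparison}")
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pb = pos[rng.integers(0, len(pos), len(pos))]
            nb = neg[rng.integers(0, len(neg), len(neg))]
            a = _rank_auc(pb, nb)
            boots[b] = a if direction == ">" else 1.0 - a
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    cutoff, sens, spec = _youden_sweep(pos, neg, direction)
    sens_ci = proportion_confint(round(sens * len(pos)), len(pos), method="beta")
    spec_ci = proportion_confint(round(spec * len(neg)), len(neg), method="beta")
    lr_plus = float("inf") if spec == 1.0 else sens / (1.0 - spec)

    return ROCResult(
        analyte=analyte,
        comparison=comparison,
        auc=auc,
        auc_ci=ci,
        p_value=p_value,
        cutoff=cutoff,
        direction=direction,
        sensitivity=sens,
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity=spec,
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
        lr_plus=lr_plus,
        band=auc_band(auc),
        youden_j=sens + spec - 1.0,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def auc_band(auc: float) -> str:
    """Ordinal quality band of an AUC.

    Exactly 0.5 is not discriminant; [0.5, 0.6) fail; [0.6, 0.7) poor;
    [0.7, 0.8) fair; [0.8, 0.9) good; [0.9, 1] excellent.  An AUC below
    0.5 is banded after re-orientation (1 - AUC), since orientation is
    handled upstream.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValidationError(f"AUC {auc} outside [0, 1]")
    a = max(auc, 1.0 - auc)
    if a == 0.5:
        return "not_discriminant"
    for lo, name in ((0.9, "excellent"), (0.8, "good"), (0.7, "fair"), (0.6, "poor")):
        if a >= lo:
            return name
    return "fail"


# ---------------------------------------------------------------------------
# Panel validation (Table-1-shaped report)
# ---------------------------------------------------------------------------


def validate_panel(
    panels: dict[str, AssayPanel],
    sheet: SampleSheet,
    comparisons=DEFAULT_COMPARISONS,
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> tuple[pd.DataFrame, dict]:
    """Run group comparison + every ROC contrast for every analyte.

    ``comparisons`` is a list of (name, positive_groups, negative_groups)
    tuples; each must select non-empty disjoint sample sets.  Returns a
    long-format table (one row per analyte x comparison) plus a detail
    dict of :class:`GroupComparison` and :class:`ROCResult` objects.
    """
    rows = []
    details: dict[str, dict] = {}
    n_sheet = len(sheet.sample_ids)
    for analyte, panel in panels.items():
        covered = len(set(panel.sample_ids) & set(sheet.sample_ids))
        if covered < 0.8 * n_sheet:
            warnings.warn(f"{analyte}: assayed in only {covered}/{n_sheet} samples")
        gc = kruskal_dunn(panel, sheet)
        values = panel.sample_values()
        details[analyte] = {"kruskal": gc, "roc": {}}
        for name, pos_groups, neg_groups in comparisons:
            pos_ids = [s for s in sheet.samples_in(pos_groups) if s in values.index]
            neg_ids = [s for s in sheet.samples_in(neg_groups) if s in values.index]
            if not pos_ids or not neg_ids:
                raise ValidationError(f"comparison {name!r} has an empty side")
            lab = pd.Series("negative", index=values.index)
            lab.loc[pos_ids] = "positive"
            sub = values.loc[pos_ids + neg_ids]
            roc = roc_analysis(
                sub, lab.loc[sub.index], "positive", n_boot=n_boot, seed=seed,
                ci_method=ci_method, analyte=analyte, comparison=name,
            )
            details[analyte]["roc"][name] = roc
            rows.append({
                "analyte": analyte,
                "comparison": name,
                "kw_H": gc.statistic,
                "kw_p": gc.p_value,
                "auc": roc.auc,
                "auc_lo": roc.auc_ci[0],
                "auc_hi": roc.auc_ci[1],
                "roc_p": roc.p_value,
                "cutoff": roc.cutoff,
                "direction": roc.direction,
                "sensitivity": roc.sensitivity,
                "sens_lo": roc.sensitivity_ci[0],
                "sens_hi": roc.sensitivity_ci[1],
                "specificity": roc.specificity,
                "spec_lo": roc.specificity_ci[0],
                "spec_hi": roc.specificity_ci[1],
                "lr_plus": roc.lr_plus,
                "band": roc.band,
                "n_pos": roc.n_pos,
                "n_neg": roc.n_neg,
            })
    table = pd.DataFrame(rows)
    return table, details
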