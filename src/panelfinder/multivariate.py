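"""Multivariate sample visualization and dual-ranking panel selection.

The discovery pipeline ranks candidate proteins two independent ways and
keeps the candidates on which both agree:

* **PLS-DA** (partial least squares discriminant analysis) on a one-hot
  class response; per-protein importance is the VIP score (variable
  importance in projection), whose squares average to 1 by construction.
* **SVM** feature ranking under repeated stratified 65/35
  learning/test splits: in each split an ANOVA prefilter is fitted on
  the learning fold only, an RBF-kernel SVM is trained on the surviving
  features and per-feature importance is measured by permutation on the
  test fold (a kernel-agnostic importance; mean |weight| of a linear SVM
  is available as an alternative).  Exhausting every subject partition
  is combinatorially infeasible, so a seeded Monte-Carlo over splits is
  used.

The consensus panel is the intersection of the two top-k lists, ordered
by mean rank position.  Classical MDS on Spearman-correlation distance
and a k-means agreement check (adjusted Rand index against the clinical
labels) support the visual cluster claims.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import f_classif
from sklearn.inspection import permutation_importance
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._rng import subseed
from .core_data import IntensityMatrix, SampleSheet, ValidationError

__all__ = [
    "PlsdaModel",
    "SvmRanking",
    "CorePanel",
    "mds_embed",
    "plsda_fit",
    "vip_scores",
    "svm_rank",
    "consensus_panel",
    "kmeans_separation",
]


def _sample_matrix(m: IntensityMatrix) -> np.ndarray:
    """samples x proteins array; multivariate stages need complete data."""
    if m.n_missing():
        raise ValidationError("multivariate analysis requires a complete (imputed) matrix")
    return m.values.to_numpy(dtype=float).T


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------


def spearman_distance(m: IntensityMatrix) -> pd.DataFrame:
    """Pairwise sample distance d(i,j) = 1 - Spearman rho."""
    x = _sample_matrix(m)
    rho = spearmanr(x, axis=1).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


def mds_embed(m: IntensityMatrix, dims: int = 2) -> pd.DataFrame:
    """Classical MDS (principal coordinates) of samples on Spearman distance.

    Rank-based, hence invariant under any monotone transformation of the
    intensities.  Coordinates are centred at the origin; axes are the
    top ``dims`` principal coordinates (negative eigenvalues of the
    non-Euclidean Spearman distance are discarded).
    """
    if m.shape[1] < 3:
        raise ValidationError("MDS needs at least 3 samples")
    d = spearman_distance(m).to_numpy()
    n = d.shape[0]
    # Gower double-centering of -D^2/2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = min(dims, int(np.sum(evals > 1e-12)))
    coords = np.zeros((n, dims))
    coords[:, :keep] = evecs[:, :keep] * np.sqrt(evals[:keep])
    return pd.DataFrame(
        coords, index=m.sample_ids, columns=[f"MDS{i + 1}" for i in range(dims)]
    )


# ---------------------------------------------------------------------------
# PLS-DA + VIP
# ---------------------------------------------------------------------------


@dataclass
class PlsdaModel:
    n_components: int
    classes: list[str]
    scores: pd.DataFrame          # samples x components
    weights: pd.DataFrame         # proteins x components
    explained_y_ss: np.ndarray    # per-component explained class sum of squares
    vip: pd.Series                # protein -> VIP score


def vip_scores(weights: np.ndarray, explained_y_ss: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ).

    Because the squared normalized weights sum to one per component, the
    mean of VIP^2 over proteins is exactly 1.
    """
    w = np.asarray(weights, dtype=float)
    ssy = np.asarray(explained_y_ss, dtype=float)
    p = w.shape[0]
    wn2 = (w / np.linalg.norm(w, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wn2 @ ssy) / ssy.sum())


def plsda_fit(
    m: IntensityMatrix, sheet: SampleSheet, n_components: int = 2
) -> PlsdaModel:
    """Fit PLS-DA on a one-hot class response and compute VIP scores.

    The class response is the one-hot indicator matrix of the clinical
    groups (a single ±-coded column would lose the multiclass
    structure).  Per component a, SSY_a is the class sum of squares
    captured by that component, q_a' q_a * t_a' t_a.
    """
    x = _sample_matrix(m)
    n, p = x.shape
    labels = sheet.group_of().reindex(m.sample_ids)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValidationError("PLS-DA needs at least 2 classes")
    if n_components >= min(n, p):
        raise ValidationError(
            f"n_components={n_components} must be < min(n_samples, n_proteins)={min(n, p)}"
        )
    y = pd.get_dummies(labels).reindex(columns=classes).to_numpy(dtype=float)

    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(x, y)

    t = pls.x_scores_
    q = pls.y_loadings_
    ssy = np.einsum("ka,ka->a", q, q) * np.einsum("na,na->a", t, t)
    vip = vip_scores(pls.x_weights_, ssy)

    comp_names = [f"comp{i + 1}" for i in range(n_components)]
    return PlsdaModel(
        n_components=n_components,
        classes=[str(c) for c in classes],
        scores=pd.DataFrame(t, index=m.sample_ids, columns=comp_names),
        weights=pd.DataFrame(pls.x_weights_, index=m.protein_ids, columns=comp_names),
        explained_y_ss=ssy,
        vip=pd.Series(vip, index=m.protein_ids, name="vip"),
    )


# ---------------------------------------------------------------------------
# SVM ranking
# ---------------------------------------------------------------------------


@dataclass
class SvmRanking:
    rank: pd.Series               # protein -> 1..p (1 = most important)
    importance: pd.Series         # mean accumulated importance
    selection_freq: pd.Series     # fraction of splits passing the prefilter
    cv_accuracy: float
    n_splits_run: int
    seed: int
    kernel: str = "rbf"           # kernel of the accuracy model
    importance_mode: str = "linear_weight"


def svm_rank(
    m: IntensityMatrix,
    sheet: SampleSheet,
    learn_frac: float = 0.65,
    n_splits: int = 200,
    prefilter_p: float = 0.05,
    importance: str = "linear_weight",
    n_permutation_repeats: int = 5,
    seed: int = 0,
) -> SvmRanking:
    """Rank proteins by SVM importance over repeated 65/35 splits.

    Per split: an ANOVA F-test prefilter (p <= ``prefilter_p``) is fitted
    on the learning fold only; an RBF-kernel SVM trained on the
    surviving features supplies the test-fold ``cv_accuracy``;
    per-feature importance is accumulated per split either as the mean
    |weight| of a linear SVM on the same features (default) or by
    permutation of the RBF model on the test fold.  Permutation
    importance is kernel-faithful but blind to redundant informative
    features — a correlated marker panel scores near zero because any
    single member can be permuted without hurting accuracy — so the
    weight-based ranking is the default.  Features never passing the
    prefilter keep importance 0 and rank after all selected ones.
    """
    if n_splits < 4:
        raise ValidationError("use at least 4 splits (fourfold cross-validation)")
    if importance not in {"permutation", "linear_weight"}:
        raise ValidationError(f"unknown importance mode {importance!r}")
    x = _sample_matrix(m)
    labels = sheet.group_of().reindex(m.sample_ids).to_numpy()
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValidationError(f"classes with < 2 samples: {list(counts[counts < 2].index)}")

    n, p = x.shape
    acc_importance = np.zeros(p)
    selected_count = np.zeros(p)
    accuracies = []
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=learn_frac, random_state=subseed(seed, "svm_splits")
    )
    for split_i, (learn, test) in enumerate(splitter.split(x, labels)):
        with np.errstate(divide="ignore", invalid="ignore"):
            f, pvals = f_classif(x[learn], labels[learn])
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        sel = np.flatnonzero(pvals <= prefilter_p)
        if sel.size == 0:
            # degenerate learning fold: fall back to the 10 largest F
            sel = np.argsort(np.where(np.isnan(f), -np.inf, f))[::-1][:10]
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale"))
        clf.fit(x[np.ix_(learn, sel)], labels[learn])
        accuracies.append(clf.score(x[np.ix_(test, sel)], labels[test]))
        selected_count[sel] += 1
        if importance == "permutation":
            imp = permutation_importance(
                clf,
                x[np.ix_(test, sel)],
                labels[test],
                n_repeats=n_permutation_repeats,
                random_state=subseed(seed, f"perm_{split_i}"),
            ).importances_mean
        else:
            lin = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
            lin.fit(x[np.ix_(learn, sel)], labels[learn])
            imp = np.abs(lin[-1].coef_).mean(axis=0)
        acc_importance[sel] += imp

    mean_importance = acc_importance / n_splits
    order = np.lexsort((np.asarray(m.protein_ids), -mean_importance))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)

    idx = pd.Index(m.protein_ids, name="protein_id")
    return SvmRanking(
        rank=pd.Series(rank, index=idx, name="svm_rank"),
        importance=pd.Series(mean_importance, index=idx, name="svm_importance"),
        selection_freq=pd.Series(selected_count / n_splits, index=idx, name="selection_freq"),
        cv_accuracy=float(np.mean(accuracies)),
        n_splits_run=n_splits,
        seed=seed,
        kernel="rbf",
        importance_mode=importance,
    )


# ---------------------------------------------------------------------------
# Consensus panel
# ---------------------------------------------------------------------------


@dataclass
class CorePanel:
    members: list[str]
    consensus_rank: pd.Series     # member -> mean of the two rank positions
    selection_rule: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def consensus_panel(
    plsda: PlsdaModel, svm: SvmRanking, k: "int | None" = None
) -> CorePanel:
    """Proteins in the top-k of BOTH the VIP and the SVM ranking.

    Both rankings must cover the same protein set (in the pipeline: the
    ANOVA-significant proteins).  ``k`` defaults to the full set size so
    that the intersection rule alone determines the panel.  Members are
    ordered by the mean of their two rank positions; ties break by
    higher VIP, then accession.
    """
    vip = plsda.vip
    if set(vip.index) != set(svm.rank.index):
        raise ValidationError("VIP and SVM rankings cover different protein sets")
    n = len(vip)
    k = n if k is None else int(k)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside 1..{n}")

    vip_rank = vip.rank(ascending=False, method="first").astype(int)
    svm_rank_s = svm.rank.reindex(vip.index)
    members_set = set(vip_rank[vip_rank <= k].index) & set(svm_rank_s[svm_rank_s <= k].index)
    if not members_set:
        warnings.warn("consensus panel is empty: the two top-k lists are disjoint")
    consensus = ((vip_rank + svm_rank_s) / 2.0).loc[sorted(members_set)]
    ordered = (
        pd.DataFrame({"consensus": consensus, "vip": vip.loc[consensus.index]})
        .sort_values(["consensus", "vip"], ascending=[True, False], kind="mergesort")
        .index.tolist()
    )
    return CorePanel(
        members=ordered,
        consensus_rank=consensus.loc[ordered].rename("consensus_rank"),
        selection_rule={"k": k, "n_candidates": n},
    )


# ---------------------------------------------------------------------------
# k-means agreement
# ---------------------------------------------------------------------------


def kmeans_separation(
    scores: pd.DataFrame,
    sheet: SampleSheet,
    k: int = 4,
    n_init: int = 50,
    seed: int = 0,
) -> tuple[pd.Series, float]:
    """k-means on ordination scores + agreement with the clinical labels.

    Returns the cluster assignment and the adjusted Rand index between
    clusters and groups (1 = perfect recovery, ~0 = chance).
    """
    x = scores.to_numpy(dtype=float)
    if k > x.shape[0]:
        raise ValidationError("k exceeds the number of samples")
    if np.allclose(x, x[0]):
        raise ValidationError("degenerate scores: all samples identical")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=subseed(seed, "kmeans"))
    assign = km.fit_predict(x)
    labels = sheet.group_of().reindex(scores.index)
    ari = float(adjusted_rand_score(labels, assign)) if k > 1 else 0.0
    return pd.Series(assign, index=scores.index, name="cluster"), ari
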