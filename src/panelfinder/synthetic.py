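"""Synthetic MS-like intensity matrices and ELISA-like assay panels.

The real study data (a label-free proteomics deposit and per-patient
immunoassay readings) are not required to exercise the pipeline: this
module generates matrices with the same structure and planted, recorded
ground truth so that every downstream stage — the group-validity filter,
differential testing, multivariate ranking and ROC validation — can be
tested for parameter recovery.

Two generative models are used:

* **Intensity matrix** — per-cell log2 intensities are normal around a
  protein-specific baseline (i.e. raw intensities are log-normal);
  designated marker proteins get a fixed log2 shift in their assigned
  tumor group; each cell then drops out (missing-not-at-random) with a
  logistic probability that decreases with the underlying log2
  intensity, reproducing the low-abundance censoring that makes a
  70 %-per-group validity filter meaningful.

* **ELISA panel** — per-sample true concentrations are log-normal with
  parameters matched to a configured per-group median and interquartile
  range; three technical replicates add multiplicative noise with a
  configured coefficient of variation.  Defaults ship with the package
  and encode the published per-group medians/IQRs of the six validated
  analytes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from ._rng import substream
from .core_data import AssayPanel, IntensityMatrix, SampleSheet, ValidationError

__all__ = [
    "SimConfig",
    "ElisaSimConfig",
    "simulate_matrix",
    "simulate_elisa",
    "load_elisa_defaults",
    "lognormal_from_quartiles",
]

#: standard normal upper quartile, used to map an IQR to a log-sd
_Z75 = norm.ppf(0.75)

#: default discovery-cohort design (MS arm): 17 hydrocephalus controls
#: and 29 tumors split over the three clinical groups
DEFAULT_MS_DESIGN = {"control": 17, "LGG_GT": 11, "EMB": 10, "other_tumor": 8}


@dataclass
class SimConfig:
    """Configuration of the planted intensity-matrix simulation.

    Defaults mirror the discovery study's scale: 1789 identified
    proteins over the 46-sample four-group design, with a core of 104
    true markers shifted by two log2 units (the pipeline's fold-change
    gate is 2-fold).  ``base_log2_sd`` is the within-group per-cell
    noise; ``protein_spread`` the between-protein baseline spread.
    Dropout probability for a cell of log2 intensity x is
    ``expit(dropout_intercept - dropout_slope * x)``: a positive slope
    makes low-abundance cells drop out preferentially.
    """

    n_per_group: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_MS_DESIGN))
    n_proteins: int = 1789
    n_markers: int = 104
    effect_log2: float = 2.0
    base_log2_mean: float = 25.0
    base_log2_sd: float = 1.0
    protein_spread: float = 2.0
    dropout_intercept: float = 22.0
    dropout_slope: float = 1.0
    reference_group: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers > self.n_proteins:
            raise ValidationError("n_markers cannot exceed n_proteins")
        if self.n_proteins <= 0 or self.n_markers < 0:
            raise ValidationError("n_proteins must be positive, n_markers non-negative")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValidationError("all group sizes must be positive")
        if self.base_log2_sd <= 0 or self.protein_spread < 0:
            raise ValidationError("noise scales must be positive")


def simulate_matrix(cfg: SimConfig) -> tuple[IntensityMatrix, SampleSheet, dict[str, str]]:
    """Draw a raw (non-log) intensity matrix with planted group markers.

    Returns the matrix (zeros-as-missing already applied, ``is_log2``
    False), the matching sample sheet and the ground truth: a map from
    marker protein id to the group in which it is up-shifted.  Markers
    are assigned round-robin to the non-reference groups, so with a
    single tumor group all markers separate tumor from reference, and
    with three tumor groups each group gets its own signature third.
    """
    rng = substream(cfg.seed, "simulate_matrix")
    groups = list(cfg.n_per_group)
    target_groups = [g for g in groups if g != cfg.reference_group] or groups[1:]
    if not target_groups:
        raise ValidationError("need at least one non-reference group to plant markers in")

    sample_ids: list[str] = []
    sample_group: list[str] = []
    for g in groups:
        for i in range(cfg.n_per_group[g]):
            sample_ids.append(f"{g}_{i + 1:02d}")
            sample_group.append(g)
    n_samples = len(sample_ids)

    protein_ids = [f"P{i + 1:05d}" for i in range(cfg.n_proteins)]
    marker_idx = rng.choice(cfg.n_proteins, size=cfg.n_markers, replace=False)
    marker_idx.sort()
    truth = {
        protein_ids[j]: target_groups[k % len(target_groups)]
        for k, j in enumerate(marker_idx)
    }

    baseline = rng.normal(cfg.base_log2_mean, cfg.protein_spread, size=cfg.n_proteins)
    log2x = baseline[:, None] + rng.normal(0.0, cfg.base_log2_sd, size=(cfg.n_proteins, n_samples))
    group_arr = np.asarray(sample_group)
    for j in marker_idx:
        log2x[j, group_arr == truth[protein_ids[j]]] += cfg.effect_log2

    p_miss = expit(cfg.dropout_intercept - cfg.dropout_slope * log2x)
    missing = rng.random(size=log2x.shape) < p_miss
    values = np.exp2(log2x)
    values[missing] = np.nan

    matrix = IntensityMatrix(
        values=pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                            columns=sample_ids),
        is_log2=False,
    )
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "group": sample_group,
        "assay": "MS",
    }))
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# ELISA simulation
# ---------------------------------------------------------------------------


def lognormal_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) from a median and quartiles.

    mu is the log median; sigma is the log-quartile half-width divided by
    the standard normal upper quartile.  The fitted distribution
    reproduces the configured median exactly and the configured quartile
    ratio q3/q1 exactly (its individual quartiles match only when the
    printed IQR is symmetric on the log scale).  A zero-width IQR (a
    table cell printed with identical quartiles) degenerates to a point
    mass at the median.
    """
    if not (median > 0 and q1 > 0 and q3 > 0):
        raise ValidationError("median and quartiles must be positive")
    if not (q1 <= median <= q3):
        raise ValidationError(
            f"inconsistent quantiles: need q1 <= median <= q3, got {q1}, {median}, {q3}"
        )
    return float(np.log(median)), float((np.log(q3) - np.log(q1)) / (2.0 * _Z75))


@dataclass
class ElisaSimConfig:
    """Configuration of the immunoassay simulator.

    ``analytes`` maps analyte -> group -> {median, q1, q3} in ng/ml,
    plus an optional per-analyte ``lloq``.  ``replicate_cv`` is the
    coefficient of variation of the multiplicative technical-replicate
    noise (default 0.05, of the order of the kits' printed CV% row).
    """

    analytes: Mapping[str, Mapping]
    n_per_group: Mapping[str, int]
    replicate_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_cv < 0:
            raise ValidationError("replicate_cv must be non-negative")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValidationError("all group sizes must be positive")
        for analyte, spec in self.analytes.items():
            for g, q in spec["groups"].items():
                lognormal_from_quartiles(q["median"], q["q1"], q["q3"])  # validates


def load_elisa_defaults(
    n_per_group: Mapping[str, int] | None = None,
    replicate_cv: float | None = None,
    seed: int = 0,
) -> ElisaSimConfig:
    """The packaged default configuration: the six published analytes
    with their per-group medians/IQRs, LLOQs and the 68-sample
    validation-cohort design (22 control, 15 post-haemorrhagic, 11+11+9
    tumors)."""
    ref = importlib.resources.files("panelfinder.data") / "table1_elisa.yaml"
    raw = yaml.safe_load(ref.read_text())
    return ElisaSimConfig(
        analytes=raw["analytes"],
        n_per_group=dict(n_per_group or raw["n_per_group"]),
        replicate_cv=raw["replicate_cv"] if replicate_cv is None else replicate_cv,
        seed=seed,
    )


def simulate_elisa(cfg: ElisaSimConfig) -> tuple[dict[str, AssayPanel], SampleSheet]:
    """Draw triplicate assay panels for every configured analyte.

    Per sample, a true concentration is drawn from the group's fitted
    log-normal; the three replicates multiply it by independent
    log-normal noise whose CV is ``replicate_cv`` (zero CV makes the
    replicates identical).  Group sample medians converge to the
    configured medians as n grows.
    """
    rng = substream(cfg.seed, "simulate_elisa")
    groups = list(cfg.n_per_group)
    sample_ids: list[str] = []
    sample_group: list[str] = []
    for g in groups:
        for i in range(cfg.n_per_group[g]):
            sample_ids.append(f"{g}_{i + 1:03d}")
            sample_group.append(g)
    group_arr = np.asarray(sample_group)
    n = len(sample_ids)

    # multiplicative noise: lognormal with unit median and the requested CV
    sd_rep = float(np.sqrt(np.log1p(cfg.replicate_cv**2)))

    panels: dict[str, AssayPanel] = {}
    for analyte, spec in cfg.analytes.items():
        true = np.empty(n)
        for g in groups:
            q = spec["groups"][g]
            mu, sigma = lognormal_from_quartiles(q["median"], q["q1"], q["q3"])
            mask = group_arr == g
            true[mask] = np.exp(mu + sigma * rng.standard_normal(mask.sum()))
        reps = true[:, None] * np.exp(sd_rep * rng.standard_normal((n, 3)))
        conc = pd.DataFrame(reps, index=pd.Index(sample_ids, name="sample_id"),
                            columns=["rep1", "rep2", "rep3"])
        panels[analyte] = AssayPanel(analyte, conc, lloq=float(spec.get("lloq", 0.0)))

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "group": sample_group,
        "assay": "ELISA",
    }))
    return panels, sheet
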