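"""End-to-end orchestration: discovery and validation runs.

A single YAML-serializable configuration drives both arms; every run
writes its resolved configuration, a manifest of produced artifacts and
the package version next to the outputs, and all randomness flows from
one root seed through named per-stage substreams, so a re-run with the
same configuration is numerically identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from copy import deepcopy
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import subseed
from .core_data import (
    IntensityMatrix,
    SampleSheet,
    ValidationError,
    read_assay_table,
    read_matrix,
    read_protein_matrix,
    read_sample_sheet,
    venn_partition,
    write_matrix,
)
from .diagnostics import DEFAULT_COMPARISONS, validate_panel
from .differential import (
    VolcanoCurve,
    anova_table,
    apply_power_gate,
    volcano_classify,
    welch_t_table,
)
from .multivariate import (
    consensus_panel,
    kmeans_separation,
    mds_embed,
    plsda_fit,
    svm_rank,
)
from .preprocess import (
    filter_group_validity,
    impute_downshifted,
    log2_transform,
    normalize_median,
    normalize_quantile,
    zscore_rows,
)
from .synthetic import ElisaSimConfig, SimConfig, load_elisa_defaults, simulate_elisa, simulate_matrix

log = logging.getLogger("panelfinder")

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "run_discovery", "run_validation"]


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "panelfinder_out",
    "inputs": {
        "matrix": None,          # proteinGroups-style TSV (None -> simulate)
        "matrix_format": "proteingroups",   # or "tsv" (write_matrix output)
        "intensity_prefix": "LFQ intensity ",
        "sheet": None,
        "assay": None,           # long-format ELISA CSV (None -> simulate)
    },
    "simulate": {                # used when inputs.matrix is None
        "n_proteins": 1789,
        "n_markers": 104,
        "effect_log2": 2.0,
        "n_per_group": {"control": 17, "LGG_GT": 11, "EMB": 10, "other_tumor": 8},
    },
    "filter": {"min_frac": 0.70},
    "normalize": {"method": "median"},          # median | quantile | none
    "impute": {"enabled": True, "width": 0.3, "shift": 1.8},
    "volcano": {"c": 0.5, "x0": 1.0, "use_adjusted": True},
    "power_gate": {"enabled": False, "min_power": 0.80},
    "plsda": {"n_components": 2},
    "svm": {
        "n_splits": 200,
        "learn_frac": 0.65,
        "prefilter_p": 0.05,
        "importance": "linear_weight",
        "n_permutation_repeats": 5,
    },
    "consensus": {"k": None},
    "kmeans": {"k": 4, "n_init": 50},
    "roc": {"n_boot": 2000, "ci_method": "bootstrap"},
}


def _merge(base: dict, override: Mapping) -> dict:
    out = deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = deepcopy(v)
    return out


def resolve_config(overrides: Mapping | None = None) -> dict:
    """Defaults merged with user overrides; unknown top-level keys rejected."""
    overrides = overrides or {}
    unknown = set(overrides) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return _merge(DEFAULT_CONFIG, overrides)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, pd.Series):
        return o.to_dict()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="index")
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    # stringify non-string dict keys (e.g. pairwise tuples)
    def clean(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return clean(dataclasses.asdict(x))
        if isinstance(x, dict):
            return {str(k) if not isinstance(k, str) else k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        return x
    path.write_text(json.dumps(clean(obj), default=_json_default, indent=1, sort_keys=True))


def _finish_run(out: Path, cfg: dict, artifacts: dict[str, str]) -> None:
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    _write_json(
        {"version": __version__, "seed": cfg["seed"], "artifacts": artifacts},
        out / "manifest.json",
    )


def _load_discovery_inputs(cfg: dict) -> tuple[IntensityMatrix, SampleSheet, dict]:
    inputs = cfg["inputs"]
    if inputs["matrix"] is None:
        sim = cfg["simulate"]
        sc = SimConfig(
            n_per_group=sim["n_per_group"],
            n_proteins=sim["n_proteins"],
            n_markers=sim["n_markers"],
            effect_log2=sim["effect_log2"],
            seed=subseed(cfg["seed"], "simulate_matrix"),
        )
        return simulate_matrix(sc)
    if inputs["matrix_format"] == "proteingroups":
        m = read_protein_matrix(inputs["matrix"], intensity_prefix=inputs["intensity_prefix"])
    else:
        m = read_matrix(inputs["matrix"])
    sheet = read_sample_sheet(inputs["sheet"])
    return m, sheet, {}


def run_discovery(cfg: dict) -> dict:
    """Discovery arm: filter -> test -> rank -> consensus panel.

    Writes per-stage artifacts plus a manifest into ``cfg['out_dir']``
    and returns the in-memory results keyed by stage.
    """
    cfg = resolve_config(cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    t0 = time.time()

    def stage(name):
        log.info("[%s] %.1fs", name, time.time() - t0)

    m_raw, sheet, truth = _load_discovery_inputs(cfg)
    sheet = sheet.subset(m_raw.sample_ids)
    stage("inputs")
    if truth:
        _write_json(truth, out / "truth.json")
        artifacts["truth"] = "truth.json"

    # presence per clinical group for the Venn overlap summary
    present = m_raw.present()
    presence = {
        g: set(present.index[present[sheet.samples_in(g)].any(axis=1)])
        for g in sheet.groups
    }
    venn = venn_partition(presence)
    _write_json(
        {"region_counts": venn.region_counts, "total": venn.total,
         "percentages": venn.percentages()},
        out / "venn.json",
    )
    artifacts["venn"] = "venn.json"
    stage("venn")

    filtered, report = filter_group_validity(m_raw, sheet, cfg["filter"]["min_frac"])
    report.per_protein_validity.to_csv(out / "filter_validity.tsv", sep="\t")
    _write_json({"n_before": report.n_before, "n_after": report.n_after},
                out / "filter_report.json")
    artifacts["filter_report"] = "filter_report.json"

    m = log2_transform(filtered)
    method = cfg["normalize"]["method"]
    if method == "median":
        m = normalize_median(m)
    elif method == "quantile":
        m = normalize_quantile(m)
    elif method != "none":
        raise ValidationError(f"unknown normalization method {method!r}")
    stage("preprocess")

    # two-group contrast: all tumor groups pooled vs control
    tumor_groups = [g for g in sheet.groups if g != "control"]
    ttab = welch_t_table(m, sheet, tumor_groups, "control")
    curve = VolcanoCurve(c=cfg["volcano"]["c"], x0=cfg["volcano"]["x0"])
    ttab = volcano_classify(ttab, curve, use_adjusted=cfg["volcano"]["use_adjusted"])
    if cfg["power_gate"]["enabled"]:
        ttab = apply_power_gate(
            ttab, m, sheet, tumor_groups[0], "control",
            min_power=cfg["power_gate"]["min_power"],
        )
    ttab.to_csv(out / "differential_ttest.tsv", sep="\t")
    artifacts["ttest"] = "differential_ttest.tsv"

    atab = anova_table(m, sheet)
    atab.to_csv(out / "differential_anova.tsv", sep="\t")
    artifacts["anova"] = "differential_anova.tsv"
    stage("differential")

    if cfg["impute"]["enabled"] and m.n_missing():
        m_complete = impute_downshifted(
            m, width=cfg["impute"]["width"], shift=cfg["impute"]["shift"],
            seed=subseed(cfg["seed"], "impute"),
        )
    else:
        # drop any residual incomplete rows so multivariate stages can run
        m_complete = m.copy_with(m.values.dropna())

    coords = mds_embed(m_complete)
    coords.to_csv(out / "mds_coordinates.csv")
    artifacts["mds"] = "mds_coordinates.csv"

    sig_ids = [p for p in atab.index[atab["significant"]] if p in set(m_complete.protein_ids)]
    results: dict[str, Any] = {
        "matrix": m_complete, "sheet": sheet, "truth": truth, "venn": venn,
        "filter_report": report, "ttest": ttab, "anova": atab, "mds": coords,
    }
    if len(sig_ids) >= 2:
        m_sig = m_complete.copy_with(m_complete.values.loc[sig_ids])
        pls = plsda_fit(m_sig, sheet, n_components=cfg["plsda"]["n_components"])
        svm = svm_rank(
            m_sig, sheet,
            learn_frac=cfg["svm"]["learn_frac"],
            n_splits=cfg["svm"]["n_splits"],
            prefilter_p=cfg["svm"]["prefilter_p"],
            importance=cfg["svm"]["importance"],
            n_permutation_repeats=cfg["svm"]["n_permutation_repeats"],
            seed=subseed(cfg["seed"], "svm"),
        )
        panel = consensus_panel(pls, svm, k=cfg["consensus"]["k"])
        panel_tab = pd.DataFrame({
            "consensus_rank": panel.consensus_rank,
            "vip": pls.vip.loc[panel.members],
            "svm_rank": svm.rank.loc[panel.members],
        })
        panel_tab.index.name = "protein_id"
        panel_tab.to_csv(out / "core_panel.tsv", sep="\t")
        artifacts["core_panel"] = "core_panel.tsv"
        pls.scores.to_csv(out / "plsda_scores.csv")
        artifacts["plsda_scores"] = "plsda_scores.csv"

        clusters, ari = kmeans_separation(
            pls.scores, sheet, k=cfg["kmeans"]["k"], n_init=cfg["kmeans"]["n_init"],
            seed=subseed(cfg["seed"], "kmeans"),
        )
        _write_json(
            {"ari": ari, "clusters": clusters, "cv_accuracy": svm.cv_accuracy,
             "n_splits": svm.n_splits_run},
            out / "cluster_agreement.json",
        )
        artifacts["clusters"] = "cluster_agreement.json"

        heat = zscore_rows(m_sig.copy_with(m_sig.values.loc[panel.members]))
        write_matrix(heat, out / "panel_zscores.tsv")
        artifacts["panel_zscores"] = "panel_zscores.tsv"
        results.update({"plsda": pls, "svm": svm, "panel": panel,
                        "kmeans_ari": ari, "clusters": clusters})
    else:
        log.warning("fewer than 2 ANOVA-significant proteins; skipping ranking stages")
    stage("multivariate")

    _finish_run(out, cfg, artifacts)
    return results


def run_validation(cfg: dict) -> dict:
    """Validation arm: assay panels -> Kruskal–Wallis/Dunn + ROC table."""
    cfg = resolve_config(cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    if cfg["inputs"]["assay"] is None:
        ecfg = load_elisa_defaults(seed=subseed(cfg["seed"], "simulate_elisa"))
        panels, sheet = simulate_elisa(ecfg)
    else:
        panels = read_assay_table(cfg["inputs"]["assay"])
        sheet = read_sample_sheet(cfg["inputs"]["sheet"])

    comparisons = [
        (name, pos_g, neg_g)
        for name, pos_g, neg_g in DEFAULT_COMPARISONS
        if sheet.samples_in(pos_g) and sheet.samples_in(neg_g)
    ]
    table, details = validate_panel(
        panels, sheet, comparisons=comparisons,
        n_boot=cfg["roc"]["n_boot"], seed=subseed(cfg["seed"], "roc"),
        ci_method=cfg["roc"]["ci_method"],
    )
    table.to_csv(out / "validation_report.tsv", sep="\t", index=False)
    artifacts["validation_report"] = "validation_report.tsv"
    _write_json(
        {a: {"kruskal": d["kruskal"], "roc": d["roc"]} for a, d in details.items()},
        out / "validation_details.json",
    )
    artifacts["validation_details"] = "validation_details.json"

    _finish_run(out, cfg, artifacts)
    return {"table": table, "details": details, "panels": panels, "sheet": sheet}
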