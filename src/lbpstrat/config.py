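"""Run configuration, input validation, and the end-to-end pipeline.

A :class:`RunConfig` names every seed and switch; a run directory written
by :func:`run_full_pipeline` contains all artifacts plus a manifest (config
echo, seeds, software versions, and row counts at each exclusion step), so
re-executing from the manifest reproduces all numeric outputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import lbpstrat
from lbpstrat import synthetic
from lbpstrat.consensus import stratify
from lbpstrat.preprocess import assemble_features
from lbpstrat.profiles import forest_data, or_table, prevalence_summary
from lbpstrat.validation import validate_clusters

#: Columns a cohort CSV must provide, with the staged exclusion rules
#: applied in the study's flowchart order: imaging availability first,
#: then self-reported pain/bothersomeness and smoking, then BMI.
EXCLUSION_STAGES = [
    ("missing imaging biomarkers",
     ["pfirrmann_l34", "pfirrmann_l45", "pfirrmann_l5s1",
      "ft_l34", "ft_l45", "ft_l5s1"]),
    ("missing self-reported data on low back pain frequency",
     ["lbp_frequency"]),
    ("missing self-reported bothersomeness", ["bothersomeness_raw"]),
    ("missing smoking status", ["smoking"]),
    ("missing BMI", ["bmi"]),
]

RANGE_RULES = {
    "sex": ("categorical", {0, 1}),
    "smoking": ("categorical", {0, 1, 2}),
    "pfirrmann_l34": ("categorical", {2, 3, 4, 5}),
    "pfirrmann_l45": ("categorical", {2, 3, 4, 5}),
    "pfirrmann_l5s1": ("categorical", {2, 3, 4, 5}),
    "lbp_frequency": ("categorical", {0, 1, 2, 3, 4}),
    "bothersomeness_raw": ("categorical", set(range(11))),
    "risk_level": ("categorical", {0, 1, 2}),
    "bmi": ("range", (10.0, 80.0)),
    "ft_l34": ("range", (0.0, np.inf)),
    "ft_l45": ("range", (0.0, np.inf)),
    "ft_l5s1": ("range", (0.0, np.inf)),
}

REQUIRED_COLUMNS = [
    "sex", "bmi", "smoking",
    "pfirrmann_l34", "pfirrmann_l45", "pfirrmann_l5s1",
    "ft_l34", "ft_l45", "ft_l5s1",
    "instrument_total", "risk_level", "lbp_frequency", "bothersomeness_raw",
]


@dataclass
class RunConfig:
    instrument: str = "SBT"
    include_risk_score: bool = True
    risk_score_column: str = "instrument_total"
    grid: dict = field(default_factory=lambda: {"n_components": [7],
                                                "n_neighbors": [20],
                                                "min_dist": [0.3],
                                                "k": [2, 3, 4, 5]})
    n_folds: int = 5
    n_boot: int = 1000
    n_shuffle_repeats: int = 10
    n_participants: int = 800
    seeds: dict = field(default_factory=dict)
    output_dir: str = "lbpstrat_run"

    SEED_NAMES = ("simulation", "umap", "folds", "kmeans", "bootstrap", "shuffle")

    def resolve_seeds(self, master: int | None = None) -> dict:
        """Fill in any absent named seeds (drawn once from ``master`` or
        from entropy) so reruns from the persisted config are reproducible."""
        rng = np.random.default_rng(master)
        for name in self.SEED_NAMES:
            if name not in self.seeds or self.seeds[name] is None:
                self.seeds[name] = int(rng.integers(0, 2**31 - 1))
        return self.seeds

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def validate_input(cohort_csv) -> pd.DataFrame:
    """Row-level problem report for a cohort CSV.

    Reports missing required columns, per-stage missing-field exclusions
    (in flowchart order), and out-of-range values.  Returns a DataFrame
    with columns (row, rule, column); empty for a clean file.
    """
    cohort = pd.read_csv(cohort_csv)
    problems = []
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    for c in missing_cols:
        problems.append({"row": -1, "rule": "missing required column", "column": c})
    excluded = np.zeros(len(cohort), dtype=bool)
    for rule, cols in EXCLUSION_STAGES:
        cols = [c for c in cols if c in cohort.columns]
        if not cols:
            continue
        stage_missing = cohort[cols].isna().any(axis=1) & ~excluded
        for idx in cohort.index[stage_missing]:
            bad = [c for c in cols if pd.isna(cohort.at[idx, c])]
            for c in bad:
                problems.append({"row": int(idx), "rule": rule, "column": c})
        excluded |= stage_missing
    for col, (kind, spec) in RANGE_RULES.items():
        if col not in cohort.columns:
            continue
        vals = cohort[col]
        ok = vals.isna()
        if kind == "categorical":
            ok |= vals.isin(list(spec))
        else:
            lo, hi = spec
            ok |= (vals >= lo) & (vals <= hi)
        for idx in cohort.index[~ok]:
            problems.append({"row": int(idx), "rule": "out-of-range value",
                             "column": col})
    return pd.DataFrame(problems, columns=["row", "rule", "column"])


def apply_exclusions(cohort: pd.DataFrame):
    """Drop rows with missing required fields, stage by stage; returns the
    retained cohort and the per-stage dropped counts."""
    counts = {}
    kept = cohort
    for rule, cols in EXCLUSION_STAGES:
        cols = [c for c in cols if c in kept.columns]
        if not cols:
            counts[rule] = 0
            continue
        drop = kept[cols].isna().any(axis=1)
        counts[rule] = int(drop.sum())
        kept = kept.loc[~drop]
    return kept.reset_index(drop=True), counts


def run_full_pipeline(config: RunConfig, cohort_csv=None, simulate=False,
                      master_seed=None) -> Path:
    """Execute the full pipeline and write all artifacts to a run directory.

    Stages: (optional) cohort simulation -> input validation and staged
    exclusions -> feature assembly and scaling -> UMAP + consensus
    k-means (grid search over ``config.grid``) -> cluster profiling
    (prevalence, adjusted ORs, forest data) -> validation (CV accuracy,
    shuffled baseline, bootstrap ROC/PR, DCA).  A stage failure aborts
    with a stage-named message; artifacts written so far are retained.
    """
    config.resolve_seeds(master_seed)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds
    manifest = {
        "package_version": lbpstrat.__version__,
        "python_version": platform.python_version(),
        "config": asdict(config),
        "stages": {},
    }

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            _write_json(out / "manifest.json", manifest)
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    if simulate:
        def _simulate():
            sim_cfg = synthetic.default_config(
                n_participants=config.n_participants,
                instrument=config.instrument, seed=seeds["simulation"])
            cohort = synthetic.generate_cohort(sim_cfg)
            synthetic.write_cohort(cohort, sim_cfg, out / "cohort.csv",
                                   out / "cohort_metadata.json")
            return cohort
        cohort = _stage("simulate", _simulate)
        manifest["stages"]["simulate"] = {"n_rows": int(len(cohort))}
    else:
        if cohort_csv is None:
            raise ValueError("either pass cohort_csv or set simulate=True")
        cohort = _stage("load", lambda: pd.read_csv(cohort_csv))
        missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
        if missing:
            raise RuntimeError("pipeline stage 'load' failed: cohort CSV is "
                               f"missing column(s): {', '.join(missing)}")
        manifest["stages"]["load"] = {"n_rows": int(len(cohort))}

    cohort, dropped = _stage("exclusions", lambda: apply_exclusions(cohort))
    manifest["stages"]["exclusions"] = {"dropped": dropped,
                                        "n_rows": int(len(cohort))}
    synthetic.marginal_report(cohort).to_csv(out / "baseline_characteristics.csv",
                                             index=False)

    result = _stage("stratify", lambda: stratify(
        cohort, instrument=config.instrument, k=None, grid=config.grid,
        n_folds=config.n_folds, seed=seeds["umap"],
        include_risk_score=config.include_risk_score,
        risk_score_column=config.risk_score_column))
    labels = result.labels
    pd.DataFrame({"id": cohort.get("id", pd.RangeIndex(len(cohort))),
                  "fold_id": result.centroid_matrix.fold_id,
                  "label": labels}).to_csv(out / "labels.csv", index=False)
    pd.DataFrame(result.centroid_matrix.assigned_centroid).to_csv(
        out / "centroid_matrix.csv", index=False)
    if result.grid_table is not None:
        result.grid_table.to_csv(out / "grid_search.csv", index=False)
    _write_json(out / "quality_metrics.json",
                {**result.quality, "hyperparams": result.hyperparams})
    manifest["stages"]["stratify"] = {"k": result.k, **result.quality}

    summary = _stage("profile", lambda: prevalence_summary(cohort, labels))
    summary.to_csv(out / "cluster_summary.csv", index=False)
    ors = _stage("profile", lambda: or_table(
        cohort, labels, risk_score_column=config.risk_score_column))
    ors.to_csv(out / "odds_ratios.csv", index=False)
    forest = forest_data(ors)
    forest.to_json(out / "forest_data.json", orient="records", indent=2)
    manifest["stages"]["profile"] = {"n_or_rows": int(len(ors))}

    fm = assemble_features(cohort, instrument=config.instrument,
                           include_risk_score=config.include_risk_score,
                           risk_score_column=config.risk_score_column,
                           scale=False)
    report = _stage("validate", lambda: validate_clusters(
        fm.to_numpy(dtype=float), labels, n_folds=config.n_folds,
        seed=seeds["bootstrap"], n_boot=config.n_boot,
        n_shuffle_repeats=config.n_shuffle_repeats))
    _write_json(out / "validation_report.json", {
        "fold_accuracies": report.fold_accuracies.tolist(),
        "mean_accuracy": report.mean_accuracy,
        "sd_accuracy": report.sd_accuracy,
        "shuffled_mean": float(np.mean(report.shuffled_accuracies)),
        "shuffled_sd": float(np.std(report.shuffled_accuracies, ddof=1)),
        "auroc": {c: report.roc_curves[c]["auroc"] for c in report.roc_curves},
        "auprc": {c: report.pr_curves[c]["auprc"] for c in report.pr_curves},
    })
    for cl, curve in report.dca.items():
        pd.DataFrame({"threshold": curve.thresholds,
                      "net_benefit": curve.net_benefit,
                      "ci_low": curve.ci_low, "ci_high": curve.ci_high,
                      "treat_all": curve.treat_all,
                      "treat_none": curve.treat_none}).to_csv(
            out / f"net_benefit_class{cl}.csv", index=False)
    for cl in report.roc_curves:
        r, p = report.roc_curves[cl], report.pr_curves[cl]
        pd.DataFrame({"fpr": r["fpr"], "tpr": r["tpr"], "tpr_low": r["tpr_low"],
                      "tpr_high": r["tpr_high"]}).to_csv(
            out / f"roc_class{cl}.csv", index=False)
        pd.DataFrame({"recall": p["recall"], "precision": p["precision"],
                      "precision_low": p["precision_low"],
                      "precision_high": p["precision_high"]}).to_csv(
            out / f"pr_class{cl}.csv", index=False)
    manifest["stages"]["validate"] = {"mean_accuracy": report.mean_accuracy}

    _write_json(out / "manifest.json", manifest)
    return out


def _write_json(path, obj):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
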