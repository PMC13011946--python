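"""Cluster characterization: prevalence summaries, cumulative FT-DD
severity score, and confounder-adjusted odds ratios.

For each cluster and each binary outcome (frequent pain; high
bothersomeness), a logistic regression restricted to that cluster's rows
estimates per-feature odds ratios adjusted for the confounders sex, BMI,
and smoking.  Wald 95% confidence intervals and two-sided p-values are
reported per feature; no multiple-testing correction is applied (each
feature is flagged at p < 0.05, matching standard forest-plot practice
for descriptive cluster profiling).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from lbpstrat.preprocess import (
    LUMBAR_LEVELS,
    bin_facet_tropism,
    bin_pfirrmann,
    derive_frequent_pain,
    encode_bothersomeness,
    robust_scale,
)

#: Cluster-specific features entering the per-cluster OR models
#: (confounders sex, bmi, smoking are added separately).
OR_FEATURES = ["pfirrmann_l34", "pfirrmann_l45", "pfirrmann_l5s1",
               "ft_l34", "ft_l45", "ft_l5s1", "risk_score"]
OR_CONFOUNDERS = ["sex", "bmi", "smoking"]

OUTCOMES = ("frequent_pain", "high_bothersomeness")


def _binary_outcome(cohort: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome == "frequent_pain":
        return derive_frequent_pain(cohort["lbp_frequency"].to_numpy().astype(int)).astype(int)
    if outcome == "high_bothersomeness":
        cat = encode_bothersomeness(cohort["bothersomeness_raw"].to_numpy().astype(int))
        return (np.asarray(cat) == 2).astype(int)
    raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


def cumulative_ftdd_score(row) -> float:
    """Cumulative facet-tropism / disc-degeneration severity score.

    Sum of the three Pfirrmann grades (2-5 each) and the three
    facet-tropism category ordinals (0 normal, 1 moderate, 2 severe);
    range 6-21.  Accepts a Series/dict (single row) or a DataFrame
    (vectorized).
    """
    if isinstance(row, pd.DataFrame):
        total = np.zeros(len(row), dtype=float)
        for level in LUMBAR_LEVELS:
            for col in (f"pfirrmann_{level}", f"ft_{level}"):
                if col not in row.columns:
                    raise ValueError(f"missing imaging field {col}")
            grades = row[f"pfirrmann_{level}"].to_numpy()
            bin_pfirrmann(grades)  # domain check
            total += grades.astype(float)
            total += np.asarray(bin_facet_tropism(row[f"ft_{level}"].to_numpy()), dtype=float)
        return total
    for level in LUMBAR_LEVELS:
        for col in (f"pfirrmann_{level}", f"ft_{level}"):
            if col not in row:
                raise ValueError(f"missing imaging field {col}")
    score = 0.0
    for level in LUMBAR_LEVELS:
        grade = row[f"pfirrmann_{level}"]
        bin_pfirrmann(grade)  # domain check
        score += float(grade) + float(bin_facet_tropism(row[f"ft_{level}"]))
    return score


def prevalence_summary(cohort: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-cluster descriptive summary.

    For each cluster: n; % frequent pain; bothersomeness low/moderate/high
    %; risk-level low/medium/high %; % severe disc degeneration (grades
    4-5) per level; % severe facet tropism (>15 degrees) per level; and
    mean +/- SE of the cumulative FT-DD score.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ValueError("labels length does not match cohort")
    freq = derive_frequent_pain(cohort["lbp_frequency"].to_numpy().astype(int))
    bother = np.asarray(encode_bothersomeness(cohort["bothersomeness_raw"].to_numpy().astype(int)))
    ftdd = cumulative_ftdd_score(cohort)

    rows = []
    for cl in np.unique(labels):
        mask = labels == cl
        n = int(mask.sum())
        row = {"cluster": int(cl), "n": n,
               "percent_frequent_pain": 100.0 * freq[mask].mean()}
        for code, nm in enumerate(["low", "moderate", "high"]):
            row[f"bothersomeness_{nm}_pct"] = 100.0 * (bother[mask] == code).mean()
        rl = cohort.loc[mask, "risk_level"].to_numpy()
        for code, nm in enumerate(["low", "medium", "high"]):
            row[f"risk_{nm}_pct"] = 100.0 * (rl == code).mean()
        for level in LUMBAR_LEVELS:
            g = cohort.loc[mask, f"pfirrmann_{level}"].to_numpy()
            row[f"severe_dd_{level}_pct"] = 100.0 * np.isin(g, [4, 5]).mean()
            a = cohort.loc[mask, f"ft_{level}"].to_numpy()
            row[f"severe_ft_{level}_pct"] = 100.0 * (np.asarray(bin_facet_tropism(a)) == 2).mean()
        row["ftdd_mean"] = float(np.mean(ftdd[mask]))
        row["ftdd_se"] = float(np.std(ftdd[mask], ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def adjusted_odds_ratios(cohort: pd.DataFrame, labels, cluster_id, outcome,
                         risk_score_column="instrument_total",
                         min_cluster_size=25, alpha=0.05,
                         scale_covariates=True) -> pd.DataFrame:
    """Confounder-adjusted odds ratios for one cluster and one outcome.

    Fits a single logistic regression on the cluster's rows: the binary
    outcome against the robust-scaled cluster features (Pfirrmann grade
    and facet-tropism angle per level, psychosocial score) plus the
    confounders sex, BMI, and smoking.  OR = exp(coefficient) with Wald
    95% CI and two-sided p-value per feature.  Zero-variance covariates
    are dropped (reported with status ``dropped``); non-convergence or
    separation is reported per row rather than raised.

    With ``scale_covariates=True`` (default) ORs are per IQR of the
    covariate; set it to False for per-unit ORs on the raw scale.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ValueError("labels length does not match cohort")
    mask = labels == cluster_id
    n = int(mask.sum())
    if n < min_cluster_size:
        raise ValueError(f"cluster {cluster_id} has {n} rows; "
                         f"need at least {min_cluster_size}")
    sub = cohort.loc[mask].reset_index(drop=True)
    y = _binary_outcome(sub, outcome)
    if y.min() == y.max():
        raise ValueError(f"degenerate outcome: '{outcome}' is constant in cluster {cluster_id}")

    design = sub[["pfirrmann_l34", "pfirrmann_l45", "pfirrmann_l5s1",
                  "ft_l34", "ft_l45", "ft_l5s1"]].astype(float).copy()
    design["risk_score"] = sub[risk_score_column].astype(float)
    for c in OR_CONFOUNDERS:
        design[c] = sub[c].astype(float)

    kept, dropped = [], []
    for c in design.columns:
        (dropped if design[c].nunique() <= 1 else kept).append(c)

    covars = robust_scale(design[kept]).to_frame() if scale_covariates else design[kept]
    X = sm.add_constant(covars, has_constant="add")
    rows = []
    status = "ok"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            status = "non_converged"
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
    except Exception as exc:  # perfect separation, singular matrix, ...
        status = f"failed: {type(exc).__name__}"
        params = bse = pvals = None

    z = 1.959963984540054  # Phi^{-1}(0.975)
    for feat in kept:
        if params is None or not np.isfinite(bse[feat]):
            rows.append({"cluster_id": int(cluster_id), "outcome": outcome,
                         "feature": feat, "odds_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan,
                         "significant": False, "status": status})
            continue
        coef, se = params[feat], bse[feat]
        rows.append({
            "cluster_id": int(cluster_id), "outcome": outcome, "feature": feat,
            "odds_ratio": float(np.exp(coef)),
            "ci_low": float(np.exp(coef - z * se)),
            "ci_high": float(np.exp(coef + z * se)),
            "p_value": float(pvals[feat]),
            "significant": bool(pvals[feat] < alpha),
            "status": status,
        })
    for feat in dropped:
        rows.append({"cluster_id": int(cluster_id), "outcome": outcome,
                     "feature": feat, "odds_ratio": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p_value": np.nan, "significant": False,
                     "status": "dropped: zero variance"})
    return pd.DataFrame(rows)


def or_table(cohort, labels, outcomes=OUTCOMES, **kwargs) -> pd.DataFrame:
    """Adjusted ORs for every (cluster, outcome) pair; clusters that are
    too small or have a degenerate outcome are skipped with a note row."""
    frames = []
    for cl in np.unique(np.asarray(labels)):
        for outcome in outcomes:
            try:
                frames.append(adjusted_odds_ratios(cohort, labels, cl, outcome, **kwargs))
            except ValueError as exc:
                frames.append(pd.DataFrame([{
                    "cluster_id": int(cl), "outcome": outcome, "feature": None,
                    "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_value": np.nan, "significant": False,
                    "status": f"skipped: {exc}"}]))
    return pd.concat(frames, ignore_index=True)


def forest_data(table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready forest layout: log10 OR and CI positions per
    (cluster, outcome) panel, significance flags, and a reference at
    OR = 1 (log position 0).  Rows with missing ORs become empty-panel
    markers instead of crashing downstream plotting."""
    if table.empty:
        raise ValueError("empty OR table")
    out = table.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log10_or"] = np.log10(out["odds_ratio"])
        out["log10_ci_low"] = np.log10(out["ci_low"])
        out["log10_ci_high"] = np.log10(out["ci_high"])
    out["reference_log10"] = 0.0
    out["panel"] = out["cluster_id"].astype(str) + ":" + out["outcome"].astype(str)
    out["empty_panel"] = ~np.isfinite(out["log10_or"])
    return out.sort_values(["outcome", "cluster_id", "feature"]).reset_index(drop=True)


def plot_forest(forest: pd.DataFrame, path=None):
    """Render forest panels (one per cluster x outcome) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = forest["panel"].unique()
    fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 4),
                             squeeze=False)
    for ax, panel in zip(axes[0], panels):
        sub = forest[(forest["panel"] == panel) & ~forest["empty_panel"]]
        ypos = np.arange(len(sub))
        ax.axvline(0.0, linestyle="--", color="tab:blue")
        for i, (_, row) in enumerate(sub.iterrows()):
            color = "red" if row["significant"] else "black"
            ax.plot([row["log10_ci_low"], row["log10_ci_high"]], [i, i], color=color)
            ax.plot(row["log10_or"], i, "o", color=color)
        ax.set_yticks(ypos)
        ax.set_yticklabels(sub["feature"])
        ax.set_xlabel("log10 odds ratio")
        ax.set_title(panel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
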