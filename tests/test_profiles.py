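"""Cluster profiling: prevalence arithmetic, the cumulative FT-DD severity
score, adjusted odds ratios, and forest-plot data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lbpstrat as L
from lbpstrat.profiles import forest_data, or_table


def hand_cohort():
    """Six rows with hand-computable summaries (clusters of 4 and 2)."""
    return pd.DataFrame({
        "id": range(6),
        "sex": [0, 1, 0, 1, 0, 1],
        "bmi": [22.0, 27.0, 31.0, 24.0, 26.0, 29.0],
        "smoking": [0, 1, 2, 0, 1, 2],
        "pfirrmann_l34": [2, 3, 4, 2, 5, 3],
        "pfirrmann_l45": [3, 4, 5, 2, 4, 3],
        "pfirrmann_l5s1": [2, 5, 4, 3, 5, 2],
        "ft_l34": [5.0, 12.0, 20.0, 3.0, 16.0, 8.0],
        "ft_l45": [9.0, 14.0, 18.0, 6.0, 11.0, 10.0],
        "ft_l5s1": [4.0, 16.0, 22.0, 9.0, 13.0, 7.0],
        "instrument": ["SBT"] * 6,
        "instrument_total": [1, 5, 3, 0, 7, 2],
        "risk_level": [0, 1, 0, 0, 2, 0],
        "lbp_frequency": [0, 3, 4, 1, 4, 2],
        "bothersomeness_raw": [0, 7, 5, 2, 9, 3],
    })


@pytest.mark.parametrize(
    "grades, angles, expected",
    [((2, 2, 2), (0.0, 5.0, 9.9), 6.0),      # minimum
     ((5, 5, 5), (16.0, 20.0, 30.0), 21.0),  # maximum
     ((2, 3, 4), (5.0, 12.0, 8.0), 10.0)],   # direct sum
)
def test_cumulative_ftdd_score_examples(grades, angles, expected):
    row = {}
    for level, g, a in zip(("l34", "l45", "l5s1"), grades, angles):
        row[f"pfirrmann_{level}"] = g
        row[f"ft_{level}"] = a
    assert L.cumulative_ftdd_score(row) == expected


def test_cumulative_ftdd_score_missing_field():
    with pytest.raises(ValueError, match="ft_l45"):
        L.cumulative_ftdd_score({"pfirrmann_l34": 2, "pfirrmann_l45": 3,
                                 "pfirrmann_l5s1": 4, "ft_l34": 1.0,
                                 "ft_l5s1": 2.0})


@settings(deadline=None, derandomize=True, max_examples=50)
@given(grades=st.tuples(*[st.integers(2, 5)] * 3),
       angles=st.tuples(*[st.floats(0, 40, allow_nan=False)] * 3),
       bump=st.integers(0, 2))
def test_cumulative_ftdd_score_monotone(grades, angles, bump):
    row = {f"pfirrmann_{lv}": g for lv, g in zip(("l34", "l45", "l5s1"), grades)}
    row.update({f"ft_{lv}": a for lv, a in zip(("l34", "l45", "l5s1"), angles)})
    base = L.cumulative_ftdd_score(row)
    worse = dict(row)
    worse["pfirrmann_l45"] = min(5, worse["pfirrmann_l45"] + bump)
    worse["ft_l34"] = worse["ft_l34"] + 10.0 * bump
    assert L.cumulative_ftdd_score(worse) >= base


def test_prevalence_summary_hand_fixture():
    cohort = hand_cohort()
    labels = np.array([0, 0, 0, 0, 1, 1])
    summary = L.prevalence_summary(cohort, labels).set_index("cluster")
    # cluster 0: rows 0-3; frequent pain rows are codes 3,4 -> 2 of 4
    assert summary.loc[0, "n"] == 4
    assert summary.loc[0, "percent_frequent_pain"] == pytest.approx(50.0)
    # bothersomeness raw [0,7,5,2] -> low,high,moderate,low
    assert summary.loc[0, "bothersomeness_low_pct"] == pytest.approx(50.0)
    assert summary.loc[0, "bothersomeness_moderate_pct"] == pytest.approx(25.0)
    # severe DD at l5s1 in cluster 0: grades [2,5,4,3] -> 2 of 4
    assert summary.loc[0, "severe_dd_l5s1_pct"] == pytest.approx(50.0)
    # severe FT (>15 deg) at l34 in cluster 0: [5,12,20,3] -> 1 of 4
    assert summary.loc[0, "severe_ft_l34_pct"] == pytest.approx(25.0)
    # cumulative score cluster 1: rows 4,5
    s4 = 5 + 4 + 5 + 2 + 1 + 1   # grades 5,4,5; ft 16->2, 11->1, 13->1
    s5 = 3 + 3 + 2 + 0 + 1 + 0   # grades 3,3,2; ft 8->0, 10->1, 7->0
    assert summary.loc[1, "ftdd_mean"] == pytest.approx((s4 + s5) / 2)
    assert summary["n"].sum() == len(cohort)


def test_prevalence_summary_single_cluster_matches_marginals(small_cohort):
    cohort, _ = small_cohort
    summary = L.prevalence_summary(cohort, np.zeros(len(cohort), dtype=int))
    freq = L.derive_frequent_pain(cohort["lbp_frequency"].to_numpy())
    assert summary.loc[0, "percent_frequent_pain"] == pytest.approx(100 * freq.mean())
    rep = L.marginal_report(cohort)
    high = rep[(rep.variable == "bothersomeness") & (rep.category == "high")]
    exact = 100 * high["count"].iloc[0] / len(cohort)
    assert summary.loc[0, "bothersomeness_high_pct"] == pytest.approx(exact)


def test_merged_clusters_are_size_weighted_average(small_cohort):
    cohort, _ = small_cohort
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 2, len(cohort))
    parts = L.prevalence_summary(cohort, labels).set_index("cluster")
    merged = L.prevalence_summary(cohort, np.zeros(len(cohort), dtype=int))
    w = parts["n"] / parts["n"].sum()
    weighted = (parts["percent_frequent_pain"] * w).sum()
    assert merged.loc[0, "percent_frequent_pain"] == pytest.approx(weighted)


def test_labels_length_mismatch_rejected(small_cohort):
    cohort, _ = small_cohort
    with pytest.raises(ValueError, match="length"):
        L.prevalence_summary(cohort, np.zeros(5))


def test_adjusted_or_single_replicate_recovers_effect():
    cfg = L.default_config(n_participants=2000, seed=9)
    cfg.subgroup_weights = (1.0, 0.0, 0.0)
    cfg.outcome_model.freq_coefficients = {"risk_level": float(np.log(2.0))}
    cohort = L.generate_cohort(cfg)
    table = L.adjusted_odds_ratios(
        cohort, np.zeros(len(cohort), dtype=int), 0, "frequent_pain",
        risk_score_column="risk_level", scale_covariates=False)
    row = table.set_index("feature").loc["risk_score"]
    assert row["status"] == "ok"
    assert row["ci_low"] <= 2.0 <= row["ci_high"]


def test_adjusted_or_degenerate_outcome_and_zero_variance(small_cohort):
    cohort, _ = small_cohort
    cohort = cohort.copy()
    labels = np.zeros(len(cohort), dtype=int)
    degenerate = cohort.copy()
    degenerate["lbp_frequency"] = 0
    with pytest.raises(ValueError, match="degenerate outcome"):
        L.adjusted_odds_ratios(degenerate, labels, 0, "frequent_pain")
    constant = cohort.copy()
    constant["sex"] = 1
    table = L.adjusted_odds_ratios(constant, labels, 0, "frequent_pain")
    row = table.set_index("feature").loc["sex"]
    assert row["status"].startswith("dropped")
    assert not row["significant"]


def test_adjusted_or_small_cluster_rejected(small_cohort):
    cohort, _ = small_cohort
    labels = np.zeros(len(cohort), dtype=int)
    labels[:10] = 1
    with pytest.raises(ValueError, match="10 rows"):
        L.adjusted_odds_ratios(cohort, labels, 1, "frequent_pain")


def test_forest_data_positions():
    table = pd.DataFrame({
        "cluster_id": [0, 0, 1], "outcome": ["frequent_pain"] * 3,
        "feature": ["a", "b", "c"],
        "odds_ratio": [1.0, 7.03, np.nan],
        "ci_low": [0.5, 3.0, np.nan], "ci_high": [2.0, 16.0, np.nan],
        "p_value": [0.9, 0.001, np.nan],
        "significant": [False, True, False], "status": ["ok", "ok", "skipped"],
    })
    forest = forest_data(table)
    by_feat = forest.set_index("feature")
    assert by_feat.loc["a", "log10_or"] == pytest.approx(0.0)
    assert by_feat.loc["b", "log10_or"] == pytest.approx(0.8470, abs=1e-3)
    assert bool(by_feat.loc["c", "empty_panel"])
    assert (forest["reference_log10"] == 0.0).all()
    with pytest.raises(ValueError):
        forest_data(table.iloc[0:0])


def test_or_table_covers_all_cluster_outcome_pairs(small_cohort):
    cohort, _ = small_cohort
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 2, len(cohort))
    table = or_table(cohort, labels)
    pairs = set(zip(table["cluster_id"], table["outcome"]))
    assert pairs == {(c, o) for c in (0, 1)
                     for o in ("frequent_pain", "high_bothersomeness")}
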