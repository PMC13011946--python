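"""Encoding, binning, and scaling of cohort variables.

All binning rules are total functions on their stated domains and raise
``ValueError`` outside them.  Scalar functions accept numpy arrays as well
and broadcast elementwise.

Clustering feature assembly follows the study design: imaging biomarkers
(disc-degeneration Pfirrmann grades and facet-tropism angles at L3/4,
L4/5, and L5/S1), smoking status, BMI, sex, and the psychosocial
instrument score.  Self-reported outcomes (LBP frequency, bothersomeness)
never enter the feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed column order of the clustering feature matrix.
FEATURE_COLUMNS = [
    "pfirrmann_l34",
    "pfirrmann_l45",
    "pfirrmann_l5s1",
    "ft_l34",
    "ft_l45",
    "ft_l5s1",
    "smoking",
    "bmi",
    "sex",
    "risk_score",
]

#: Columns that are outcomes and must never appear among features.
OUTCOME_COLUMNS = ["lbp_frequency", "bothersomeness_raw"]

LUMBAR_LEVELS = ["l34", "l45", "l5s1"]

DD_SEVERITY_LABELS = ["mild", "moderate", "severe"]
FT_CATEGORY_LABELS = ["normal", "moderate", "severe"]
BOTHERSOMENESS_LABELS = ["low", "moderate", "high"]
BMI_LABELS = ["underweight", "healthy", "overweight", "obese"]


@dataclass
class FeatureMatrix:
    """Robust-scaled clustering inputs with inverse-transform metadata.

    ``values`` holds the scaled n x p matrix; ``scaling_params`` maps each
    column name to its (median, IQR) pair so ``x_scaled * IQR + median``
    reproduces the raw input exactly.  Columns with zero IQR are centred
    only and listed in ``zero_iqr_columns``.
    """

    values: np.ndarray
    column_names: list[str]
    scaling_params: dict[str, tuple[float, float]]
    instrument: str = "SBT"
    zero_iqr_columns: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def inverse_transform(self) -> np.ndarray:
        """Map scaled values back to the original scale."""
        out = np.empty_like(self.values)
        for j, name in enumerate(self.column_names):
            median, iqr = self.scaling_params[name]
            scale = iqr if name not in self.zero_iqr_columns else 1.0
            out[:, j] = self.values[:, j] * scale + median
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


def _check_range(x, lo, hi, name, lo_open=False, hi_open=False):
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    bad_lo = (x <= lo) if lo_open else (x < lo)
    bad_hi = (x >= hi) if hi_open else (x > hi)
    if np.any(bad_lo | bad_hi):
        raise ValueError(f"{name} outside allowed range "
                         f"{'(' if lo_open else '['}{lo}, {hi}{')' if hi_open else ']'}")


def bin_pfirrmann(grade):
    """Bin a Pfirrmann grade into disc-degeneration severity.

    Grade 2 is mild, grade 3 moderate, and grades 4-5 severe degeneration.
    Returns 0/1/2 (mild/moderate/severe); use
    ``DD_SEVERITY_LABELS`` for names.
    """
    g = np.asarray(grade)
    if not np.all(np.isin(g, [2, 3, 4, 5])):
        raise ValueError("Pfirrmann grade must be in {2, 3, 4, 5}")
    out = np.where(g <= 2, 0, np.where(g == 3, 1, 2))
    return out if out.ndim else int(out)


def bin_facet_tropism(angle):
    """Bin a facet-tropism angle (degrees) into a severity category.

    Normal is [0, 10) degrees, moderately accentuated [10, 15], and
    severely accentuated >15; the boundary at exactly 10 degrees falls in
    the moderate bin and exactly 15 degrees is still moderate.  Returns
    0/1/2 (normal/moderate/severe).
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a < 0):
        raise ValueError("facet-tropism angle must be finite and non-negative")
    out = np.where(a < 10.0, 0, np.where(a <= 15.0, 1, 2))
    return out if out.ndim else int(out)


def encode_bothersomeness(raw):
    """Encode 0-10 bothersomeness: 0-3 low, 4-5 moderate, 6-10 high."""
    r = np.asarray(raw)
    if not np.all(np.isin(r, np.arange(11))):
        raise ValueError("bothersomeness must be an integer in 0..10")
    out = np.where(r <= 3, 0, np.where(r <= 5, 1, 2))
    return out if out.ndim else int(out)


def derive_frequent_pain(lbp_frequency):
    """Composite 'frequent pain': LBP on >30 days (code 3) or daily (4)."""
    c = np.asarray(lbp_frequency)
    if not np.all(np.isin(c, np.arange(5))):
        raise ValueError("lbp_frequency must be an integer code in 0..4")
    out = np.isin(c, [3, 4])
    return out if out.ndim else bool(out)


def bmi_category(bmi):
    """WHO BMI category: <18.5 underweight, 18.5-25 healthy, 25-30
    overweight, >=30 obese.  Returns 0/1/2/3."""
    b = np.asarray(bmi, dtype=float)
    _check_range(b, 10.0, 80.0, "BMI", lo_open=True, hi_open=True)
    out = np.where(b < 18.5, 0, np.where(b < 25.0, 1, np.where(b < 30.0, 2, 3)))
    return out if out.ndim else int(out)


# Default STarT Back risk mapping: overall score <=3 -> low; otherwise the
# psychosocial subscale (items 5-9) decides: <=3 -> medium, >=4 -> high.
DEFAULT_SBT_CUTOFFS = {"total_low_max": 3, "subscore_high_min": 4}

# Default short-form Orebro cutoffs: <40 low, 40-49 medium, >=50 high.
DEFAULT_OREBRO_CUTOFFS = {"medium_min": 40.0, "high_min": 50.0}


def sbt_risk_level(total_score, psychosocial_subscore, cutoffs=None):
    """STarT Back Tool risk level from total score and psychosocial subscale.

    Parameters
    ----------
    total_score : int in 0..9
    psychosocial_subscore : int in 0..5, at most ``total_score``
    cutoffs : optional override of :data:`DEFAULT_SBT_CUTOFFS`

    Returns 0 (low), 1 (medium), or 2 (high).
    """
    c = dict(DEFAULT_SBT_CUTOFFS, **(cutoffs or {}))
    t = np.asarray(total_score)
    s = np.asarray(psychosocial_subscore)
    if not np.all(np.isin(t, np.arange(10))):
        raise ValueError("SBT total score must be in 0..9")
    if not np.all(np.isin(s, np.arange(6))):
        raise ValueError("SBT psychosocial subscore must be in 0..5")
    if np.any(s > t):
        raise ValueError("SBT psychosocial subscore cannot exceed the total score")
    out = np.where(
        t <= c["total_low_max"], 0, np.where(s >= c["subscore_high_min"], 2, 1)
    )
    return out if out.ndim else int(out)


def orebro_risk_level(score, cutoffs=None):
    """Short-form Orebro risk level from the total score (1..100)."""
    c = dict(DEFAULT_OREBRO_CUTOFFS, **(cutoffs or {}))
    s = np.asarray(score, dtype=float)
    _check_range(s, 1.0, 100.0, "Orebro score")
    out = np.where(s < c["medium_min"], 0, np.where(s < c["high_min"], 1, 2))
    return out if out.ndim else int(out)


def robust_scale(matrix, column_names=None, instrument="SBT") -> FeatureMatrix:
    """Scale each column to (x - median) / IQR.

    The IQR is Q3 - Q1 with linear-interpolation quantiles.  Columns with
    zero IQR are centred only (divisor 1) and flagged.  Accepts an array
    or DataFrame; at least two rows are required.
    """
    if isinstance(matrix, pd.DataFrame):
        column_names = list(matrix.columns)
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        if values.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if column_names is None:
            column_names = [f"x{j}" for j in range(values.shape[1])]
    if values.shape[0] < 2:
        raise ValueError("robust scaling needs at least 2 rows")
    if np.isnan(values).any():
        raise ValueError("feature matrix contains missing values; "
                         "rows with missing inputs must be excluded upstream")

    q1, median, q3 = np.percentile(values, [25, 50, 75], axis=0)
    iqr = q3 - q1
    zero = iqr <= 0
    divisor = np.where(zero, 1.0, iqr)
    scaled = (values - median) / divisor
    params = {name: (float(m), float(i))
              for name, m, i in zip(column_names, median, iqr)}
    return FeatureMatrix(
        values=scaled,
        column_names=list(column_names),
        scaling_params=params,
        instrument=instrument,
        zero_iqr_columns=[n for n, z in zip(column_names, zero) if z],
    )


def assemble_features(
    cohort: pd.DataFrame,
    instrument: str = "SBT",
    include_risk_score: bool = True,
    risk_score_column: str = "instrument_total",
    scale: bool = True,
):
    """Build the clustering feature matrix from a cohort table.

    Columns, in fixed order: Pfirrmann grades (ordinal 2-5) and
    facet-tropism angles (degrees) at L3/4, L4/5, L5/S1; smoking (ordinal
    0-2); BMI (raw kg/m^2); sex (0/1); and the psychosocial instrument
    score (the numerical score by default; set ``risk_score_column`` to
    ``"risk_level"`` for the coarse 0-2 level, or
    ``include_risk_score=False`` to cluster on non-psychosocial features
    only).  Outcome columns are never included.

    Returns a :class:`FeatureMatrix` (robust-scaled unless ``scale=False``,
    in which case a raw DataFrame is returned).
    """
    columns = FEATURE_COLUMNS[:-1]
    missing = [c for c in columns if c not in cohort.columns]
    if include_risk_score and risk_score_column not in cohort.columns:
        missing.append(risk_score_column)
    if missing:
        raise ValueError(f"cohort is missing required column(s): {', '.join(missing)}")

    data = cohort[columns].astype(float).copy()
    names = list(columns)
    if include_risk_score:
        data["risk_score"] = cohort[risk_score_column].astype(float)
        names.append("risk_score")
    if data.isna().any().any():
        bad = list(data.columns[data.isna().any()])
        raise ValueError(f"missing values in column(s): {', '.join(bad)}")
    if not scale:
        return data
    fm = robust_scale(data[names], instrument=instrument)
    return fm
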