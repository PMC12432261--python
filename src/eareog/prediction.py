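"""Linear gaze-angle prediction from saccade voltage deflections.

An ordinary-least-squares model maps deflection features (µV) to the signed
change in horizontal gaze angle (degrees).  Three feature sets are
supported: the single best horizontal montage, all configured montages, and
the gold-standard periorbital channel.  Evaluation reports mean absolute
errors grouped by direction × amplitude (plus per-direction and overall
totals) under leave-one-participant-out cross-validation by default, and
method agreement via Bland–Altman statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

__all__ = [
    "AngleModel",
    "AgreementStats",
    "fit_angle_model",
    "predict_angle",
    "evaluate_mae",
    "bland_altman",
    "FEATURE_SETS",
]

FEATURE_SETS = ("best_pair", "all_pairs", "gold_standard")


@dataclass
class AngleModel:
    """Affine map from deflection features (µV) to angle change (deg)."""

    feature_labels: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_labels):
            raise ValueError("coefficient count must equal feature count")


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman agreement summary (convention: method A − method B)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    points: tuple = ()  # (mean, diff) pairs for plotting

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_diff + 1e-12 and self.mean_diff - 1e-12 <= self.loa_high):
            raise ValueError("limits of agreement must bracket the mean difference")


def _design(table: pd.DataFrame, feature_labels) -> np.ndarray:
    missing = [f for f in feature_labels if f not in table.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    X = table[list(feature_labels)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN; drop invalid epochs first")
    return X


def fit_angle_model(
    table: pd.DataFrame,
    feature_labels,
    target_col: str = "angle_change_deg",
) -> AngleModel:
    """OLS fit of signed angle change on deflection features.

    ``table`` holds one row per valid saccade with one column per feature.
    Raises on a rank-deficient design, naming the collinear features.
    """
    feature_labels = tuple(feature_labels)
    X = _design(table, feature_labels)
    y = table[target_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 distinct target values")
    aug = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(aug) < aug.shape[1]:
        raise ValueError(f"rank-deficient design; collinear features among {feature_labels}")
    reg = LinearRegression().fit(X, y)
    return AngleModel(
        feature_labels=feature_labels,
        coefficients=reg.coef_,
        intercept=float(reg.intercept_),
        training_meta={"n": int(len(y))},
    )


def predict_angle(model: AngleModel, features) -> np.ndarray | float:
    """Evaluate the affine model on a feature mapping, DataFrame or array."""
    if isinstance(features, pd.DataFrame):
        X = _design(features, model.feature_labels)
    elif isinstance(features, dict):
        missing = [f for f in model.feature_labels if f not in features]
        if missing:
            raise KeyError(f"missing features: {missing}")
        x = np.asarray([features[f] for f in model.feature_labels], dtype=float)
        return float(x @ model.coefficients + model.intercept)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != len(model.feature_labels):
            raise ValueError("feature count mismatch")
    return X @ model.coefficients + model.intercept


def _predictions(table: pd.DataFrame, feature_labels, cv: str, target_col: str) -> np.ndarray:
    """Model predictions per row, in-sample or leave-one-participant-out."""
    if cv == "insample":
        model = fit_angle_model(table, feature_labels, target_col)
        return np.asarray(predict_angle(model, table))
    if cv != "loo":
        raise ValueError("cv must be 'loo' or 'insample'")
    pred = np.full(len(table), np.nan)
    participants = table["participant"].to_numpy()
    for pid in np.unique(participants):
        held = participants == pid
        if held.all():
            raise ValueError("leave-one-participant-out needs >=2 participants")
        model = fit_angle_model(table[~held], feature_labels, target_col)
        pred[held] = np.asarray(predict_angle(model, table[held]))
    return pred


def evaluate_mae(
    table: pd.DataFrame,
    feature_labels,
    cv: str = "loo",
    target_col: str = "angle_change_deg",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean absolute prediction error grouped by direction × amplitude.

    Returns ``(report, per_saccade)``.  The report has one row per
    direction × amplitude cell plus per-direction and overall totals with
    columns mae_deg, sd_deg, n.  Empty cells simply do not appear.
    """
    if table.empty:
        raise ValueError("empty evaluation table")
    pred = _predictions(table, tuple(feature_labels), cv, target_col)
    per = table[["participant", "direction", "amplitude_deg"]].copy()
    per["truth_deg"] = table[target_col].to_numpy()
    per["predicted_deg"] = pred
    per["abs_error_deg"] = np.abs(per["predicted_deg"] - per["truth_deg"])

    def _cell(name_direction, name_amplitude, err):
        return {
            "direction": name_direction,
            "amplitude_deg": name_amplitude,
            "mae_deg": float(err.mean()),
            "sd_deg": float(err.std(ddof=1)) if len(err) > 1 else 0.0,
            "n": int(len(err)),
        }

    rows = []
    for (direction, amp), grp in per.groupby(["direction", "amplitude_deg"], sort=True):
        rows.append(_cell(direction, amp, grp["abs_error_deg"]))
    for direction, grp in per.groupby("direction", sort=True):
        rows.append(_cell(direction, "total", grp["abs_error_deg"]))
    rows.append(_cell("all", "total", per["abs_error_deg"]))
    return pd.DataFrame(rows), per


def bland_altman(a, b) -> AgreementStats:
    """Bland–Altman agreement between paired measurements ``a`` and ``b``.

    diffs = a − b; limits of agreement are mean ± 1.96 · sample SD (n−1
    denominator).  Per-point (mean, diff) pairs are kept for plotting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if len(a) < 2:
        raise ValueError("need at least 2 paired measurements")
    diffs = a - b
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    points = tuple(zip(((a + b) / 2.0).tolist(), diffs.tolist()))
    return AgreementStats(
        mean_diff=mean_diff,
        sd_diff=sd,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        points=points,
    )
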