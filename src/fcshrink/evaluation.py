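"""Scoring of replicate-2 predictions: per-subject MSE and summary tables.

Each predictor is scored against the observed session-2 map by the mean
squared error over ROI voxels,

    MSE_i = (1/|S*|) Σ_{v∈S*} (V̂_i2(v) − V_i2(v))²,

where S* drops voxels NaN in either the prediction or the observation.
MSE can be computed on the Fisher-Z scale (the headline scale) or on the
back-transformed correlation scale.  Improvement over the raw predictor is
summarised as a percent reduction, 100·(MSE_raw − MSE_other)/MSE_raw.

The summary block reports per-method mean, median, min, max and Tukey
outliers.  Quartiles follow the median-exclusive convention (quartile =
median of the lower/upper half, excluding the overall median for odd n),
so the boxplot outlier count is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .shrinkage import EstimatorResult

__all__ = [
    "mse_per_subject",
    "percent_reduction",
    "evaluation_table",
    "summarize",
    "tukey_quartiles",
    "tukey_outliers",
    "EvaluationReport",
]

METHODS = ("raw", "mean", "shrinkage")


def mse_per_subject(
    pred: EstimatorResult, observed_fisher: np.ndarray, scale: str = "fisher"
) -> np.ndarray:
    """Per-subject MSE of a prediction against the observed session-2 maps.

    ``observed_fisher`` is the (I, V) observed Fisher-Z session-2 panel;
    with ``scale="correlation"`` both sides are tanh-transformed before
    squaring.  Voxels NaN in either side are dropped per subject.
    """
    if scale not in ("fisher", "correlation"):
        raise ValueError(f"scale must be 'fisher' or 'correlation', got {scale!r}")
    pred_maps = pred.fisher if scale == "fisher" else pred.correlation
    obs = observed_fisher if scale == "fisher" else np.tanh(observed_fisher)
    if pred_maps.shape != obs.shape:
        raise ValueError(
            f"prediction shape {pred_maps.shape} != observation shape {obs.shape}"
        )
    ok = np.isfinite(pred_maps) & np.isfinite(obs)
    n = ok.sum(axis=1)
    if np.any(n == 0):
        raise ValueError("a subject has no voxel that is non-NaN in both maps")
    sq = np.where(ok, (pred_maps - obs) ** 2, 0.0)
    return sq.sum(axis=1) / n


def percent_reduction(mse_raw: float, mse_other: float) -> float:
    """MSE improvement over the raw predictor, in percent; NaN when raw MSE is 0."""
    if mse_raw == 0:
        return float("nan")
    return 100.0 * (mse_raw - mse_other) / mse_raw


def _round_half_up(x: float, places: int = 2) -> float:
    if not np.isfinite(x):
        return float("nan")
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def evaluation_table(
    results: dict[str, EstimatorResult],
    observed_fisher: np.ndarray,
    subjects: list[str],
    scale: str = "fisher",
) -> pd.DataFrame:
    """Per-subject MSE table for the raw/mean/shrinkage predictors.

    Columns: subject_id, mse_raw, mse_mean, red_mean_pct, mse_shrinkage,
    red_shrink_pct — unrounded internals, plus ``*_display`` columns rounded
    half-up to 2 decimals for reporting.
    """
    missing = [m for m in METHODS if m not in results]
    if missing:
        raise ValueError(f"missing estimator results: {missing}")
    mse = {m: mse_per_subject(results[m], observed_fisher, scale) for m in METHODS}
    red_mean = [percent_reduction(r, o) for r, o in zip(mse["raw"], mse["mean"])]
    red_shrink = [percent_reduction(r, o) for r, o in zip(mse["raw"], mse["shrinkage"])]
    df = pd.DataFrame(
        {
            "subject_id": subjects,
            "mse_raw": mse["raw"],
            "mse_mean": mse["mean"],
            "red_mean_pct": red_mean,
            "mse_shrinkage": mse["shrinkage"],
            "red_shrink_pct": red_shrink,
        }
    )
    for col in ("red_mean_pct", "red_shrink_pct"):
        df[col + "_display"] = df[col].map(_round_half_up)
    return df


def tukey_quartiles(values: np.ndarray) -> tuple[float, float]:
    """Q1/Q3 as medians of the lower/upper halves, excluding the overall
    median for odd n (the convention behind classic boxplot fences)."""
    xs = np.sort(np.asarray(values, dtype=np.float64))
    n = xs.size
    if n < 2:
        raise ValueError("quartiles need at least 2 values")
    half = n // 2
    return float(np.median(xs[:half])), float(np.median(xs[n - half:]))


def tukey_outliers(values: np.ndarray) -> np.ndarray:
    """Indices of values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]."""
    x = np.asarray(values, dtype=np.float64)
    q1, q3 = tukey_quartiles(x)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return np.nonzero((x < lo) | (x > hi))[0]


@dataclass
class EvaluationReport:
    """Per-subject table plus the per-method summary block."""

    table: pd.DataFrame
    summary: pd.DataFrame
    scale: str


def summarize(table: pd.DataFrame, scale: str = "fisher") -> EvaluationReport:
    """Summary block: per-method mean/median/min/max MSE and Tukey outliers."""
    rows = []
    for method in METHODS:
        col = table[f"mse_{method}"].to_numpy()
        out_idx = tukey_outliers(col) if col.size >= 2 else np.array([], dtype=int)
        rows.append(
            {
                "method": method,
                "mean_mse": col.mean(),
                "median_mse": float(np.median(col)),
                "min_mse": col.min(),
                "max_mse": col.max(),
                "n_outliers": len(out_idx),
                "outlier_subjects": ",".join(table["subject_id"].iloc[out_idx]),
                "mean_red_pct": percent_reduction(
                    table["mse_raw"].mean(), table[f"mse_{method}"].mean()
                ),
            }
        )
    return EvaluationReport(table=table, summary=pd.DataFrame(rows), scale=scale)
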