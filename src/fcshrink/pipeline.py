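"""Stage orchestration: simulate → fit → evaluate, with reproducible runs.

Each stage writes into its own output directory:

``simulate``
    per-scan 4-D NIfTIs + TSV manifest + 3-D mask from a seeded synthetic
    config, plus ground-truth tables (true X, true λ) and a copy of the
    resolved config.
``fit``
    loads a manifest + mask, computes seed correlation and Fisher maps,
    variance components, λ/ICC, and the raw/mean/shrinkage predictions of
    every subject's session-2 map; emits per-voxel TSVs, per-subject map
    TSVs and NIfTI volumes.
``evaluate``
    consumes exactly the files ``fit`` emits and writes ``mse_table.tsv``
    (per-subject MSEs with an Average row) and ``summary.tsv``.

All floating TSV output is written at full precision; rounded values live
only in ``*_display`` columns.  Given the same config and master seed, a
run is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, evaluation, imaging, shrinkage, synthetic
from .panels import FisherPanel

__all__ = ["simulate", "fit", "evaluate", "run_all"]

logger = logging.getLogger(__name__)

_FIT_FILES = {
    "observed": "observed_session2_fisher.tsv",
    "voxelwise": "voxelwise.tsv",
}


class StageError(RuntimeError):
    """An error attributed to a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write_wide(path: Path, values: np.ndarray, subjects: list[str]) -> None:
    df = pd.DataFrame(values, columns=[f"v{k}" for k in range(values.shape[1])])
    df.insert(0, "subject_id", subjects)
    df.to_csv(path, sep="\t", index=False)


def _read_wide(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return df.drop(columns="subject_id").to_numpy(dtype=np.float64), list(df["subject_id"])


def simulate(config: synthetic.SyntheticConfig, out_dir: str | Path) -> Path:
    """Generate a seeded time-series study and write it as NIfTI fixtures."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel, truth = synthetic.generate_timeseries_panel(config)
    mask = imaging.grid_for_voxels(config.n_voxels)
    manifest, mask_path = imaging.write_panel_niftis(panel, mask, out_dir)
    _write_wide(out_dir / "truth_x.tsv", truth.x, panel.subjects)
    pd.DataFrame({"voxel": np.arange(config.n_voxels), "lambda_true": truth.lambda_true}).to_csv(
        out_dir / "truth_lambda.tsv", sep="\t", index=False
    )
    resolved = asdict(config)
    resolved["mu_x"] = (
        float(config.mu_x) if np.isscalar(config.mu_x) else [float(m) for m in config.mu_x_per_voxel]
    )
    (out_dir / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    logger.info(
        "simulate: %d subjects x %d sessions x %d voxels x %d time points -> %s",
        config.n_subjects, config.n_sessions, config.n_voxels, config.n_timepoints, out_dir,
    )
    return out_dir


def fit(
    manifest_path: str | Path,
    mask_path: str | Path,
    out_dir: str | Path,
    lambda_mode: str = "estimate",
    fixed_lambda: float = shrinkage.DEFAULT_FIXED_LAMBDA,
    write_niftis: bool = False,
) -> Path:
    """Estimate λ and the three session-2 predictions from a two-session study."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        mask = imaging.load_mask(mask_path)
        panel = imaging.load_panel(manifest_path, mask)
    except (ValueError, OSError) as exc:
        raise StageError("fit/load", str(exc)) from exc
    if set(panel.sessions) != {"1", "2"}:
        raise StageError(
            "fit/load", f"two-replicate analysis needs sessions '1' and '2', got {panel.sessions}"
        )

    fisher = connectivity.fisher_panel_from_timeseries(panel)
    n_nan = int(np.isnan(fisher.values).sum())
    logger.info(
        "fit: %d subjects, %d sessions, %d voxels, %d NaN map entries",
        fisher.n_subjects, fisher.n_sessions, fisher.n_voxels, n_nan,
    )

    try:
        comp = shrinkage.variance_components(fisher)
        if lambda_mode == "estimate":
            lam = shrinkage.lambda_map(comp, fallback=fixed_lambda)
        elif lambda_mode == "fixed":
            lam = shrinkage.lambda_map(fixed_lambda=fixed_lambda, n_voxels=fisher.n_voxels)
        else:
            raise ValueError(f"lambda_mode must be 'estimate' or 'fixed', got {lambda_mode!r}")
        results = {
            "raw": shrinkage.raw_estimator(fisher),
            "mean": shrinkage.mean_estimator(fisher),
            "shrinkage": shrinkage.shrink(fisher, lam),
        }
    except ValueError as exc:
        raise StageError("fit/estimate", str(exc)) from exc

    vox = pd.DataFrame(
        {
            "voxel": np.arange(fisher.n_voxels),
            "x": mask.indices[:, 0],
            "y": mask.indices[:, 1],
            "z": mask.indices[:, 2],
            "lambda": lam.values,
            "icc": lam.icc,
            "var_u": comp.var_u,
            "var_v": comp.var_v,
            "var_x": comp.var_x,
            "d_bar": comp.d_bar,
            "var_x_clamped": comp.clamped.astype(int),
            "effective_i": comp.effective_i,
        }
    )
    vox.to_csv(out_dir / _FIT_FILES["voxelwise"], sep="\t", index=False)
    _write_wide(out_dir / _FIT_FILES["observed"], fisher.session("2"), fisher.subjects)
    for method, res in results.items():
        _write_wide(out_dir / f"predicted_{method}_fisher.tsv", res.fisher, res.subjects)
        _write_wide(out_dir / f"predicted_{method}_correlation.tsv", res.correlation, res.subjects)

    if write_niftis:
        ref = mask_path
        maps_dir = out_dir / "maps"
        imaging.write_map(lam.values, mask, ref, maps_dir / "lambda.nii.gz")
        imaging.write_map(lam.icc, mask, ref, maps_dir / "icc.nii.gz")
        for method, res in results.items():
            for i, sub in enumerate(res.subjects):
                imaging.write_map(
                    res.correlation[i], mask, ref, maps_dir / f"{method}_{sub}.nii.gz"
                )
    (out_dir / "fit_config.yaml").write_text(
        yaml.safe_dump(
            {
                "manifest": str(manifest_path),
                "mask": str(mask_path),
                "lambda_mode": lambda_mode,
                "fixed_lambda": float(fixed_lambda),
            }
        )
    )
    return out_dir


def evaluate(fit_dir: str | Path, out_dir: str | Path, scale: str = "fisher") -> Path:
    """Score the fitted predictions against the observed session-2 maps."""
    fit_dir, out_dir = Path(fit_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        observed, subjects = _read_wide(fit_dir / _FIT_FILES["observed"])
        results = {}
        for method in evaluation.METHODS:
            pred, pred_subjects = _read_wide(fit_dir / f"predicted_{method}_fisher.tsv")
            if pred_subjects != subjects:
                raise ValueError(f"subject order mismatch in predicted_{method}_fisher.tsv")
            results[method] = shrinkage.EstimatorResult(
                method=method, fisher=pred, subjects=pred_subjects
            )
    except (OSError, ValueError) as exc:
        raise StageError("evaluate/load", str(exc)) from exc

    table = evaluation.evaluation_table(results, observed, subjects, scale=scale)
    report = evaluation.summarize(table, scale=scale)
    avg = {
        "subject_id": "Average",
        "mse_raw": table["mse_raw"].mean(),
        "mse_mean": table["mse_mean"].mean(),
        "red_mean_pct": evaluation.percent_reduction(
            table["mse_raw"].mean(), table["mse_mean"].mean()
        ),
        "mse_shrinkage": table["mse_shrinkage"].mean(),
        "red_shrink_pct": evaluation.percent_reduction(
            table["mse_raw"].mean(), table["mse_shrinkage"].mean()
        ),
    }
    full = pd.concat([table, pd.DataFrame([avg])], ignore_index=True)
    for col in ("red_mean_pct", "red_shrink_pct"):
        full[col + "_display"] = full[col].map(evaluation._round_half_up)
    full.to_csv(out_dir / "mse_table.tsv", sep="\t", index=False)
    report.summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    logger.info("evaluate: %d subjects scored on the %s scale -> %s", len(subjects), scale, out_dir)
    return out_dir


def run_all(
    config: synthetic.SyntheticConfig,
    out_dir: str | Path,
    lambda_mode: str = "estimate",
    fixed_lambda: float = shrinkage.DEFAULT_FIXED_LAMBDA,
    scale: str = "fisher",
) -> Path:
    """simulate → fit → evaluate in one seeded, reproducible run."""
    out_dir = Path(out_dir)
    sim_dir = simulate(config, out_dir / "sim")
    fit_dir = fit(
        sim_dir / "manifest.tsv",
        sim_dir / "mask.nii.gz",
        out_dir / "fit",
        lambda_mode=lambda_mode,
        fixed_lambda=fixed_lambda,
    )
    evaluate(fit_dir, out_dir / "eval", scale=scale)
    return out_dir
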