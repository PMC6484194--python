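"""Seed time courses, seed-based correlation maps, and the Fisher-Z pair.

The seed signal of a scan is the unweighted mean over all ROI voxels of
the voxel time series (every voxel contributes, including the voxel being
correlated — the self-correlation inflation this induces is part of the
definition).  The connectivity map is the per-voxel Pearson correlation
between the voxel series and the seed, and Fisher's variance-stabilising
transform V = arctanh(W) moves correlations onto the scale where the
measurement-error model is additive.
"""

from __future__ import annotations

import logging

import numpy as np

from .panels import ConnectivityPanel, FisherPanel, TimeSeriesPanel

__all__ = [
    "seed_timecourse",
    "correlation_map",
    "correlation_panel",
    "fisher_z",
    "inverse_fisher_z",
    "fisher_panel_from_timeseries",
    "FISHER_CLIP",
]

logger = logging.getLogger(__name__)

#: correlations are clipped to |W| <= 1 - FISHER_CLIP before arctanh so the
#: Fisher value stays finite; genuine correlations are perturbed by < 1e-7.
FISHER_CLIP = 1e-7


def seed_timecourse(panel: TimeSeriesPanel, i: int, j: int) -> np.ndarray:
    """Mean over all ROI voxels at each time point, for scan (subject i, session j)."""
    return panel.values[i, j].mean(axis=0)


def _pearson_against_seed(y: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """Correlate each row of ``y`` (V, T) with ``seed`` (T,); zero-variance rows -> NaN."""
    yc = y - y.mean(axis=1, keepdims=True)
    sc = seed - seed.mean()
    num = yc @ sc
    den2 = (yc * yc).sum(axis=1) * (sc * sc).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den2 > 0.0, num / np.sqrt(den2), np.nan)
    # guard against round-off pushing |W| infinitesimally past 1
    return np.clip(w, -1.0, 1.0)


def correlation_map(panel: TimeSeriesPanel, i: int, j: int) -> np.ndarray:
    """Seed-based correlation map for one scan: one Pearson r per ROI voxel.

    Degenerate voxels (zero temporal variance, or a zero-variance seed)
    yield NaN and a logged warning; they are excluded from all downstream
    voxelwise statistics.
    """
    if panel.n_timepoints < 3:
        raise ValueError("correlation map requires at least 3 time points")
    seed = seed_timecourse(panel, i, j)
    w = _pearson_against_seed(panel.values[i, j], seed)
    n_bad = int(np.isnan(w).sum())
    if n_bad:
        logger.warning(
            "scan (subject=%s, session=%s): %d degenerate voxel(s) set to NaN",
            panel.subjects[i], panel.sessions[j], n_bad,
        )
    return w


def correlation_panel(panel: TimeSeriesPanel) -> ConnectivityPanel:
    """Correlation maps for every (subject, session) scan, as a (I, J, V) panel."""
    out = np.empty((panel.n_subjects, panel.n_sessions, panel.n_voxels))
    for i in range(panel.n_subjects):
        for j in range(panel.n_sessions):
            out[i, j] = correlation_map(panel, i, j)
    return ConnectivityPanel(out, list(panel.subjects), list(panel.sessions))


def fisher_z(w: np.ndarray | float) -> np.ndarray | float:
    """Fisher-Z transform V = ½·log((1+W)/(1−W)) = arctanh(W).

    Input is clipped to |W| ≤ 1 − 1e−7 first so perfect correlations map to
    a large finite value instead of ±inf; NaN propagates.
    """
    w = np.clip(np.asarray(w, dtype=np.float64), -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP)
    return np.arctanh(w)


def inverse_fisher_z(v: np.ndarray | float) -> np.ndarray | float:
    """Inverse Fisher-Z transform W = tanh(V); output in (−1, 1), NaN propagates."""
    return np.tanh(np.asarray(v, dtype=np.float64))


def fisher_panel_from_timeseries(panel: TimeSeriesPanel) -> FisherPanel:
    """Convenience: correlation panel followed by the Fisher-Z transform."""
    corr = correlation_panel(panel)
    return FisherPanel(fisher_z(corr.values), list(corr.subjects), list(corr.sessions))
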