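"""Synthetic replicated connectivity data with known ground truth.

Two generators emulate a two-session test–retest resting-state study under
the classical measurement-error model on the Fisher-Z scale,

    V_ij(v) = X_i(v) + U_ij(v),
    X_i(v) ~ N(mu_x(v), sigma2_x),   U_ij(v) ~ N(0, sigma2_u),

all mutually independent:

* :func:`generate_fisher_panel` samples the model directly, giving exact
  control of both variance components;
* :func:`generate_timeseries_panel` synthesises voxel time series whose
  finite-length correlation estimates carry Fisher sampling error on top
  of a session-level effect, so the full time-series → correlation →
  shrinkage pipeline can be exercised end to end.  Here ``sigma2_u`` plays
  the role of the session-effect variance; the effective measurement-error
  variance on the Fisher scale is approximately sigma2_u + 1/(T−3).

Both generators are bit-reproducible: one master seed drives a dedicated
substream per (subject, session), so output does not depend on generation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .panels import FisherPanel, TimeSeriesPanel
from .shrinkage import LambdaMap

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_fisher_panel",
    "generate_timeseries_panel",
    "true_lambda",
    "load_config",
]

#: ground-truth correlations are clipped to this bound before signal
#: synthesis to avoid degenerate (perfectly collinear) time series
RHO_BOUND = 0.999


@dataclass(frozen=True)
class SyntheticConfig:
    """Study dimensions and generative parameters.

    ``mu_x`` is the per-voxel mean true Fisher-Z connectivity (a scalar is
    broadcast over voxels).  ``sigma2_x`` is the between-subject variance of
    the true connectivity, ``sigma2_u`` the measurement-error variance (for
    the time-series generator: the session-effect variance, to which the
    finite-length sampling variance 1/(T−3) adds).  Units of both are
    squared Fisher-Z.  Defaults mirror a short two-session paediatric
    resting-state protocol: 21 subjects, 2 sessions, 74 time points.
    """

    n_subjects: int = 21
    n_sessions: int = 2
    n_voxels: int = 200
    n_timepoints: int = 74
    mu_x: float | np.ndarray = 0.3
    sigma2_x: float = 0.04
    sigma2_u: float = 0.01
    ar1: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_sessions < 2:
            raise ValueError("n_sessions must be >= 2")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.n_timepoints < 5:
            raise ValueError("n_timepoints must be >= 5 (Fisher sampling variance degenerate)")
        if self.sigma2_x < 0 or self.sigma2_u < 0:
            raise ValueError("variances must be non-negative")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 must lie in (-1, 1)")
        mu = np.atleast_1d(np.asarray(self.mu_x, dtype=np.float64))
        if mu.size not in (1, self.n_voxels):
            raise ValueError(f"mu_x must be scalar or length n_voxels={self.n_voxels}")

    @property
    def mu_x_per_voxel(self) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.mu_x, dtype=np.float64)), (self.n_voxels,)
        ).copy()


@dataclass
class GroundTruth:
    """True latent quantities behind a synthetic panel.

    ``x`` is the (I, V) matrix of true subject-level Fisher-Z values;
    ``lambda_true`` the model-implied shrinkage weight per voxel;
    ``rho`` the (I, J, V) session-level true correlations (time-series
    mode only, else None).
    """

    x: np.ndarray
    lambda_true: np.ndarray
    rho: np.ndarray | None = None


def _lambda_from_variances(sigma2_x: float, sigma2_u_eff: float) -> float:
    # weight on the group mean; both components zero => 1 by convention
    # (the raw map then carries no information beyond the mean)
    total = sigma2_x + sigma2_u_eff
    if total == 0.0:
        return 1.0
    return float(np.clip(sigma2_u_eff / total, 0.0, 1.0))


def _streams(config: SyntheticConfig) -> tuple[np.random.Generator, list[np.random.Generator]]:
    root = np.random.SeedSequence(config.rng_seed)
    subject_seq, session_seq = root.spawn(2)
    session_children = session_seq.spawn(config.n_subjects * config.n_sessions)
    return (
        np.random.default_rng(subject_seq),
        [np.random.default_rng(s) for s in session_children],
    )


def generate_fisher_panel(config: SyntheticConfig) -> tuple[FisherPanel, GroundTruth]:
    """Sample the measurement-error model directly on the Fisher-Z scale."""
    ii, jj, vv = config.n_subjects, config.n_sessions, config.n_voxels
    subject_rng, session_rngs = _streams(config)
    x = config.mu_x_per_voxel[None, :] + np.sqrt(config.sigma2_x) * subject_rng.standard_normal(
        (ii, vv)
    )
    values = np.empty((ii, jj, vv))
    for i in range(ii):
        for j in range(jj):
            rng = session_rngs[i * jj + j]
            values[i, j] = x[i] + np.sqrt(config.sigma2_u) * rng.standard_normal(vv)
    lam = np.full(vv, _lambda_from_variances(config.sigma2_x, config.sigma2_u))
    return FisherPanel(values), GroundTruth(x=x, lambda_true=lam)


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], phi: float) -> np.ndarray:
    """Unit-variance noise along the last axis; white when phi == 0."""
    eps = rng.standard_normal(shape)
    if phi == 0.0:
        return eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0]
    innov = np.sqrt(1.0 - phi * phi)
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + innov * eps[..., t]
    return out


def generate_timeseries_panel(config: SyntheticConfig) -> tuple[TimeSeriesPanel, GroundTruth]:
    """Synthesise voxel time series whose seed correlations realise the model.

    For each scan a standard-normal seed driver s(t) is drawn and each
    voxel's signal is ``rho·s(t) + sqrt(1−rho²)·ε(v,t)`` with white-noise ε,
    where ``rho(i,j,v) = tanh(X_i(v) + B_ij(v))`` and the session effect
    B_ij(v) ~ N(0, sigma2_u) is added on the Fisher scale, keeping the
    measurement-error model additive on the analysis scale.

    Note the generated signals correlate with the *driver*; the analysis
    seed (ROI-mean signal) is close to the driver but not identical, so the
    realised correlations carry the usual seed-contamination of ROI
    averaging in addition to Fisher sampling noise.
    """
    ii, jj, vv, tt = (
        config.n_subjects,
        config.n_sessions,
        config.n_voxels,
        config.n_timepoints,
    )
    subject_rng, session_rngs = _streams(config)
    x = config.mu_x_per_voxel[None, :] + np.sqrt(config.sigma2_x) * subject_rng.standard_normal(
        (ii, vv)
    )
    values = np.empty((ii, jj, vv, tt))
    rho = np.empty((ii, jj, vv))
    for i in range(ii):
        for j in range(jj):
            rng = session_rngs[i * jj + j]
            b = np.sqrt(config.sigma2_u) * rng.standard_normal(vv)
            r = np.clip(np.tanh(x[i] + b), -RHO_BOUND, RHO_BOUND)
            rho[i, j] = r
            s = _ar1_noise(rng, (tt,), config.ar1)
            eps = _ar1_noise(rng, (vv, tt), config.ar1)
            values[i, j] = r[:, None] * s[None, :] + np.sqrt(1.0 - r * r)[:, None] * eps
    sigma2_u_eff = config.sigma2_u + 1.0 / (tt - 3)
    lam = np.full(vv, _lambda_from_variances(config.sigma2_x, sigma2_u_eff))
    return (
        TimeSeriesPanel(
            values,
            [f"sub-{i + 1:02d}" for i in range(ii)],
            [str(j + 1) for j in range(jj)],
        ),
        GroundTruth(x=x, lambda_true=lam, rho=rho),
    )


def true_lambda(truth: GroundTruth, config: SyntheticConfig) -> LambdaMap:
    """The model-implied shrinkage weight map, for parameter-recovery tests."""
    return LambdaMap(values=truth.lambda_true.copy(), source="true")


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a flat key:value config file (keys = SyntheticConfig field names)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain flat key: value pairs")
    known = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SyntheticConfig(**raw)
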