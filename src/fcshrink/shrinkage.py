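"""Variance components, shrinkage weights, and the three replicate-2 predictors.

Given Fisher-Z connectivity maps from two sessions, the second-session map
of each subject is predicted three ways:

* **raw** — the subject's own session-1 map, V̂_i2(v) = V_i1(v);
* **mean** — the group average of session-1 maps, identical for every subject;
* **shrinkage** — the convex combination
  V̂_i2(v) = λ(v)·V̄_1(v) + (1−λ(v))·V_i1(v),

which is the best linear unbiased predictor of the true subject value under
the measurement-error model V_ij = X_i + U_ij when

    λ(v) = Var{U}(v) / (Var{X}(v) + Var{U}(v)) = 1 − ICC(v).

λ = 0 means the raw map is perfectly reliable (no shrinkage); λ = 1 means it
is pure noise and the predictor collapses to the group mean.  The intraclass
correlation coefficient ICC = Var{X}/(Var{X}+Var{U}) is reported alongside
as 1 − λ.

Variance components are estimated voxelwise from the session difference
D_i(v) = V_i2(v) − V_i1(v):

    Var{U}(v) = ½ · (1/(I−1)) · Σ_i (D_i(v) − D̄(v))²
    Var{V}(v) = (1/J) · Σ_j (1/(I−1)) · Σ_i (V_ij(v) − V̄_j(v))²
    Var{X}(v) = max(Var{V}(v) − Var{U}(v), 0)

Var{V} is the within-session between-subject sample variance pooled over
sessions; its expectation under the model is Var{X} + Var{U}, so the
subtraction is a coherent moment estimator.  Negative Var{X} estimates — a
routine finite-sample artifact — are clamped to zero and flagged, which
pins λ at 1 for that voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panels import FisherPanel

__all__ = [
    "VarianceComponents",
    "LambdaMap",
    "EstimatorResult",
    "raw_estimator",
    "mean_estimator",
    "variance_components",
    "lambda_map",
    "shrink",
    "DEFAULT_FIXED_LAMBDA",
]

logger = logging.getLogger(__name__)

#: fallback shrinkage weight for voxels where λ cannot be estimated
#: (effective I < 2); 0.1 is a published rule-of-thumb close to the average
#: voxel reliability in scan-rescan studies
DEFAULT_FIXED_LAMBDA = 0.1


@dataclass
class VarianceComponents:
    """Per-voxel variance decomposition of the Fisher-Z panel."""

    var_u: np.ndarray  # measurement-error variance, squared Fisher-Z
    var_v: np.ndarray  # total single-measurement variance
    var_x: np.ndarray  # between-subject variance, clamped >= 0
    d_bar: np.ndarray  # mean session difference
    clamped: np.ndarray  # True where var_v - var_u was negative
    effective_i: np.ndarray  # subjects with both sessions finite, per voxel


@dataclass
class LambdaMap:
    """Voxelwise shrinkage weight λ(v) ∈ [0, 1]; the weight on the mean map."""

    values: np.ndarray
    source: str = "estimated"  # estimated | fixed | true

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("lambda values must lie in [0, 1]")

    @property
    def icc(self) -> np.ndarray:
        """Test–retest reliability ICC(v) = 1 − λ(v)."""
        return 1.0 - self.values


@dataclass
class EstimatorResult:
    """A predicted replicate-2 map per subject, on both analysis scales."""

    method: str  # raw | mean | shrinkage
    fisher: np.ndarray  # (I, V) predicted Fisher-Z maps
    correlation: np.ndarray = field(init=False)  # tanh of fisher
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fisher = np.asarray(self.fisher, dtype=np.float64)
        self.correlation = np.tanh(self.fisher)
        if not self.subjects:
            self.subjects = [f"sub-{i + 1:02d}" for i in range(self.fisher.shape[0])]


def raw_estimator(fisher: FisherPanel, session: str = "1") -> EstimatorResult:
    """Each subject's own session-1 map, used as-is to predict session 2."""
    return EstimatorResult(
        method="raw", fisher=fisher.session(session).copy(), subjects=list(fisher.subjects)
    )


def mean_estimator(fisher: FisherPanel, session: str = "1") -> EstimatorResult:
    """Group average of session-1 maps, replicated to every subject.

    NaN (degenerate) voxels are excluded from the average subject-by-subject;
    a voxel NaN in all subjects stays NaN.
    """
    s1 = fisher.session(session)
    n_eff = np.isfinite(s1).sum(axis=0)
    if np.any(n_eff < s1.shape[0]):
        logger.info(
            "mean estimator: %d voxel(s) averaged over fewer than %d subjects",
            int((n_eff < s1.shape[0]).sum()), s1.shape[0],
        )
    with np.errstate(invalid="ignore"):
        mean_map = np.where(n_eff > 0, np.nansum(s1, axis=0) / np.maximum(n_eff, 1), np.nan)
    return EstimatorResult(
        method="mean",
        fisher=np.broadcast_to(mean_map, s1.shape).copy(),
        subjects=list(fisher.subjects),
    )


def variance_components(
    fisher: FisherPanel, sessions: tuple[str, str] = ("1", "2")
) -> VarianceComponents:
    """Estimate Var{U}, Var{V}, Var{X} per voxel from a two-session panel.

    Subjects with a NaN in either session are dropped voxelwise; voxels with
    fewer than 2 complete subjects get NaN components (downstream λ falls
    back to a fixed value there).
    """
    if fisher.n_subjects < 2:
        raise ValueError("variance components require >=2 subjects")
    v1 = fisher.session(sessions[0])
    v2 = fisher.session(sessions[1])
    ok = np.isfinite(v1) & np.isfinite(v2)  # (I, V)
    n = ok.sum(axis=0).astype(np.int64)

    excluded = int((n < fisher.n_subjects).sum())
    if excluded:
        logger.warning(
            "variance components: %d voxel(s) estimated with reduced subject counts", excluded
        )

    def _masked(a: np.ndarray) -> np.ndarray:
        return np.where(ok, a, np.nan)

    v1m, v2m = _masked(v1), _masked(v2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = v2m - v1m
        d_bar = np.nansum(d, axis=0) / np.maximum(n, 1)
        ss_d = np.nansum((d - d_bar) ** 2, axis=0)
        var_u = 0.5 * ss_d / np.maximum(n - 1, 1)
        var_per_session = []
        for vm in (v1m, v2m):
            m_j = np.nansum(vm, axis=0) / np.maximum(n, 1)
            var_per_session.append(np.nansum((vm - m_j) ** 2, axis=0) / np.maximum(n - 1, 1))
        var_v = 0.5 * (var_per_session[0] + var_per_session[1])
    bad = n < 2
    for arr in (d_bar, var_u, var_v):
        arr[bad] = np.nan
    raw_x = var_v - var_u
    clamped = np.where(bad, False, raw_x < 0.0)
    var_x = np.where(bad, np.nan, np.maximum(raw_x, 0.0))
    return VarianceComponents(
        var_u=var_u, var_v=var_v, var_x=var_x, d_bar=d_bar,
        clamped=clamped, effective_i=n,
    )


def lambda_map(
    comp: VarianceComponents | None = None,
    fixed_lambda: float | None = None,
    n_voxels: int | None = None,
    fallback: float = DEFAULT_FIXED_LAMBDA,
) -> LambdaMap:
    """Shrinkage weight map: estimated from variance components or fixed.

    With ``fixed_lambda`` given, returns a constant map (``n_voxels`` or the
    component length sets its size).  Otherwise λ(v) = Var{U}/(Var{X}+Var{U}),
    with λ = 1 where both components are zero and ``fallback`` where the
    components could not be estimated.
    """
    if fixed_lambda is not None:
        if not 0.0 <= fixed_lambda <= 1.0:
            raise ValueError(f"fixed_lambda must lie in [0, 1], got {fixed_lambda}")
        size = n_voxels if n_voxels is not None else len(comp.var_u)
        return LambdaMap(values=np.full(size, float(fixed_lambda)), source="fixed")
    if comp is None:
        raise ValueError("either variance components or fixed_lambda must be given")
    total = comp.var_x + comp.var_u
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(total > 0.0, comp.var_u / total, 1.0)
    degenerate = ~np.isfinite(comp.var_u)
    if degenerate.any():
        logger.warning(
            "lambda: %d voxel(s) fall back to fixed lambda=%.3f (effective I < 2)",
            int(degenerate.sum()), fallback,
        )
        lam = np.where(degenerate, fallback, lam)
    return LambdaMap(values=np.clip(lam, 0.0, 1.0), source="estimated")


def shrink(
    fisher: FisherPanel, lam: LambdaMap, session: str = "1"
) -> EstimatorResult:
    """Shrinkage predictor: λ-weighted convex combination of mean and raw maps."""
    if lam.values.shape[0] != fisher.n_voxels:
        raise ValueError(
            f"lambda map covers {lam.values.shape[0]} voxels, panel has {fisher.n_voxels}"
        )
    raw = raw_estimator(fisher, session)
    mean = mean_estimator(fisher, session)
    pred = lam.values[None, :] * mean.fisher + (1.0 - lam.values[None, :]) * raw.fisher
    return EstimatorResult(method="shrinkage", fisher=pred, subjects=list(fisher.subjects))
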