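"""In-memory containers for subject × session connectivity data.

The analysis operates on two array shapes:

* a voxel time-series panel ``Y[i, j, v, t]`` — BOLD-like signals for
  subject *i*, scanning session *j*, ROI voxel *v*, time point *t*;
* a Fisher panel ``V[i, j, v]`` — Fisher-Z transformed seed correlations,
  the scale on which the measurement-error model is additive.

Subjects and sessions are carried as ordered label lists so that maps can
be written back to disk against the right identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeriesPanel", "FisherPanel", "ConnectivityPanel"]


def _check_labels(values: np.ndarray, subjects: list[str], sessions: list[str]) -> None:
    if values.shape[0] != len(subjects):
        raise ValueError(
            f"subject axis has length {values.shape[0]} but {len(subjects)} subject ids given"
        )
    if values.shape[1] != len(sessions):
        raise ValueError(
            f"session axis has length {values.shape[1]} but {len(sessions)} session labels given"
        )
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    if len(set(sessions)) != len(sessions):
        raise ValueError("duplicate session labels")


@dataclass
class TimeSeriesPanel:
    """Voxel time series ``Y[i, j, v, t]`` over a fixed ROI voxel enumeration."""

    values: np.ndarray  # (I, J, V, T), float64
    subjects: list[str]
    sessions: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError(f"expected 4-D array (I,J,V,T), got shape {self.values.shape}")
        _check_labels(self.values, self.subjects, self.sessions)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-series panel contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]


@dataclass
class FisherPanel:
    """Fisher-Z connectivity ``V[i, j, v]``; NaN marks degenerate voxels."""

    values: np.ndarray  # (I, J, V), float64
    subjects: list[str] = field(default_factory=list)
    sessions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3-D array (I,J,V), got shape {self.values.shape}")
        if not self.subjects:
            self.subjects = [f"sub-{i + 1:02d}" for i in range(self.values.shape[0])]
        if not self.sessions:
            self.sessions = [str(j + 1) for j in range(self.values.shape[1])]
        _check_labels(self.values, self.subjects, self.sessions)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]

    def session_index(self, label: str) -> int:
        try:
            return self.sessions.index(label)
        except ValueError:
            raise KeyError(f"session {label!r} not in panel (have {self.sessions})") from None

    def session(self, label: str) -> np.ndarray:
        """Return the (I, V) slice for one session label."""
        return self.values[:, self.session_index(label), :]


# A correlation panel shares the FisherPanel layout; values live in [-1, 1].
ConnectivityPanel = FisherPanel
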