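"""NIfTI input/output: ROI masks, subject × session scan panels, voxel maps.

Scans are listed in a TSV manifest with columns ``subject_id``, ``session``,
``path``; each path is a 4-D NIfTI on the mask's grid.  Voxel coordinates
are 0-based array indices in a fixed ascending (x, y, z) enumeration, used
identically by every operation; world/affine geometry is copied through
headers but never enters the computation.  Output maps write NaN outside
the mask so true zero correlations stay distinguishable from background.
No resampling is performed — a grid mismatch is an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .panels import TimeSeriesPanel

__all__ = ["RoiMask", "load_mask", "load_panel", "write_map", "write_panel_niftis"]

MANIFEST_COLUMNS = ("subject_id", "session", "path")


@dataclass
class RoiMask:
    """An ROI as a fixed enumeration of voxel indices on a reference grid."""

    shape: tuple[int, int, int]
    indices: np.ndarray  # (|S|, 3) int voxel coordinates, ascending (x, y, z)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise ValueError("mask indices must be an (n, 3) array")
        if self.indices.shape[0] < 1:
            raise ValueError("empty mask")
        if np.any(self.indices < 0) or np.any(self.indices >= np.asarray(self.shape)):
            raise ValueError("mask indices out of grid bounds")
        if len({tuple(ix) for ix in self.indices}) != len(self.indices):
            raise ValueError("duplicate voxels in mask")

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Pull mask voxels (in enumeration order) out of a 3-D or 4-D volume."""
        i, j, k = self.indices.T
        return volume[i, j, k]


def load_mask(path: str | Path) -> RoiMask:
    """Read a 3-D NIfTI mask; voxels with value > 0.5 are in the ROI.

    The 0.5 threshold admits both binary masks and probabilistic atlas
    masks whose resampling introduced fractional values.  The enumeration
    order is ascending (x, then y, then z), 0-based.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"mask {path} must be 3-D, got {img.ndim}-D")
    data = np.asarray(img.dataobj, dtype=np.float64)
    inside = np.nan_to_num(data, nan=0.0) > 0.5
    if not inside.any():
        raise ValueError(f"empty mask: no voxel of {path} exceeds 0.5")
    return RoiMask(shape=tuple(img.shape), indices=np.argwhere(inside))


def load_panel(manifest_path: str | Path, mask: RoiMask) -> TimeSeriesPanel:
    """Read all scans of a manifest into a (I, J, V, T) time-series panel.

    Subjects are ordered by first appearance in the manifest, sessions by
    sorted label; every subject must provide the same session set, every
    scan the same grid and T.
    """
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest {manifest_path} lacks columns: {missing}")
    subjects = list(dict.fromkeys(manifest["subject_id"]))
    sessions = sorted(set(manifest["session"]))
    by_key = {(r.subject_id, r.session): r.path for r in manifest.itertuples()}
    for sub in subjects:
        lacking = [ses for ses in sessions if (sub, ses) not in by_key]
        if lacking:
            raise ValueError(f"incomplete sessions: subject {sub} lacks session(s) {lacking}")

    base = Path(manifest_path).parent
    values = None
    for i, sub in enumerate(subjects):
        for j, ses in enumerate(sessions):
            scan_path = Path(by_key[(sub, ses)])
            if not scan_path.is_absolute():
                scan_path = base / scan_path
            img = nib.load(str(scan_path))
            if img.ndim != 4:
                raise ValueError(f"{scan_path}: expected a 4-D scan, got {img.ndim}-D")
            if tuple(img.shape[:3]) != mask.shape:
                raise ValueError(
                    f"{scan_path}: grid {tuple(img.shape[:3])} does not match mask grid {mask.shape}"
                )
            data = mask.extract(np.asarray(img.dataobj, dtype=np.float64))
            if values is None:
                values = np.empty((len(subjects), len(sessions), mask.n_voxels, data.shape[1]))
            elif data.shape[1] != values.shape[3]:
                raise ValueError(
                    f"{scan_path}: T={data.shape[1]} differs from first scan T={values.shape[3]}"
                )
            values[i, j] = data
    return TimeSeriesPanel(values, subjects, sessions)


def write_map(
    values: np.ndarray,
    mask: RoiMask,
    reference_path: str | Path,
    out_path: str | Path,
) -> Path:
    """Write one value per mask voxel as a 3-D NIfTI; background is NaN.

    Header geometry (affine) is copied from the reference volume.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mask.n_voxels,):
        raise ValueError(
            f"expected {mask.n_voxels} values (one per mask voxel), got shape {values.shape}"
        )
    ref = nib.load(str(reference_path))
    vol = np.full(mask.shape, np.nan)
    i, j, k = mask.indices.T
    vol[i, j, k] = values
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol, ref.affine), str(out_path))
    return out_path


def write_panel_niftis(
    panel: TimeSeriesPanel,
    mask: RoiMask,
    out_dir: str | Path,
    affine: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write a panel as per-scan 4-D NIfTIs plus the mask and a TSV manifest.

    Out-of-mask voxels of the 4-D volumes are zero.  Returns the paths of
    the manifest and mask files.  This is the bridge that lets the real-data
    pipeline run unchanged on synthetic fixtures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    i, j, k = mask.indices.T
    mask_vol = np.zeros(mask.shape, dtype=np.float64)
    mask_vol[i, j, k] = 1.0
    mask_path = out_dir / "mask.nii.gz"
    nib.save(nib.Nifti1Image(mask_vol, affine), str(mask_path))

    rows = []
    for si, sub in enumerate(panel.subjects):
        for sj, ses in enumerate(panel.sessions):
            vol = np.zeros(mask.shape + (panel.n_timepoints,))
            vol[i, j, k, :] = panel.values[si, sj]
            name = f"{sub}_ses-{ses}.nii.gz"
            nib.save(nib.Nifti1Image(vol, affine), str(out_dir / name))
            rows.append({"subject_id": sub, "session": ses, "path": name})
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path, mask_path


def grid_for_voxels(n_voxels: int) -> RoiMask:
    """A near-cubic grid whose first ``n_voxels`` enumeration entries form the ROI."""
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    shape = (side, side, side)
    flat = np.arange(n_voxels)
    indices = np.stack(np.unravel_index(flat, shape), axis=1)
    return RoiMask(shape=shape, indices=indices)
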