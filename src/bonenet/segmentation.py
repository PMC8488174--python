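"""CT-driven bone segmentation and TAC / HU extraction.

Bone tissue is separated from marrow and surrounding soft tissue by a
Hounsfield-unit window (default [332, 50000], the calibrated bone window
for mouse CT); per-bone volumes of interest are the intersection of an
integer label map with the windowed mask, and per-frame mean activity
(TAC) and mean HU are read out over each VOI.  PET and CT must share the
voxel grid — no resampling is attempted here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .core import FrameSchedule, TACTable

#: Calibrated bone HU window (lower, upper), treated as a closed interval.
DEFAULT_HU_WINDOW: tuple[float, float] = (332.0, 50000.0)


@dataclass(frozen=True)
class HUWindow:
    lower: float = DEFAULT_HU_WINDOW[0]
    upper: float = DEFAULT_HU_WINDOW[1]

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("HU window requires lower < upper")


@dataclass
class VOISet:
    """Per-bone voxel sets after HU windowing.

    ``label_map`` holds the original integer labels, ``labels`` maps bone
    name -> label value, ``mask`` is the retained-voxel mask, and bones
    whose VOI was emptied by the window are listed in ``empty_bones``.
    """

    label_map: np.ndarray
    labels: dict[str, int]
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.label_map.shape != self.mask.shape:
            raise ValueError("label map and mask must share the voxel grid")
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("labels must be unique per bone")

    def voxel_indices(self, bone: str) -> np.ndarray:
        lab = self.labels[bone]
        return np.flatnonzero((self.label_map == lab) & self.mask)

    @property
    def voxel_counts(self) -> dict[str, int]:
        return {b: int(self.voxel_indices(b).size) for b in self.labels}

    @property
    def empty_bones(self) -> list[str]:
        return [b for b, n in self.voxel_counts.items() if n == 0]


def _as_array(vol: nib.Nifti1Image | np.ndarray) -> np.ndarray:
    if isinstance(vol, nib.spatialimages.SpatialImage):
        return np.asarray(vol.dataobj)
    return np.asarray(vol)


def threshold_mask(ct: nib.Nifti1Image | np.ndarray, window: HUWindow = HUWindow()) -> np.ndarray:
    """Boolean mask of voxels with ``lower <= HU <= upper`` (closed interval)."""
    hu = _as_array(ct).astype(float)
    return (hu >= window.lower) & (hu <= window.upper)


def restrict_labels(
    label_map: nib.Nifti1Image | np.ndarray,
    mask: np.ndarray,
    bone_labels: dict[str, int],
) -> VOISet:
    """Intersect each labelled bone region with the windowed mask.

    Bones reduced to zero voxels are flagged (``VOISet.empty_bones``), not
    dropped, so downstream readouts can emit missing values for them.
    """
    labels = _as_array(label_map)
    mask = np.asarray(mask, dtype=bool)
    if labels.shape != mask.shape:
        raise ValueError(
            f"label map grid {labels.shape} does not match mask grid {mask.shape}"
        )
    vois = VOISet(label_map=labels, labels=dict(bone_labels), mask=mask)
    if vois.empty_bones:
        warnings.warn(
            f"bones with no voxels after HU windowing: {vois.empty_bones}",
            stacklevel=2,
        )
    return vois


def extract_tacs(
    pet: nib.Nifti1Image | np.ndarray,
    schedule: FrameSchedule,
    vois: VOISet,
    decay_corrected: bool = False,
    aggregate: str = "mean",
) -> TACTable:
    """Per-bone mean (or median) activity concentration per frame.

    An empty VOI yields a row of NaNs plus a warning rather than silent
    zeros.  Row order follows the declared bone order of the VOI set.
    """
    vol = _as_array(pet).astype(float)
    if vol.ndim != 4:
        raise ValueError("PET volume must be 4-D (x, y, z, frame)")
    if vol.shape[:3] != vois.label_map.shape:
        raise ValueError("PET and label map must share the voxel grid")
    if vol.shape[3] != len(schedule):
        raise ValueError(
            f"PET has {vol.shape[3]} frames but schedule has {len(schedule)}"
        )
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")

    flat = vol.reshape(-1, vol.shape[3])
    rows = {}
    for bone in vois.labels:
        idx = vois.voxel_indices(bone)
        if idx.size == 0:
            warnings.warn(f"VOI {bone!r} is empty; emitting missing values", stacklevel=2)
            rows[bone] = np.full(len(schedule), np.nan)
        elif aggregate == "mean":
            rows[bone] = flat[idx].mean(axis=0)
        else:
            rows[bone] = np.median(flat[idx], axis=0)

    values = pd.DataFrame.from_dict(rows, orient="index")
    values.index.name = "bone"
    values.columns = [f"{m:.10g}" for m in schedule.midpoints_min]
    return TACTable(values=values, schedule=schedule, decay_corrected=decay_corrected)


def extract_hu(ct: nib.Nifti1Image | np.ndarray, vois: VOISet, aggregate: str = "mean") -> pd.Series:
    """Mean (or median) HU over each bone's retained voxels; NaN if empty."""
    hu = _as_array(ct).astype(float).reshape(-1)
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    out = {}
    for bone in vois.labels:
        idx = vois.voxel_indices(bone)
        if idx.size == 0:
            out[bone] = np.nan
        else:
            out[bone] = float(np.mean(hu[idx]) if aggregate == "mean" else np.median(hu[idx]))
    return pd.Series(out, name="hu").rename_axis("bone")
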