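"""Small digital PET/CT phantoms for exercising the segmentation stage.

A phantom is a voxel grid holding a handful of pairwise-disjoint bone
regions (axis-aligned boxes or spheres), each with its own Hounsfield
value and kinetic parameters.  Rasterisation produces a 3-D CT volume, a
4-D dynamic PET volume framed on a schedule, and an integer label map,
all sharing one affine — enough to validate HU-window segmentation and
TAC/HU extraction end to end without any real scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .core import F18_HALF_LIFE_MIN, FrameSchedule
from .kinetics import (
    DEFAULT_INPUT_FUNCTION,
    InputFunctionParams,
    KineticParams,
    apply_physical_decay,
    simulate_tissue_tac,
)
from .synthetic import bin_to_frames


@dataclass(frozen=True)
class Region:
    """Axis-aligned box (``lo`` inclusive, ``hi`` exclusive, voxel indices)
    or sphere (``center`` voxel, ``radius`` in voxels)."""

    kind: str
    lo: tuple[int, int, int] | None = None
    hi: tuple[int, int, int] | None = None
    center: tuple[float, float, float] | None = None
    radius: float | None = None

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        if self.kind == "box":
            lo, hi = self.lo, self.hi
            if lo is None or hi is None:
                raise ValueError("box region requires lo and hi")
            if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, shape)):
                raise ValueError(f"box {lo}..{hi} outside grid {shape}")
            if any(h <= l for l, h in zip(lo, hi)):
                raise ValueError("box must have positive extent")
            m = np.zeros(shape, dtype=bool)
            m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
            return m
        if self.kind == "sphere":
            if self.center is None or self.radius is None:
                raise ValueError("sphere region requires center and radius")
            idx = np.indices(shape, dtype=float)
            d2 = sum((idx[i] - self.center[i]) ** 2 for i in range(3))
            m = d2 <= self.radius**2
            if not m.any():
                raise ValueError("sphere contains no voxels")
            # sphere must be inside the grid
            lo_ok = all(self.center[i] - self.radius >= -0.5 for i in range(3))
            hi_ok = all(self.center[i] + self.radius <= shape[i] - 0.5 for i in range(3))
            if not (lo_ok and hi_ok):
                raise ValueError("sphere extends outside grid")
            return m
        raise ValueError(f"unknown region kind {self.kind!r}")


@dataclass
class PhantomSpec:
    """Geometry, density and kinetics of a digital phantom."""

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (0.4, 0.4, 0.4)
    regions: dict[str, Region] = field(default_factory=dict)
    hu: dict[str, float] = field(default_factory=dict)
    kinetics: dict[str, KineticParams] = field(default_factory=dict)
    background_hu: float = 40.0
    background_activity: float = 5.0

    def __post_init__(self) -> None:
        missing = set(self.regions) - set(self.hu) | set(self.regions) - set(self.kinetics)
        if missing:
            raise ValueError(f"regions missing HU or kinetics: {sorted(missing)}")

    def label_order(self) -> list[str]:
        """Bones in declaration order; label i+1 is the i-th bone."""
        return list(self.regions)


def rasterize_phantom(
    spec: PhantomSpec,
    schedule: FrameSchedule,
    aif: InputFunctionParams = DEFAULT_INPUT_FUNCTION,
    half_life_min: float = F18_HALF_LIFE_MIN,
    decay_corrected: bool = False,
    grid_step_min: float = 0.05,
) -> tuple[nib.Nifti1Image, nib.Nifti1Image, nib.Nifti1Image]:
    """Rasterise a phantom into (CT 3-D, PET 4-D, label map 3-D) NIfTIs.

    Each bone region is filled uniformly with its HU and its simulated
    framed TAC; the background holds ``background_hu`` and a constant
    activity.  Regions must be pairwise disjoint.  All three images share
    a diagonal affine built from the voxel size.
    """
    if not spec.regions:
        raise ValueError("phantom must define at least one region")
    shape = spec.shape
    ct = np.full(shape, spec.background_hu, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int16)
    n_frames = len(schedule)
    pet = np.full(shape + (n_frames,), float(spec.background_activity), dtype=np.float64)

    t_end = schedule.ends_s[-1] / 60.0 + grid_step_min
    t_grid = np.arange(0.0, t_end + grid_step_min, grid_step_min)

    occupied = np.zeros(shape, dtype=bool)
    for i, (bone, region) in enumerate(spec.regions.items(), start=1):
        m = region.mask(shape)
        if (m & occupied).any():
            raise ValueError(f"region {bone!r} overlaps a previous region")
        occupied |= m
        ct[m] = spec.hu[bone]
        labels[m] = i
        curve = simulate_tissue_tac(aif, spec.kinetics[bone], t_grid)
        if not decay_corrected:
            curve = apply_physical_decay(curve, t_grid, half_life_min, "decay")
        frames = bin_to_frames(curve, t_grid, schedule)
        pet[m, :] = frames

    affine = np.diag(list(spec.voxel_size_mm) + [1.0])
    ct_img = nib.Nifti1Image(ct, affine)
    pet_img = nib.Nifti1Image(pet, affine)
    label_img = nib.Nifti1Image(labels, affine)
    return ct_img, pet_img, label_img
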