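"""Core containers shared by every pipeline stage.

The study design this package targets is a 60-min dynamic total-body
FDG-PET acquisition of the mouse skeleton: activity concentration is
recorded per bone volume of interest over a fixed frame schedule, and
all downstream quantification (SUV, equilibrium averaging, correlation
networks) operates on the resulting bone x frame table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Physical half-life of fluorine-18, minutes. Single source of truth for
#: every decay computation in the package.
F18_HALF_LIFE_MIN: float = 109.77

#: The seven skeletal volumes of interest, appendicular then axial.
DEFAULT_BONES: tuple[str, ...] = (
    "tibia",
    "femur",
    "humerus",
    "forearm",
    "spine",
    "sternum",
    "skull",
)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous time bins of a dynamic PET acquisition.

    Parameters
    ----------
    starts_s, durations_s
        Frame start times and durations in seconds.  Frames must be
        contiguous (each frame starts where the previous one ends),
        non-overlapping and strictly positive in duration.
    """

    starts_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durs)
        if starts.ndim != 1 or starts.shape != durs.shape:
            raise ValueError("starts and durations must be 1-D and equal length")
        if len(starts) == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if starts[0] < 0:
            raise ValueError("first frame start must be non-negative")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_counts(cls, blocks: Sequence[tuple[int, float]], start_s: float = 0.0) -> "FrameSchedule":
        """Build a schedule from (count, duration_s) blocks, e.g. ``[(6, 30), (3, 60)]``."""
        durs: list[float] = []
        for count, dur in blocks:
            if count < 1:
                raise ValueError("block count must be >= 1")
            durs.extend([float(dur)] * int(count))
        durations = np.array(durs)
        starts = start_s + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    def __len__(self) -> int:
        return len(self.starts_s)

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def span_s(self) -> float:
        """Total scan span in seconds (first start to last end)."""
        return float(self.ends_s[-1] - self.starts_s[0])

    @property
    def span_min(self) -> float:
        return self.span_s / 60.0

    @property
    def midpoints_min(self) -> np.ndarray:
        """Frame midpoint times in minutes, the time axis used for any
        time-indexed computation on framed data."""
        return (self.starts_s + 0.5 * self.durations_s) / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    def shift(self, offset_s: float) -> "FrameSchedule":
        """Return a copy with all frame starts shifted by ``offset_s`` seconds."""
        return FrameSchedule(self.starts_s + offset_s, self.durations_s.copy())

    def frames_within(self, window_min: tuple[float, float]) -> np.ndarray:
        """Indices of frames whose [start, end] lies entirely inside the window.

        The window is given in minutes post time-zero of the schedule.  No
        fractional weighting is applied: a frame either contributes fully or
        not at all.
        """
        lo_s, hi_s = window_min[0] * 60.0, window_min[1] * 60.0
        tol = 1e-9
        ok = (self.starts_s >= lo_s - tol) & (self.ends_s <= hi_s + tol)
        return np.nonzero(ok)[0]


def mouse_60min_schedule() -> FrameSchedule:
    """The 60-min dynamic reconstruction schedule used for the mouse cohort:
    6 x 30 s, 3 x 60 s, 2 x 120 s, 10 x 300 s (21 frames, 0-3600 s)."""
    return FrameSchedule.from_counts([(6, 30), (3, 60), (2, 120), (10, 300)])


@dataclass
class TACTable:
    """Bone x frame activity-concentration matrix for one animal (or an
    across-animal average).

    ``values`` is indexed by bone name with one column per frame; column
    labels are frame midpoint times in minutes.  ``units`` documents the
    concentration scale and ``decay_corrected`` whether physical isotope
    decay has been compensated.
    """

    values: pd.DataFrame
    schedule: FrameSchedule
    units: str = "kBq/mL"
    decay_corrected: bool = False
    animal_id: str | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.schedule):
            raise ValueError(
                f"table has {self.values.shape[1]} frame columns but schedule "
                f"has {len(self.schedule)} frames"
            )
        if self.values.index.duplicated().any():
            dupes = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValueError(f"duplicate bone rows: {dupes}")

    @property
    def bones(self) -> list[str]:
        return list(self.values.index)

    def copy_with(self, **kwargs) -> "TACTable":
        out = replace(self, values=self.values.copy())
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out


def decay_factor(t_min: np.ndarray | float, half_life_min: float = F18_HALF_LIFE_MIN) -> np.ndarray:
    """exp(-ln2 * t / T_half): fraction of activity remaining after ``t_min``."""
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    return np.exp(-np.log(2.0) * np.asarray(t_min, dtype=float) / half_life_min)
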