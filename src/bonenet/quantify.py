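"""SUV quantification, equilibrium averaging and the density-metabolism quotient.

SUV follows the body-weight convention with tissue density 1 g/mL:

    SUV = C_tissue [kBq/mL] / (injected dose [kBq] / body weight [g])

The bone uptake "at equilibrium" is the unweighted mean of the frames
lying entirely inside a late-scan window (default 45-60 min, which for
the 60-min mouse schedule is exactly the three final 300-s frames).  The
density-to-metabolism quotient expresses each bone's equilibrium SUV and
mean HU as a percentage of the respective totals over all bones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import F18_HALF_LIFE_MIN, FrameSchedule, TACTable
from .kinetics import apply_physical_decay

DEFAULT_EQUILIBRIUM_WINDOW_MIN: tuple[float, float] = (45.0, 60.0)


@dataclass(frozen=True)
class AnimalMeta:
    """Per-animal scan metadata: injected dose (MBq), body weight (g) and
    the delay between injection and scan start (s)."""

    animal_id: str
    dose_MBq: float
    weight_g: float
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_MBq <= 0:
            raise ValueError("injected dose must be positive")
        if self.weight_g <= 0:
            raise ValueError("body weight must be positive")
        if self.delay_s < 0:
            raise ValueError("injection-to-scan delay must be non-negative")


@dataclass
class SUVRecord:
    """Per-bone, per-animal SUV time course and its equilibrium average."""

    bone: str
    animal_id: str
    suv_tac: np.ndarray
    equilibrium_suv: float
    n_equilibrium_frames: int


@dataclass
class EquilibriumResult:
    value: float
    n_frames: int
    frame_indices: np.ndarray


def correct_time_delay(schedule: FrameSchedule, delay_s: float) -> FrameSchedule:
    """Shift frame starts so time zero is the injection instant.

    The scanner clock starts ``delay_s`` seconds after injection, so on
    the injection clock every frame starts ``delay_s`` later.
    """
    if delay_s < 0:
        raise ValueError("delay must be non-negative")
    return schedule.shift(delay_s)


def compute_suv(
    conc_kBq_per_mL: np.ndarray | float, dose_MBq: float, weight_g: float
) -> np.ndarray | float:
    """Body-weight SUV (dimensionless, density 1 g/mL)."""
    if dose_MBq <= 0:
        raise ValueError("injected dose must be positive")
    if weight_g <= 0:
        raise ValueError("body weight must be positive")
    dose_kBq = dose_MBq * 1000.0
    return np.asarray(conc_kBq_per_mL, dtype=float) * weight_g / dose_kBq


def decay_correct_table(table: TACTable, half_life_min: float = F18_HALF_LIFE_MIN) -> TACTable:
    """Undo physical decay frame-by-frame using frame midpoint times.

    Identity if the table is already decay corrected.
    """
    if table.decay_corrected:
        return table.copy_with()
    t_mid = table.schedule.midpoints_min
    corrected = apply_physical_decay(table.values.to_numpy(), t_mid, half_life_min, "undo")
    out = table.copy_with(decay_corrected=True)
    out.values.loc[:, :] = corrected
    return out


def suv_table(table: TACTable, meta: AnimalMeta) -> TACTable:
    """Convert an activity-concentration table to SUV units."""
    suv = compute_suv(table.values.to_numpy(), meta.dose_MBq, meta.weight_g)
    out = table.copy_with(units="SUV")
    out.values.loc[:, :] = suv
    return out


def equilibrium_average(
    suv_tac: np.ndarray,
    schedule: FrameSchedule,
    window_min: tuple[float, float] = DEFAULT_EQUILIBRIUM_WINDOW_MIN,
) -> EquilibriumResult:
    """Unweighted mean over frames lying entirely inside the window.

    Frames contribute fully or not at all (no fractional weighting); with
    the 60-min mouse schedule and the default window this is exactly the
    three last 300-s frames (45-50, 50-55, 55-60 min).
    """
    suv_tac = np.asarray(suv_tac, dtype=float)
    if suv_tac.shape != (len(schedule),):
        raise ValueError("SUV TAC length must equal frame count")
    idx = schedule.frames_within(window_min)
    if idx.size == 0:
        raise ValueError(
            f"no frame lies entirely within [{window_min[0]:g}, {window_min[1]:g}] min; "
            f"schedule spans [{schedule.starts_s[0] / 60:g}, {schedule.ends_s[-1] / 60:g}] min"
        )
    return EquilibriumResult(
        value=float(np.mean(suv_tac[idx])), n_frames=int(idx.size), frame_indices=idx
    )


def suv_records(
    table: TACTable,
    meta: AnimalMeta,
    window_min: tuple[float, float] = DEFAULT_EQUILIBRIUM_WINDOW_MIN,
) -> list[SUVRecord]:
    """Per-bone SUV records (time course + equilibrium mean) for one animal."""
    suv = suv_table(table, meta)
    out = []
    for bone in suv.bones:
        tac = suv.values.loc[bone].to_numpy(dtype=float)
        eq = equilibrium_average(tac, table.schedule, window_min)
        out.append(
            SUVRecord(
                bone=bone,
                animal_id=meta.animal_id,
                suv_tac=tac,
                equilibrium_suv=eq.value,
                n_equilibrium_frames=eq.n_frames,
            )
        )
    return out


def density_metabolism_quotient(
    equilibrium_suv: pd.Series, mean_hu: pd.Series
) -> pd.DataFrame:
    """Each bone's SUV and HU as a percentage of the totals over all bones.

    Returns a DataFrame indexed by bone with columns ``suv_percent`` and
    ``hu_percent``, each summing to 100.
    """
    suv = equilibrium_suv.astype(float)
    hu = mean_hu.astype(float)
    if set(suv.index) != set(hu.index):
        raise ValueError("SUV and HU tables must cover the same bones")
    hu = hu.reindex(suv.index)
    if suv.isna().any() or hu.isna().any():
        raise ValueError("missing values in SUV or HU input")
    if (suv < 0).any() or (hu < 0).any():
        raise ValueError("SUV and HU values must be non-negative")
    if suv.sum() <= 0 or hu.sum() <= 0:
        raise ValueError("totals must be positive")
    return pd.DataFrame(
        {
            "suv_percent": 100.0 * suv / suv.sum(),
            "hu_percent": 100.0 * hu / hu.sum(),
        }
    ).rename_axis("bone")
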