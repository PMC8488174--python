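"""Delimited-text readers/writers for every table the pipeline exchanges.

Dialect: UTF-8 CSV, comma separator, '.' decimal, mandatory header row.
TAC tables carry a ``bone`` column (plus optional ``animal_id``) followed
by one column per frame named by the frame midpoint time in minutes; the
frame schedule travels in a sidecar CSV (``start_s,duration_s``) and
per-animal metadata in a third (``animal_id,dose_MBq,weight_g,delay_s``).
Readers validate loudly — duplicate keys, non-numeric cells and frame
mismatches are named errors, never silent coercion.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import FrameSchedule, TACTable


class ParseError(ValueError):
    """A malformed input file; the message names the file, line and field."""


def write_schedule(schedule: FrameSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {"start_s": schedule.starts_s, "duration_s": schedule.durations_s}
    ).to_csv(path, index=False)


def read_schedule(path: str | Path) -> FrameSchedule:
    df = _read_csv(path, required=("start_s", "duration_s"))
    try:
        return FrameSchedule(
            df["start_s"].to_numpy(dtype=float), df["duration_s"].to_numpy(dtype=float)
        )
    except ValueError as e:
        raise ParseError(f"{path}: invalid schedule: {e}") from e


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ParseError(f"{path}: cannot parse CSV: {e}") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], path: Path) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise ParseError(f"{path}: empty cell in column {col!r} at line {line}")
        df[col] = converted
    return df


def write_tac_tables(tables: Sequence[TACTable], path: str | Path) -> None:
    """Write one or more animals' TAC tables into a single CSV.

    The ``animal_id`` column is included whenever any table carries one.
    """
    frames = []
    with_animal = any(t.animal_id is not None for t in tables)
    for t in tables:
        df = t.values.reset_index()
        if with_animal:
            df.insert(0, "animal_id", t.animal_id or "")
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tac_tables(
    path: str | Path,
    schedule: FrameSchedule,
    units: str = "kBq/mL",
    decay_corrected: bool = False,
) -> list[TACTable]:
    """Read a (possibly multi-animal) TAC CSV against its frame schedule.

    Returns one table per animal (a single table without ``animal_id`` is
    treated as one anonymous animal).  Frame-column count must match the
    schedule; duplicate (animal, bone) keys are rejected.
    """
    path = Path(path)
    df = _read_csv(path, required=("bone",))
    frame_cols = [c for c in df.columns if c not in ("bone", "animal_id")]
    if len(frame_cols) != len(schedule):
        raise ParseError(
            f"{path}: {len(frame_cols)} frame columns but schedule has "
            f"{len(schedule)} frames"
        )
    df = _check_numeric(df, frame_cols, path)

    expected = [f"{m:.10g}" for m in schedule.midpoints_min]

    def build(sub: pd.DataFrame, animal_id: str | None) -> TACTable:
        dup = sub["bone"][sub["bone"].duplicated()]
        if not dup.empty:
            who = f" for animal {animal_id!r}" if animal_id else ""
            raise ParseError(f"{path}: duplicated bone row(s) {sorted(set(dup))}{who}")
        values = sub.set_index("bone")[frame_cols].astype(float)
        values.columns = expected
        return TACTable(
            values=values,
            schedule=schedule,
            units=units,
            decay_corrected=decay_corrected,
            animal_id=animal_id,
        )

    if "animal_id" in df.columns:
        return [
            build(sub.drop(columns="animal_id"), str(aid))
            for aid, sub in df.groupby("animal_id", sort=False)
        ]
    return [build(df, None)]


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path, required=("animal_id", "dose_MBq", "weight_g", "delay_s"))
    df = _check_numeric(df, ("dose_MBq", "weight_g", "delay_s"), path)
    dup = df["animal_id"][df["animal_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicated animal_id(s) {sorted(set(dup))}")
    if (df["dose_MBq"] <= 0).any() or (df["weight_g"] <= 0).any() or (df["delay_s"] < 0).any():
        raise ParseError(f"{path}: dose and weight must be positive, delay non-negative")
    return df


def write_hu_table(hu: pd.DataFrame, path: str | Path) -> None:
    hu.to_csv(path, index=False)


def read_hu_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path, required=("animal_id", "bone", "hu"))
    df = _check_numeric(df, ("hu",), path)
    dup = df.duplicated(subset=["animal_id", "bone"])
    if dup.any():
        raise ParseError(f"{path}: duplicated (animal_id, bone) rows")
    return df


def write_graph(g: nx.Graph, graphml_path: str | Path, edgelist_path: str | Path) -> None:
    """Export the relationship graph as GraphML plus a plain TSV edge list.

    Node attributes: bone name and degree; edge attribute: Pearson R.
    """
    export = nx.Graph(**g.graph)
    for n, d in g.degree():
        export.add_node(n, bone=str(n), degree=int(d))
    for a, b, data in g.edges(data=True):
        export.add_edge(a, b, weight=float(data["weight"]))
    nx.write_graphml(export, graphml_path)

    with open(edgelist_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["bone_a", "bone_b", "r"])
        for a, b, data in sorted(g.edges(data=True)):
            writer.writerow([a, b, f"{data['weight']:.6f}"])
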