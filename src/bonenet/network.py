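"""Bone-bone relationship graph from time-activity profiles.

The core procedure: assemble one signal profile per bone (frame-wise mean
across animals, or one row per bone x animal), compute the all-vs-all
Pearson correlation matrix, then keep only edges that (a) exceed a
correlation threshold (strictly, R > r_min) and (b) rank within the top-k
correlations of at least one endpoint.  Thresholding plus kNN pruning
minimises the edge count while every bone stays in the graph as a node,
so weakly connected bones show up as low-degree or isolated nodes rather
than vanishing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import TACTable

DEFAULT_R_MIN: float = 0.7
DEFAULT_KNN: int = 3


def assemble_profiles(
    tables: Sequence[TACTable], mode: str = "mouse_average"
) -> pd.DataFrame:
    """Stack per-animal TAC tables into one profile matrix.

    ``mouse_average`` (default): one row per bone, the frame-wise mean
    across animals.  ``per_animal``: one row per bone x animal, labelled
    ``bone|animal_id``.  All animals must share the bone set and frame
    schedule.
    """
    if len(tables) == 0:
        raise ValueError("no TAC tables given")
    first = tables[0]
    bones = first.bones
    for t in tables[1:]:
        if set(t.bones) != set(bones):
            raise ValueError("animals disagree on the bone set")
        same = np.allclose(t.schedule.starts_s, first.schedule.starts_s) and np.allclose(
            t.schedule.durations_s, first.schedule.durations_s
        )
        if not same:
            raise ValueError("animals disagree on the frame schedule")

    if mode == "mouse_average":
        stacked = np.stack([t.values.loc[bones].to_numpy(dtype=float) for t in tables])
        profiles = pd.DataFrame(
            stacked.mean(axis=0), index=pd.Index(bones, name="bone"), columns=first.values.columns
        )
    elif mode == "per_animal":
        rows = {}
        for i, t in enumerate(tables):
            aid = t.animal_id or f"animal{i + 1}"
            for bone in bones:
                rows[f"{bone}|{aid}"] = t.values.loc[bone].to_numpy(dtype=float)
        profiles = pd.DataFrame.from_dict(rows, orient="index")
        profiles.columns = first.values.columns
        profiles.index.name = "profile"
    else:
        raise ValueError("mode must be 'mouse_average' or 'per_animal'")

    if profiles.isna().any().any():
        raise ValueError("profiles contain missing values")
    return profiles


def pearson_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """All-vs-all Pearson correlation of profile rows.

    Symmetric with unit diagonal; a zero-variance row is an error naming
    the offending bone (its correlation is undefined).
    """
    x = profiles.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("profiles need at least 3 time points")
    sd = x.std(axis=1)
    flat = [str(lbl) for lbl, s in zip(profiles.index, sd) if s == 0]
    if flat:
        raise ValueError(f"zero-variance profiles (correlation undefined): {flat}")
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=profiles.index, columns=profiles.index)


def _ranked_candidates(r: pd.DataFrame, node: str, r_min: float) -> list[str]:
    """Candidate neighbours of ``node`` with R > r_min, best first.

    Ties broken by higher R then lexicographic neighbour name.
    """
    others = [(n, float(r.loc[node, n])) for n in r.index if n != node]
    cands = [(n, v) for n, v in others if v > r_min]
    cands.sort(key=lambda nv: (-nv[1], nv[0]))
    return [n for n, _ in cands]


def knn_threshold_graph(
    r: pd.DataFrame,
    r_min: float = DEFAULT_R_MIN,
    k: int = DEFAULT_KNN,
    rule: str = "union",
) -> nx.Graph:
    """Relationship graph from a correlation matrix.

    Candidate edges are pairs with R strictly above ``r_min``; a candidate
    survives kNN pruning if it ranks within the top-``k`` candidates of at
    least one endpoint (``rule='union'``, default) or of both
    (``rule='mutual'``).  Every input bone remains a node regardless of
    connectivity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rule not in ("union", "mutual"):
        raise ValueError("rule must be 'union' or 'mutual'")
    nodes = [str(n) for n in r.index]
    if list(r.index) != list(r.columns):
        raise ValueError("correlation matrix rows and columns must match")

    top: dict[str, set[str]] = {
        n: set(_ranked_candidates(r, n, r_min)[:k]) for n in nodes
    }
    g = nx.Graph(r_min=float(r_min), k=int(k), rule=rule)
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            val = float(r.loc[a, b])
            if val <= r_min:
                continue
            in_a, in_b = b in top[a], a in top[b]
            keep = (in_a or in_b) if rule == "union" else (in_a and in_b)
            if keep:
                g.add_edge(a, b, weight=val)
    return g


@dataclass
class GraphSummary:
    degrees: dict[str, int]
    components: list[set[str]]
    mean_edge_weight: float
    n_edges: int


def graph_summary(g: nx.Graph) -> GraphSummary:
    """Per-node degree, connected components and mean edge weight."""
    weights = [d["weight"] for _, _, d in g.edges(data=True)]
    return GraphSummary(
        degrees={n: int(d) for n, d in g.degree()},
        components=[set(c) for c in nx.connected_components(g)],
        mean_edge_weight=float(np.mean(weights)) if weights else float("nan"),
        n_edges=g.number_of_edges(),
    )
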