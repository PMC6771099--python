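"""Directed weighted networks of cross-border patient flows.

Each off-diagonal OD entry becomes a directed edge residence -> hospital
weighted by the number of patients who moved.  Self-flows (local care) are
kept as a node attribute rather than a self-loop, so the graph isolates the
inter-municipal structure while conserving totals.  Hub identification,
hub-excluded subnetworks and weak components support the reading of a
regional system as a central core plus satellite clusters.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .od import ODMatrix
from .io import ValidationError


def build_flow_graph(od: ODMatrix) -> nx.DiGraph:
    """Directed graph with one edge per non-zero off-diagonal OD entry.

    Node attributes: ``self_flow`` (diagonal entry), ``resident_total``
    (row sum) and ``hospitalized_total`` (column sum).
    """
    g = nx.DiGraph(source_filter=od.filter_applied)
    row_totals = od.counts.sum(axis=1)
    col_totals = od.counts.sum(axis=0)
    for u in od.unit_ids:
        g.add_node(
            u,
            self_flow=int(od.counts.at[u, u]),
            resident_total=int(row_totals[u]),
            hospitalized_total=int(col_totals[u]),
        )
    stacked = od.counts.stack()
    for (i, j), w in stacked[stacked > 0].items():
        if i != j:
            g.add_edge(i, j, weight=int(w))
    return g


def node_strengths(g: nx.DiGraph) -> pd.DataFrame:
    """Weighted in- and out-degree per node."""
    frame = pd.DataFrame(
        {
            "in_strength": pd.Series(dict(g.in_degree(weight="weight"))),
            "out_strength": pd.Series(dict(g.out_degree(weight="weight"))),
        }
    ).reindex(list(g.nodes))
    frame.index.name = "unit"
    return frame.fillna(0).astype(int)


def identify_hubs(g: nx.DiGraph, k: int = 1) -> list[str]:
    """Top-k nodes by in-strength (patients attracted), ties lexicographic."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    strengths = node_strengths(g)["in_strength"]
    ranked = sorted(strengths.index, key=lambda u: (-strengths[u], u))
    return ranked[: min(k, len(ranked))]


def remove_node_subnetwork(g: nx.DiGraph, unit: str) -> nx.DiGraph:
    """Copy of the graph with one node and all its incident edges removed."""
    if unit not in g:
        raise ValidationError(f"unit {unit!r} not in graph")
    h = g.copy()
    h.remove_node(unit)
    return h


def weak_components(g: nx.DiGraph) -> list[set[str]]:
    """Weakly connected components (direction ignored), largest first."""
    comps = [set(c) for c in nx.weakly_connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def edge_weight_sum(g: nx.DiGraph) -> int:
    return int(sum(w for _, _, w in g.edges(data="weight")))


# ---------------------------------------------------------------------------
# Origin entropy
# ---------------------------------------------------------------------------


def origin_entropy(
    od: ODMatrix, include_self: bool = True, normalize: bool = True
) -> pd.Series:
    """Shannon entropy of each origin's destination-choice distribution.

    Low entropy: an origin's patients concentrate on a single hospital
    municipality (well-ordered flows); high entropy: destinations are
    dispersed.  Natural log; with ``normalize`` the value is divided by
    ``ln(m)`` where *m* is the number of destinations actually used,
    defining 0 for a single destination, so the index lies in [0, 1].
    ``include_self`` controls whether local care counts as a destination.
    Absolute values depend on these conventions and are not comparable
    across differently configured studies.
    """
    counts = od.counts.copy().astype(float)
    if not include_self:
        np.fill_diagonal(counts.values, 0.0)
    out = {}
    for origin, row in counts.iterrows():
        used = row[row > 0]
        if used.empty:
            out[origin] = float("nan")  # no cases: entropy undefined
            continue
        p = (used / used.sum()).to_numpy()
        h = float(-(p * np.log(p)).sum())
        if normalize:
            h = 0.0 if len(p) == 1 else h / math.log(len(p))
        out[origin] = h
    series = pd.Series(out).reindex(od.unit_ids)
    series.index.name = "origin"
    return series.rename("entropy")


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def graph_to_edge_csv(g: nx.DiGraph, path: str | Path) -> None:
    rows = [
        {"origin": i, "destination": j, "weight": w}
        for i, j, w in sorted(g.edges(data="weight"))
    ]
    pd.DataFrame(rows, columns=["origin", "destination", "weight"]).to_csv(
        path, index=False
    )


def graph_to_graphml(g: nx.DiGraph, path: str | Path) -> None:
    h = g.copy()
    if h.graph.get("source_filter") is None:
        h.graph.pop("source_filter", None)
    nx.write_graphml(h, str(path))


def node_metrics_to_csv(g: nx.DiGraph, path: str | Path) -> None:
    frame = node_strengths(g)
    frame["self_flow"] = pd.Series(nx.get_node_attributes(g, "self_flow"))
    frame.to_csv(path, index=True)
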