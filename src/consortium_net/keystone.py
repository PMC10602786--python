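"""Centrality-based keystone scoring of consortium networks.

Keystone taxa in co-occurrence networks show low betweenness, high
closeness and high degree.  The key-score condenses this into

    key_score = degree + closeness - betweenness

on *homogenized* centralities: each raw index is divided by its sum over
all nodes, putting the three on one unitless scale that sums to one.

Raw centralities are computed on the absolute edge weights (signs carry
interaction direction, not topology): degree is node strength (sum of
|weight|), path length uses distance 1/|weight|, closeness is harmonic
(so disconnected networks are handled and isolated nodes score exactly
zero), betweenness is weighted shortest-path betweenness.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import ConsortiumNetwork

__all__ = [
    "KeyScoreTable",
    "centralities",
    "homogenize",
    "key_score",
    "rank_keystones",
    "keystone_table",
]


@dataclass
class KeyScoreTable:
    """Per-node raw and homogenized centralities plus key-score."""

    frame: pd.DataFrame  # index: taxon; columns: *_raw, betweenness, closeness, degree, key_score

    def ranked(self) -> list[str]:
        return rank_keystones(self)

    def __len__(self) -> int:
        return len(self.frame)


def centralities(net: ConsortiumNetwork) -> pd.DataFrame:
    """Raw betweenness, closeness (harmonic) and degree (strength).

    Isolated nodes get (0, 0, 0); an empty network gives an empty frame.
    """
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for a, b, d in net.graph.edges(data=True):
        w = abs(float(d["weight"]))
        if w <= 0:
            raise ValueError(f"edge ({a},{b}) has non-positive weight")
        g.add_edge(a, b, weight=w, distance=1.0 / w)
    nodes = sorted(g.nodes)
    strength = dict(g.degree(weight="weight"))
    closeness = nx.harmonic_centrality(g, distance="distance")
    betweenness = nx.betweenness_centrality(g, weight="distance", normalized=False)
    return pd.DataFrame(
        {
            "betweenness_raw": [betweenness[v] for v in nodes],
            "closeness_raw": [closeness[v] for v in nodes],
            "degree_raw": [strength[v] for v in nodes],
        },
        index=pd.Index(nodes, name="taxon"),
        dtype=float,
    )


def homogenize(raw: np.ndarray) -> np.ndarray:
    """Sum-to-one normalization of one centrality index; all-zero stays zero."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw centralities must be non-negative")
    total = raw.sum()
    return raw / total if total > 0 else np.zeros_like(raw)


def key_score(betweenness: float, closeness: float, degree: float) -> float:
    """Key-score of one node from its homogenized centralities."""
    return degree + closeness - betweenness


def keystone_table(net: ConsortiumNetwork) -> KeyScoreTable:
    """Full per-node table: raw, homogenized and key-score columns."""
    raw = centralities(net)
    frame = raw.copy()
    frame["betweenness"] = homogenize(raw["betweenness_raw"].to_numpy())
    frame["closeness"] = homogenize(raw["closeness_raw"].to_numpy())
    frame["degree"] = homogenize(raw["degree_raw"].to_numpy())
    frame["key_score"] = frame["degree"] + frame["closeness"] - frame["betweenness"]
    return KeyScoreTable(frame)


def rank_keystones(table: KeyScoreTable) -> list[str]:
    """Taxa in descending key-score order.

    Ties break by higher homogenized degree, then lexicographic taxon ID
    (stable and documented).
    """
    df = table.frame
    order = sorted(
        df.index,
        key=lambda t: (-df.at[t, "key_score"], -df.at[t, "degree"], t),
    )
    return order
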