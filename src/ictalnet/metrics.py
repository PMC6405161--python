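"""Nodal graph measures on a weighted connectome.

Six per-node measures: degree and binary clustering on the nonzero
adjacency; strength on the weights; efficiency, betweenness and closeness
on shortest paths with the inverse-weight distance d = 1/w (strong
connections are short, so short paths mean strong integration -- the
standard convention for connectomes). Disconnected pairs contribute 0 to
efficiency and are excluded from the closeness average; isolated nodes get
0 for all path-based measures.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Connectome

METRIC_NAMES = ("degree", "strength", "clustering", "efficiency", "betweenness", "closeness")


def _graph(c: Connectome) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(c.n))
    rows, cols = np.nonzero(np.triu(c.weights, k=1))
    for i, j in zip(rows.tolist(), cols.tolist()):
        w = float(c.weights[i, j])
        g.add_edge(i, j, weight=w, distance=1.0 / w)
    return g


def nodal_metrics(c: Connectome, weighted_clustering: bool = False) -> pd.DataFrame:
    """All six nodal measures, one row per region (indexed by label).

    ``weighted_clustering`` switches the clustering coefficient to the
    weighted (geometric-mean) variant; the default is the binary triangle
    fraction on the nonzero adjacency.
    """
    g = _graph(c)
    n = c.n
    degree = np.array([g.degree(i) for i in range(n)], dtype=float)
    strength = c.weights.sum(axis=1)
    clustering_dict = nx.clustering(g, weight="weight" if weighted_clustering else None)
    clustering = np.array([clustering_dict[i] for i in range(n)])

    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="distance"))
    efficiency = np.zeros(n)
    closeness = np.zeros(n)
    for i in range(n):
        d = lengths.get(i, {i: 0.0})
        inv = [1.0 / d[j] for j in d if j != i]
        reach = [d[j] for j in d if j != i]
        if n > 1:
            efficiency[i] = sum(inv) / (n - 1)  # unreachable pairs count 0
        if reach:
            closeness[i] = 1.0 / (sum(reach) / len(reach))

    betweenness_dict = nx.betweenness_centrality(g, weight="distance", normalized=True)
    betweenness = np.array([betweenness_dict[i] for i in range(n)])

    return pd.DataFrame(
        {
            "degree": degree,
            "strength": strength,
            "clustering": clustering,
            "efficiency": efficiency,
            "betweenness": betweenness,
            "closeness": closeness,
        },
        index=pd.Index(c.labels, name="region"),
    )
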