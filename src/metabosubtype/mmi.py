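"""Metabolite-metabolite interaction (MMI) network.

Edges join metabolite pairs whose Pearson correlation (on standardized log2
intensities, the same scale as the co-expression network stage) exceeds the
threshold in absolute value, strictly (default |r| > 0.4).  Isolated nodes
are retained so hub lists stay complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import MetaboliteAbundanceMatrix
from .wmcna import metabolite_correlation

__all__ = ["MmiNetwork", "build_mmi_network", "network_summary"]


@dataclass
class MmiNetwork:
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (i, j, r) with i < j in node order
    threshold: float

    def degree(self) -> pd.Series:
        deg = pd.Series(0, index=self.nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, j, r in self.edges:
            g.add_edge(i, j, r=float(r))
        return g


def build_mmi_network(
    matrix: MetaboliteAbundanceMatrix,
    subset: list[str] | None = None,
    r_threshold: float = 0.4,
) -> MmiNetwork:
    """Correlation-thresholded network over (a subset of) the metabolites."""
    if subset is not None:
        missing = [m for m in subset if m not in matrix.values.index]
        if missing:
            raise ValueError(f"subset metabolites not in matrix: {missing[:5]}")
        matrix = MetaboliteAbundanceMatrix(matrix.values.loc[subset], matrix.group)
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 metabolites")
    cor = metabolite_correlation(matrix)
    ids = list(cor.index)
    r = cor.to_numpy()
    edges = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if abs(r[a, b]) > r_threshold:
                edges.append((ids[a], ids[b], float(r[a, b])))
    return MmiNetwork(nodes=ids, edges=edges, threshold=r_threshold)


def network_summary(net: MmiNetwork) -> dict:
    deg = net.degree()
    return {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "degree_min": int(deg.min()) if len(deg) else 0,
        "degree_median": float(np.median(deg)) if len(deg) else 0.0,
        "degree_max": int(deg.max()) if len(deg) else 0,
        "n_isolated": int((deg == 0).sum()),
    }
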