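"""Bridge-centrality indices over a two-community symptom network.

Given an estimated network (weights omega) and a partition into an MD and a
CF community, four node-level indices quantify how strongly a node connects
the two communities:

* bridge strength — sum of |w| over edges to the other community;
* bridge expected influence — the same sum but signed;
* bridge closeness — reciprocal of the mean weighted geodesic distance to
  the nodes of the other community (edge length = 1/|w|);
* bridge betweenness — how often the node lies strictly inside a weighted
  geodesic between a cross-community pair, with tied geodesics splitting
  the credit equally.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .ising import IsingModel

INDEX_NAMES = (
    "bridge_strength",
    "bridge_expected_influence",
    "bridge_closeness",
    "bridge_betweenness",
)


def _check_partition(model: IsingModel, partition: dict[str, str]) -> None:
    missing = [lab for lab in model.labels if lab not in partition]
    if missing:
        raise ValueError(f"partition missing nodes: {missing}")
    if len(set(partition[lab] for lab in model.labels)) != 2:
        raise ValueError("bridge indices require exactly two communities")


def _other_indices(model: IsingModel, partition: dict[str, str], node: str):
    own = partition[node]
    return [j for j, lab in enumerate(model.labels) if partition[lab] != own]


def bridge_strength(model: IsingModel, partition: dict[str, str], node: str) -> float:
    """Sum of |omega_ij| over neighbours j in the other community."""
    _check_partition(model, partition)
    i = model.index(node)
    other = _other_indices(model, partition, node)
    return float(np.abs(model.omega[i, other]).sum())


def bridge_expected_influence(model: IsingModel, partition: dict[str, str], node: str) -> float:
    """Signed sum of omega_ij over neighbours j in the other community."""
    _check_partition(model, partition)
    i = model.index(node)
    other = _other_indices(model, partition, node)
    return float(model.omega[i, other].sum())


def to_graph(model: IsingModel) -> nx.Graph:
    """Weighted graph of the nonzero couplings; 'length' = 1/|weight|."""
    g = nx.Graph()
    g.add_nodes_from(model.labels)
    n = model.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            w = model.omega[i, j]
            if w != 0:
                g.add_edge(model.labels[i], model.labels[j], weight=w, length=1.0 / abs(w))
    return g


def bridge_closeness(
    model: IsingModel, partition: dict[str, str], node: str, graph: nx.Graph | None = None
) -> float:
    """1 / mean geodesic distance from ``node`` to the other community.

    Only reachable other-community nodes enter the mean; a node that reaches
    none of them gets closeness 0.
    """
    _check_partition(model, partition)
    g = graph if graph is not None else to_graph(model)
    dist = nx.single_source_dijkstra_path_length(g, node, weight="length")
    own = partition[node]
    targets = [d for lab, d in dist.items() if lab != node and partition[lab] != own]
    if not targets:
        return 0.0
    return float(1.0 / np.mean(targets))


def bridge_betweenness(
    model: IsingModel, partition: dict[str, str], node: str, graph: nx.Graph | None = None
) -> float:
    """Geodesic intermediacy between cross-community pairs.

    For every unordered pair (a, b) with a and b in different communities and
    both distinct from ``node``, the node earns (number of geodesics through
    it) / (number of geodesics), i.e. equal split among tied geodesics.
    """
    _check_partition(model, partition)
    g = graph if graph is not None else to_graph(model)
    comms: dict[str, list[str]] = {}
    for lab in model.labels:
        comms.setdefault(partition[lab], []).append(lab)
    (ca, cb) = sorted(comms)
    total = 0.0
    for a in comms[ca]:
        if a == node:
            continue
        for b in comms[cb]:
            if b == node:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, a, b, weight="length"))
            except nx.NetworkXNoPath:
                continue
            through = sum(1 for p in paths if node in p[1:-1])
            if through:
                total += through / len(paths)
    return total


def bridge_indices(
    model: IsingModel, partition: dict[str, str] | None = None
) -> pd.DataFrame:
    """All four bridge indices for every node, as a DataFrame indexed by node."""
    if partition is None:
        partition = {
            lab: ("MD" if lab.startswith("MD") else "CF") for lab in model.labels
        }
    _check_partition(model, partition)
    g = to_graph(model)
    rows = {}
    for lab in model.labels:
        rows[lab] = {
            "bridge_strength": bridge_strength(model, partition, lab),
            "bridge_expected_influence": bridge_expected_influence(model, partition, lab),
            "bridge_closeness": bridge_closeness(model, partition, lab, g),
            "bridge_betweenness": bridge_betweenness(model, partition, lab, g),
        }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[list(model.labels)]
    df.index.name = "node"
    return df


def rank_bridge_nodes(indices: pd.DataFrame, by: str = "bridge_strength") -> list[str]:
    """Nodes in descending order of the chosen index; ties break by label."""
    if by not in indices.columns:
        raise ValueError(f"unknown index {by!r}; available: {list(indices.columns)}")
    order = sorted(indices.index, key=lambda lab: (-indices.loc[lab, by], lab))
    return order
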