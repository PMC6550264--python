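"""The weighted, undirected patient-sharing network over providers.

Each fragmented transition between providers A and B — in either direction —
adds one to the weight F_AB of the unordered pair {A, B}.  F_AB therefore
counts the occasions on which the most recent record of a patient's care was
held at one of the two providers when the patient attended the other, which
is precisely the data-sharing demand between them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


@dataclass
class PatientSharingNetwork:
    """Undirected weighted graph: provider nodes, F_AB edge weights.

    Weights are stored once per unordered pair under a sorted 2-tuple key;
    no self-pairs; stored weights are >= 1.  Nodes with no fragmented
    transitions are legitimate isolated members of the graph.
    """

    nodes: set[str] = field(default_factory=set)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        return sum(self.weights.values())

    def weight(self, a: str, b: str) -> float:
        return self.weights.get((a, b) if a <= b else (b, a), 0.0)

    def degree(self) -> dict[str, float]:
        """Weighted degree (strength) of every node, isolated nodes at 0."""
        k = {v: 0.0 for v in self.nodes}
        for (a, b), w in self.weights.items():
            k[a] += w
            k[b] += w
        return k

    def neighbors(self) -> dict[str, dict[str, float]]:
        """Adjacency as nested dicts (symmetric, no self entries)."""
        adj: dict[str, dict[str, float]] = {v: {} for v in self.nodes}
        for (a, b), w in self.weights.items():
            adj[a][b] = w
            adj[b][a] = w
        return adj


def build_network(transitions: pd.DataFrame,
                  node_universe: Iterable[str] | None = None) -> PatientSharingNetwork:
    """Tally fragmented transitions into the patient-sharing network.

    Each fragmented transition increments exactly one unordered provider pair
    by one; non-fragmented transitions are ignored.  ``node_universe``
    optionally supplies providers that should appear as (possibly isolated)
    nodes even if they never share a patient.
    """
    net = PatientSharingNetwork()
    if node_universe is not None:
        net.nodes.update(str(v) for v in node_universe)
    if len(transitions):
        frag = transitions[transitions["fragmented"]]
        for a, b in zip(frag["from_provider"], frag["to_provider"]):
            key = (a, b) if a <= b else (b, a)
            net.weights[key] = net.weights.get(key, 0.0) + 1.0
            net.nodes.add(a)
            net.nodes.add(b)
    return net


def network_summary(net: PatientSharingNetwork,
                    weight_thresholds: Iterable[float] = ()) -> dict:
    """Size, density and weight-distribution summary of the network.

    Density is the share of the n(n-1)/2 possible provider pairs actually
    connected, as a percentage (None when fewer than two nodes).  For every
    caller-given threshold t the count and share of edges with weight
    strictly above t is included.
    """
    n = net.n_nodes
    n_possible = n * (n - 1) // 2
    density = 100.0 * net.n_edges / n_possible if n_possible else None
    summary = {
        "n_nodes": n,
        "n_edges": net.n_edges,
        "n_possible": n_possible,
        "density_pct": density,
        "total_weight": net.total_weight,
        "thresholds": {},
    }
    for t in weight_thresholds:
        above = sum(1 for w in net.weights.values() if w > t)
        summary["thresholds"][t] = {
            "n_edges_above": above,
            "pct_of_edges": 100.0 * above / net.n_edges if net.n_edges else 0.0,
        }
    return summary


def threshold_network(net: PatientSharingNetwork,
                      min_weight: float) -> PatientSharingNetwork:
    """Keep only edges with weight strictly above ``min_weight``.

    The node set is unchanged, so thresholding affects edges and density but
    never drops providers.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    return PatientSharingNetwork(
        nodes=set(net.nodes),
        weights={k: w for k, w in net.weights.items() if w > min_weight},
    )


# ---------------------------------------------------------------------------
# interop and persistence

def write_edge_list(net: PatientSharingNetwork, path: str | os.PathLike) -> None:
    """Weighted edge-list TSV: pair sorted within a row, rows sorted."""
    with open(path, "w") as fh:
        fh.write("provider_a\tprovider_b\tweight\n")
        for (a, b) in sorted(net.weights):
            w = net.weights[(a, b)]
            fh.write(f"{a}\t{b}\t{w:g}\n")


def read_edge_list(path: str | os.PathLike,
                   node_universe: Iterable[str] | None = None) -> PatientSharingNetwork:
    """Read the edge-list TSV dialect back into a network."""
    df = pd.read_csv(path, sep="\t", dtype={"provider_a": str, "provider_b": str})
    net = PatientSharingNetwork()
    if node_universe is not None:
        net.nodes.update(str(v) for v in node_universe)
    for a, b, w in zip(df["provider_a"], df["provider_b"], df["weight"]):
        if a == b:
            raise ValueError(f"self-pair {a!r} not allowed")
        key = (a, b) if a <= b else (b, a)
        net.weights[key] = net.weights.get(key, 0.0) + float(w)
        net.nodes.update((a, b))
    return net


def to_networkx(net: PatientSharingNetwork):
    """Export as a :class:`networkx.Graph` with a ``weight`` edge attribute."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_weighted_edges_from((a, b, w) for (a, b), w in sorted(net.weights.items()))
    return g


def write_graphml(net: PatientSharingNetwork, path: str | os.PathLike) -> None:
    """Write GraphML with the ``weight`` edge attribute."""
    import networkx as nx

    nx.write_graphml(to_networkx(net), path)


def from_mapping(weights: Mapping[tuple[str, str], float],
                 nodes: Iterable[str] = ()) -> PatientSharingNetwork:
    """Build a network directly from an unordered-pair weight mapping."""
    net = PatientSharingNetwork(nodes=set(nodes))
    for (a, b), w in weights.items():
        if a == b:
            raise ValueError(f"self-pair {a!r} not allowed")
        if w <= 0:
            raise ValueError("edge weights must be positive")
        key = (a, b) if a <= b else (b, a)
        net.weights[key] = net.weights.get(key, 0.0) + float(w)
        net.nodes.update((a, b))
    return net
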