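"""Typed gene-interaction networks and degree-based hub detection.

Edges carry an interaction type (enzyme-enzyme relation, protein-protein
interaction, gene-expression interaction, or literature co-citation) and a
polarity (association / inhibition / activation).  The graph is undirected
and simple: parallel edges from different sources merge into a single edge
annotated with the set of types.  Hub genes are flagged by standardizing a
node's degree against the empirical degree distribution and taking the
one-sided upper-tail normal probability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeRecord",
    "HubResult",
    "INTERACTION_TYPES",
    "POLARITIES",
    "build_network",
    "connectivity",
    "hub_test",
    "export_graph",
    "read_graph",
]

INTERACTION_TYPES = frozenset(
    {"enzyme_enzyme", "protein_protein", "gene_expression", "cocitation"}
)
POLARITIES = frozenset({"association", "inhibition", "activation"})


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    interaction_type: str
    polarity: str = "association"

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(
                f"unknown interaction type {self.interaction_type!r}; "
                f"expected one of {sorted(INTERACTION_TYPES)}"
            )
        if self.polarity not in POLARITIES:
            raise ValueError(
                f"unknown polarity {self.polarity!r}; expected one of {sorted(POLARITIES)}"
            )


@dataclass(frozen=True)
class HubResult:
    node: str
    degree: int
    z: float
    p: float
    degenerate: bool = False


def build_network(edges: Iterable[EdgeRecord]) -> nx.Graph:
    """Merge typed edge records into an undirected simple graph.

    Self-loops are dropped with a warning.  Parallel edges (same endpoints,
    any direction) are merged; the surviving edge carries the union of
    interaction types and polarities as sorted tuples in its attributes.
    """
    graph = nx.Graph()
    for rec in edges:
        u, v = rec.source.strip().upper(), rec.target.strip().upper()
        if u == v:
            logger.warning("dropping self-loop on %s", u)
            continue
        if graph.has_edge(u, v):
            data = graph.edges[u, v]
            data["types"] = tuple(sorted(set(data["types"]) | {rec.interaction_type}))
            data["polarities"] = tuple(sorted(set(data["polarities"]) | {rec.polarity}))
        else:
            graph.add_edge(u, v, types=(rec.interaction_type,), polarities=(rec.polarity,))
    return graph


def connectivity(graph: nx.Graph) -> dict[str, int]:
    """Degree (connectivity) of every node in the merged simple graph."""
    return {node: int(deg) for node, deg in graph.degree()}


def hub_test(degrees: Mapping[str, int]) -> list[HubResult]:
    """Standardize each node's degree against the empirical distribution.

    z_i = (k_i - mean) / sample SD (ddof=1); p_i = 1 - Phi(z_i), one-sided
    upper tail.  A regular graph (zero degree variance) is degenerate:
    every z is defined as 0 and every p as 0.5, with the flag set.
    Results are sorted by ascending p, ties by descending degree then node.
    """
    if len(degrees) < 2:
        raise ValueError("hub test needs at least 2 nodes")
    ks = list(degrees.values())
    mean = sum(ks) / len(ks)
    var = sum((k - mean) ** 2 for k in ks) / (len(ks) - 1)
    sd = math.sqrt(var)
    out = []
    for node, k in degrees.items():
        if sd == 0:
            out.append(HubResult(node=node, degree=int(k), z=0.0, p=0.5, degenerate=True))
        else:
            z = (k - mean) / sd
            out.append(HubResult(node=node, degree=int(k), z=z, p=float(norm.sf(z))))
    out.sort(key=lambda h: (h.p, -h.degree, h.node))
    return out


def export_graph(graph: nx.Graph, path: str | Path) -> None:
    """Write GraphML with type/polarity attributes (joined with ``|``).

    GraphML attributes must be scalars, so the tuple-valued ``types`` and
    ``polarities`` are serialized as sorted pipe-joined strings; the reader
    reverses the encoding, making the round trip lossless.
    """
    encoded = nx.Graph()
    encoded.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        encoded.add_edge(u, v,
                         types="|".join(sorted(data.get("types", ()))),
                         polarities="|".join(sorted(data.get("polarities", ()))))
    nx.write_graphml(encoded, str(path))


def read_graph(path: str | Path) -> nx.Graph:
    """Read a GraphML file written by :func:`export_graph`."""
    raw = nx.read_graphml(str(path))
    graph = nx.Graph()
    graph.add_nodes_from(raw.nodes)
    for u, v, data in raw.edges(data=True):
        graph.add_edge(
            u, v,
            types=tuple(t for t in data.get("types", "").split("|") if t),
            polarities=tuple(t for t in data.get("polarities", "").split("|") if t),
        )
    return graph
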