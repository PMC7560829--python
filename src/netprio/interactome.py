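"""Protein–protein interaction networks and their random-walk transition operator.

An :class:`Interactome` is an undirected, optionally weighted gene graph.
All propagation code in this package works on its column-stochastic
transition matrix W, where column u distributes the walker's mass from
gene u to its neighbours proportionally to edge weight:

    W[v, u] = weight(u, v) / weighted_degree(u)

Edge lists are plain TSV (gene_a, gene_b, optional positive weight), with
``#``-prefixed comment lines allowed, the common interchange dialect for
interactomes such as InWeb_IM, Reactome and HINT+HI.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "load_edgelist",
    "save_edgelist",
    "largest_connected_component",
    "transition_matrix",
    "write_graphml",
]


class Interactome:
    """Undirected weighted gene network.

    Wraps a :class:`networkx.Graph` whose nodes are gene symbols (kept
    verbatim, case-sensitive) and whose edges carry a positive ``weight``
    attribute (default 1.0). Self-loops are forbidden; constructing from a
    graph containing any raises :class:`ValidationError`.
    """

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges):
            raise ValidationError("interactome must not contain self-loops")
        for u, v, w in graph.edges(data="weight", default=1.0):
            if not (w > 0):
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) has non-positive weight {w!r}"
                )
        self._graph = graph

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "Interactome":
        """Build a network from (u, v[, weight]) tuples.

        Duplicate edges (in either orientation) collapse to one edge with
        the last weight winning; self-loops are dropped (their endpoints
        are kept as nodes).
        """
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_loops = 0
        for edge in edges:
            u, v = edge[0], edge[1]
            w = float(edge[2]) if len(edge) > 2 else 1.0
            if w <= 0:
                raise ValidationError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            g.add_edge(u, v, weight=w)
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        return cls(g)

    # -- basic queries -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> list[str]:
        """Node symbols in sorted order (the canonical matrix ordering)."""
        return sorted(self._graph.nodes)

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def __len__(self) -> int:
        return self.n_nodes

    def degree(self, gene: str) -> int:
        return self._graph.degree[gene]

    def neighbors(self, gene: str) -> list[str]:
        return sorted(self._graph[gene])

    def edge_weight(self, u: str, v: str) -> float:
        return self._graph.edges[u, v].get("weight", 1.0)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (u, v, weight) with u < v, sorted — deterministic."""
        out = []
        for u, v, w in self._graph.edges(data="weight", default=1.0):
            a, b = (u, v) if u <= v else (v, u)
            out.append((a, b, float(w)))
        return sorted(out)

    def subgraph(self, genes: Iterable[str]) -> "Interactome":
        return Interactome(nx.Graph(self._graph.subgraph(genes)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()


def load_edgelist(path: str | Path, delimiter: str = "\t") -> Interactome:
    """Read an interactome from a delimited edge list.

    Each non-comment, non-blank line must have two or three fields:
    ``gene_a  gene_b  [weight]``. Duplicate edges collapse with the last
    weight winning; self-loops are dropped (logged) but their node kept.

    Raises :class:`ParseError` naming the line number for malformed lines
    and :class:`ValidationError` for non-positive weights.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"{path}:{lineno}: expected 2-3 fields, got {len(fields)}"
                )
            u, v = fields[0].strip(), fields[1].strip()
            if not u or not v:
                raise ParseError(f"{path}:{lineno}: empty gene symbol")
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from exc
            else:
                w = 1.0
            if w <= 0:
                raise ValidationError(
                    f"{path}:{lineno}: non-positive weight {w} on edge ({u}, {v})"
                )
            edges.append((u, v, w))
    return Interactome.from_edges(edges)


def save_edgelist(net: Interactome, path: str | Path, delimiter: str = "\t") -> None:
    """Write the network in the same TSV dialect :func:`load_edgelist` reads."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# gene_a\tgene_b\tweight\n")
        for u, v, w in net.edges():
            fh.write(f"{u}{delimiter}{v}{delimiter}{w:g}\n")
        # isolated nodes round-trip as self-loops, which the loader drops
        # while retaining the endpoint as a node
        for gene in net.nodes:
            if net.degree(gene) == 0:
                fh.write(f"{gene}{delimiter}{gene}\n")


def largest_connected_component(net: Interactome) -> Interactome:
    """Induced subgraph of the largest connected component.

    Ties between equally sized components are broken in favour of the one
    containing the lexicographically smallest gene symbol. Propagation
    probabilities are only meaningful on a connected graph, so pipelines
    apply this before building the transition operator.
    """
    if net.n_nodes == 0:
        raise ValidationError("cannot take the largest component of an empty network")
    components = [sorted(c) for c in nx.connected_components(net.graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return net.subgraph(components[0])


def transition_matrix(net: Interactome) -> tuple[sp.csr_matrix, list[str]]:
    """Column-stochastic random-walk operator W and its node ordering.

    ``W[v, u] = weight(u, v) / weighted_degree(u)``, so each column sums
    to one and ``W @ p`` advances a probability vector by one walk step.

    Raises :class:`ValidationError` if any node has zero degree; take the
    largest connected component first.
    """
    nodes = net.nodes
    if not nodes:
        raise ValidationError("empty network has no transition matrix")
    adj = nx.to_scipy_sparse_array(
        net.graph, nodelist=nodes, weight="weight", format="csr"
    ).astype(float)
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    if np.any(col_sums == 0):
        bad = [nodes[i] for i in np.flatnonzero(col_sums == 0)[:5]]
        raise ValidationError(
            f"zero-degree node(s) {bad}; take the largest connected component first"
        )
    # adjacency is symmetric, so scaling columns by 1/degree gives W[v,u]=w(u,v)/deg(u)
    w = adj @ sp.diags(1.0 / col_sums)
    return sp.csr_matrix(w), nodes


def write_graphml(net: Interactome, path: str | Path) -> None:
    """Export to GraphML for Cytoscape/Gephi-style visualization tools."""
    nx.write_graphml(net.graph, str(path))
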