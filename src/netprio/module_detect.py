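"""Hot-subnetwork detection and first-neighbor module extraction.

The hot-subnetwork procedure follows the hierarchical heat-diffusion
recipe used for finding gene clusters that are simultaneously highly
mutated and topologically close:

1. a random-walk similarity matrix ``F = r (I - (1-r) W)^{-1}`` whose
   column u is exactly the restart-walk distribution seeded at u alone;
2. an "exchanged heat" digraph with edge u -> v of weight
   ``F[v, u] * score(u)`` — heat produced at u according to its mutation
   score and delivered to v along the diffusion kernel;
3. a threshold sweep: for each delta (descending over edge weights) keep
   edges with weight >= delta and record the strongly connected
   components. As delta decreases, components can only merge, giving a
   nested hierarchy of clusters;
4. significance by score permutation: score values are shuffled uniformly
   across the scored vertices, the largest-component-size curve is
   recomputed per shuffle, delta* is chosen to maximize the observed
   excess over the mean null curve, and the p-value uses the add-one
   permutation estimator at delta*.

Vertex scores are patient carrier fractions for candidate genes and a
fixed constant for seed genes (default: the maximum candidate fraction,
keeping seeds hot without letting them dominate).

Separately, :func:`first_neighbor_module` extracts the direct-interaction
neighborhood of the seed genes, the standard view for asking which
candidates touch known high-risk genes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .exceptions import NetprioError, ValidationError
from .interactome import Interactome, transition_matrix
from .propagation import DEFAULT_RESTART, SeedSet
from .variant_filter import CandidateGene

__all__ = [
    "VertexScores",
    "ModuleHierarchy",
    "ModuleSignificance",
    "FirstNeighborModule",
    "vertex_scores",
    "similarity_matrix",
    "hot_graph",
    "component_hierarchy",
    "significance",
    "consensus_module_genes",
    "first_neighbor_module",
    "count_seed_candidate_interactions",
    "write_clusters_tsv",
    "write_first_neighbor_tsv",
]


def vertex_scores(
    candidates: Sequence[CandidateGene],
    seeds: SeedSet | Iterable[str],
    seed_score: Optional[float] = None,
) -> dict[str, float]:
    """Mutation scores: carrier fraction for candidates, a constant for seeds.

    ``seed_score`` defaults to the maximum candidate carrier fraction so
    that known disease genes are as hot as the hottest candidate.
    """
    scores = {c.gene: c.patient_carrier_fraction for c in candidates}
    if seed_score is None:
        seed_score = max(scores.values()) if scores else 1.0
    if seed_score < 0:
        raise ValidationError("seed_score must be non-negative")
    seed_genes = seeds.genes if isinstance(seeds, SeedSet) else tuple(seeds)
    for g in seed_genes:
        scores[g] = float(seed_score)
    if not any(v > 0 for v in scores.values()):
        raise ValidationError("vertex scores must contain at least one positive value")
    return scores


def similarity_matrix(
    net: Interactome, restart: float = DEFAULT_RESTART
) -> tuple[np.ndarray, list[str]]:
    """Dense diffusion kernel ``F = r (I - (1-r) W)^{-1}`` and node order.

    Column u equals the restart-walk distribution with u as the only
    seed; every column sums to one. Dense inversion is intended for
    networks up to a few thousand nodes.
    """
    if not (0.0 < restart <= 1.0):
        raise ValidationError(f"restart must lie in (0, 1], got {restart}")
    w, nodes = transition_matrix(net)
    n = len(nodes)
    a = np.eye(n) - (1.0 - restart) * w.toarray()
    try:
        f = restart * np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - r>0 keeps A invertible
        raise NetprioError(f"similarity system is singular: {exc}") from exc
    return f, nodes


def hot_graph(
    f: np.ndarray, nodes: Sequence[str], scores: Mapping[str, float]
) -> nx.DiGraph:
    """Exchanged-heat digraph: u -> v weighted ``F[v, u] * score(u)``.

    Genes without a score contribute no heat (score 0); self-edges and
    zero-weight edges are omitted. Score keys must be network genes.
    """
    unknown = set(scores) - set(nodes)
    if unknown:
        raise ValidationError(f"scored genes absent from the kernel: {sorted(unknown)[:5]}")
    index = {g: i for i, g in enumerate(nodes)}
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, score in scores.items():
        if score <= 0:
            continue
        col = f[:, index[u]] * score
        for vi, w in enumerate(col):
            if w > 0 and nodes[vi] != u:
                g.add_edge(u, nodes[vi], weight=float(w))
    return g


@dataclass
class ModuleHierarchy:
    """Nested strongly-connected-component clusters over a delta sweep."""

    thresholds: list[float]  # descending
    components: list[list[frozenset[str]]]  # per threshold, size >= 2 only

    def at(self, delta: float) -> list[frozenset[str]]:
        """Components at the smallest recorded threshold >= delta."""
        chosen: list[frozenset[str]] = []
        for t, comps in zip(self.thresholds, self.components):
            if t >= delta:
                chosen = comps
            else:
                break
        return chosen


def _scc_sets(graph: nx.DiGraph) -> list[frozenset[str]]:
    return [
        frozenset(c)
        for c in nx.strongly_connected_components(graph)
        if len(c) >= 2
    ]


def _check_nesting(
    finer: list[frozenset[str]], coarser: list[frozenset[str]]
) -> None:
    """Every component at the larger delta must sit inside one at the smaller."""
    owner: dict[str, int] = {}
    for i, comp in enumerate(coarser):
        for g in comp:
            owner[g] = i
    for comp in finer:
        owners = {owner.get(g, -1) for g in comp}
        if len(owners) != 1 or -1 in owners:
            raise AssertionError(
                "hierarchy nesting violated: component split as delta decreased"
            )


def component_hierarchy(hot: nx.DiGraph) -> ModuleHierarchy:
    """Sweep delta over distinct edge weights (descending) and collect SCCs.

    Only components of size >= 2 are recorded. The nesting property —
    components merge but never split as delta decreases — is asserted at
    every step; a violation indicates an implementation bug.
    """
    weights = sorted({d["weight"] for _, _, d in hot.edges(data=True)}, reverse=True)
    thresholds: list[float] = []
    levels: list[list[frozenset[str]]] = []
    prev: Optional[list[frozenset[str]]] = None
    for delta in weights:
        sub = nx.DiGraph()
        sub.add_nodes_from(hot.nodes)
        sub.add_edges_from(
            (u, v) for u, v, d in hot.edges(data=True) if d["weight"] >= delta
        )
        comps = _scc_sets(sub)
        if prev is not None:
            _check_nesting(prev, comps)
        thresholds.append(float(delta))
        levels.append(comps)
        prev = comps
    return ModuleHierarchy(thresholds=thresholds, components=levels)


@dataclass
class ModuleSignificance:
    selected_delta: float
    clusters: list[frozenset[str]]
    p_value: float
    n_perm: int
    thresholds: list[float] = field(default_factory=list)
    observed_sizes: list[int] = field(default_factory=list)
    null_mean_sizes: list[float] = field(default_factory=list)


def _largest_scc_curve(h: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Largest SCC size of the graph {edges with weight >= delta}, per delta."""
    out = np.empty(len(thresholds), dtype=int)
    for i, delta in enumerate(thresholds):
        mask = sp.csr_matrix(h >= delta)
        _, labels = connected_components(mask, directed=True, connection="strong")
        out[i] = int(np.bincount(labels).max())
    return out


def significance(
    net: Interactome,
    scores: Mapping[str, float],
    restart: float = DEFAULT_RESTART,
    n_perm: int = 100,
    rng_seed: int = 0,
    n_thresholds: int = 40,
) -> ModuleSignificance:
    """Score-permutation test for hot clusters.

    The null shuffles the score values uniformly across the scored
    vertices (network topology fixed). The test statistic is the largest
    strongly-connected-component size as a function of delta, evaluated
    on a log-uniform grid spanning the observed positive edge weights;
    ``selected_delta`` maximizes the observed excess over the mean null
    curve and fixes the resolution at which ``clusters`` are reported.
    The p-value is the add-one permutation estimator on the *studentized*
    maximal excess (per-delta excess scaled by its null spread), referred
    to each permutation's own maximum — a max-T correction that keeps the
    test calibrated despite the sweep over delta.
    """
    if n_perm < 19:
        raise ValidationError("n_perm must be >= 19 for a meaningful p-value")
    scored = [g for g, v in scores.items() if v > 0]
    if len(scored) < 2:
        raise ValidationError("need at least 2 scored vertices")
    f, nodes = similarity_matrix(net, restart)
    index = {g: i for i, g in enumerate(nodes)}
    s = np.zeros(len(nodes))
    for g, v in scores.items():
        if v < 0:
            raise ValidationError(f"negative score for {g}")
        s[index[g]] = v
    h_base = f.copy()
    np.fill_diagonal(h_base, 0.0)
    h_obs = h_base * s[np.newaxis, :]

    pos = h_obs[h_obs > 0]
    # heat weights span orders of magnitude (diffusion decays geometrically
    # with distance), so the sweep uses a log-uniform grid between the
    # smallest and largest positive weight
    thresholds = np.unique(
        np.geomspace(pos.min(), pos.max(), min(n_thresholds, pos.size))
    )[::-1]
    obs = _largest_scc_curve(h_obs, thresholds)

    rng = np.random.default_rng(rng_seed)
    scored_idx = np.array([index[g] for g in sorted(scored)])
    null = np.empty((n_perm, len(thresholds)), dtype=int)
    for k in range(n_perm):
        s_perm = s.copy()
        s_perm[scored_idx] = s[scored_idx][rng.permutation(len(scored_idx))]
        null[k] = _largest_scc_curve(h_base * s_perm[np.newaxis, :], thresholds)

    null_mean = null.mean(axis=0)
    # studentized max-T: excess largest-component size per delta is scaled
    # by its null spread (+1 component to bound the denominator away from
    # zero where the null is degenerate), the observed maximum over the
    # sweep is referred to each permutation's own maximum, keeping the
    # test calibrated despite the selection of delta* and insensitive to
    # the high-variance percolation regime at small delta
    denom = null.std(axis=0) + 1.0
    z = (obs - null_mean) / denom
    t_null = ((null - null_mean[np.newaxis, :]) / denom[np.newaxis, :]).max(axis=1)
    p_value = (1 + int(np.sum(t_null >= z.max()))) / (1 + n_perm)
    # the reporting resolution delta* maximizes the plain excess component
    # size, which lands in the regime where the hot cluster is fully
    # assembled rather than at its sharpest (smallest) core
    best = int(np.argmax(obs - null_mean))  # ties resolve to the largest delta
    delta_star = float(thresholds[best])

    mask = sp.csr_matrix(h_obs >= delta_star)
    _, labels = connected_components(mask, directed=True, connection="strong")
    clusters = []
    for lab in np.unique(labels):
        members = [nodes[i] for i in np.flatnonzero(labels == lab)]
        if len(members) >= 2:
            clusters.append(frozenset(members))
    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    return ModuleSignificance(
        selected_delta=delta_star,
        clusters=clusters,
        p_value=float(p_value),
        n_perm=n_perm,
        thresholds=[float(t) for t in thresholds],
        observed_sizes=[int(x) for x in obs],
        null_mean_sizes=[float(x) for x in null.mean(axis=0)],
    )


def consensus_module_genes(
    per_network_significance: Mapping[str, ModuleSignificance],
    min_networks: int = 2,
    alpha: float = 0.05,
) -> set[str]:
    """Genes in a significant cluster in at least ``min_networks`` networks."""
    counts: dict[str, int] = {}
    for sig in per_network_significance.values():
        if sig.p_value > alpha:
            continue
        seen = set().union(*sig.clusters) if sig.clusters else set()
        for g in seen:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_networks}


# -- first-neighbor module ---------------------------------------------


@dataclass
class FirstNeighborModule:
    """Direct seed-gene interactions with other seeds or candidates.

    ``pairs`` holds (seed, partner, candidate_flag) triples; every pair is
    an edge of the source interactome and the first member is a seed.
    """

    pairs: list[tuple[str, str, bool]]

    def flagged(self) -> list[tuple[str, str]]:
        return [(s, p) for s, p, flag in self.pairs if flag]


def first_neighbor_module(
    net: Interactome,
    seeds: SeedSet | Iterable[str],
    candidates: Iterable[str],
) -> FirstNeighborModule:
    """All (seed, neighbor) pairs where the neighbor is a seed or candidate.

    ``candidate_flag`` marks partners in ``candidates``. A partner that
    is both seed and candidate is flagged; seed-seed edges appear in both
    orientations (once per seed row).
    """
    seed_genes = seeds.genes if isinstance(seeds, SeedSet) else tuple(seeds)
    seed_set = set(seed_genes)
    cand_set = set(candidates)
    pairs: list[tuple[str, str, bool]] = []
    for seed in sorted(seed_set):
        if seed not in net:
            continue
        for nbr in net.neighbors(seed):
            if nbr in seed_set or nbr in cand_set:
                pairs.append((seed, nbr, nbr in cand_set))
    return FirstNeighborModule(pairs=pairs)


def count_seed_candidate_interactions(module: FirstNeighborModule) -> int:
    """Number of candidate-flagged pairs; a partner seen under two seeds counts twice."""
    return sum(1 for _, _, flag in module.pairs if flag)


# -- output -------------------------------------------------------------


def write_clusters_tsv(sig: ModuleSignificance, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cluster_id", "size", "genes"])
        for i, cluster in enumerate(sig.clusters, start=1):
            writer.writerow([i, len(cluster), ",".join(sorted(cluster))])


def write_first_neighbor_tsv(module: FirstNeighborModule, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["seed", "partner", "candidate_flag"])
        for seed, partner, flag in module.pairs:
            writer.writerow([seed, partner, int(flag)])
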