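"""Random walk with restart, degree-aware adjustment, and candidate ranking.

The walker iterates the fixed-point map

    p_{t+1} = (1 - r) * W @ p_t + r * s

where W is the column-stochastic transition operator of the interactome,
``r`` is the restart probability and ``s`` is the restart distribution,
uniform over the seed genes. The stationary ``p`` measures network
proximity to the seeds; it exists and is unique for r in (0, 1] because
the map is a contraction with factor (1 - r) in L1.

Raw visitation probabilities are biased toward hub genes. The
degree-aware adjustment compares them with a *reference* walk restarted
uniformly at every node — which captures the purely topological,
seed-independent visitation profile — and scores each gene by the
log-likelihood ratio

    score(v) = log( p(v) / p_ref(v) ).

Candidates are ranked by descending adjusted score; seeds are never
ranked as candidates.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .exceptions import ConvergenceError, ValidationError
from .interactome import Interactome, transition_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "PropagationResult",
    "LeaveOneOutResult",
    "DEFAULT_RESTART",
    "rwr",
    "reference_distribution",
    "degree_adjusted_scores",
    "rank_candidates",
    "prioritize",
    "leave_one_out_control",
    "load_seeds",
    "save_seeds",
]

#: default restart probability, the conventional choice for PPI-based
#: gene prioritization; exposed everywhere as configuration
DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000

SEED_CATEGORIES = frozenset(
    {"high", "intermediate", "low", "driver", "low_and_high", "unknown"}
)


@dataclass(frozen=True)
class SeedSet:
    """Curated disease genes used as restart points, with risk categories."""

    genes: tuple[str, ...]
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise ValidationError("seed set must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise ValidationError(f"duplicate seed genes: {dupes}")
        for gene, cat in self.categories.items():
            if cat not in SEED_CATEGORIES:
                raise ValidationError(f"unknown risk category {cat!r} for {gene}")
        object.__setattr__(self, "categories", dict(self.categories))

    @classmethod
    def from_genes(
        cls, genes: Iterable[str], category: str = "unknown"
    ) -> "SeedSet":
        genes = tuple(genes)
        return cls(genes=genes, categories={g: category for g in genes})

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def drop(self, gene: str) -> "SeedSet":
        if gene not in self:
            raise ValidationError(f"{gene} is not a seed")
        return SeedSet(
            genes=tuple(g for g in self.genes if g != gene),
            categories={g: c for g, c in self.categories.items() if g != gene},
        )


@dataclass(frozen=True)
class LeaveOneOutResult:
    heldout: str
    rank: int
    n_ranked: int


@dataclass
class PropagationResult:
    """Converged walk, reference walk, adjusted scores and candidate ranks."""

    probabilities: dict[str, float]
    reference: dict[str, float]
    adjusted_score: dict[str, float]
    candidate_ranks: list[tuple[str, int]]
    unrankable: frozenset[str]
    restart: float
    iterations_used: int

    def rank_of(self, gene: str) -> Optional[int]:
        for g, r in self.candidate_ranks:
            if g == gene:
                return r
        return None


def _as_gene_list(seeds: SeedSet | Iterable[str]) -> list[str]:
    return list(seeds.genes) if isinstance(seeds, SeedSet) else list(seeds)


def _power_iteration(
    w, s: np.ndarray, restart: float, tol: float, max_iter: int
) -> tuple[np.ndarray, int]:
    """Iterate p <- (1-r) W p + r s columnwise until max L1 change < tol."""
    p = s.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - restart) * (w @ p) + restart * s
        residual = np.abs(p_next - p).sum(axis=0).max()
        p = p_next
        if residual < tol:
            return p, it
    raise ConvergenceError(
        f"random walk did not converge in {max_iter} iterations "
        f"(last L1 residual {residual:.3e})",
        residual=float(residual),
    )


def _restart_vector(nodes: Sequence[str], seeds: Sequence[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(nodes)}
    s = np.zeros(len(nodes))
    for g in seeds:
        s[index[g]] = 1.0
    s /= s.sum()
    return s


def _retained_seeds(net: Interactome, seeds: Iterable[str]) -> list[str]:
    seeds = list(dict.fromkeys(seeds))
    retained = [g for g in seeds if g in net]
    dropped = sorted(set(seeds) - set(retained))
    if dropped:
        logger.warning(
            "%d seed(s) absent from the network and dropped: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    if not retained:
        raise ValidationError("no seed gene overlaps the network")
    return retained


def _check_walk_params(restart: float, tol: float) -> None:
    if not (0.0 < restart <= 1.0):
        raise ValidationError(f"restart must lie in (0, 1], got {restart}")
    if not tol > 0:
        raise ValidationError("tol must be positive")


def rwr(
    net: Interactome,
    seeds: SeedSet | Iterable[str],
    restart: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> dict[str, float]:
    """Converged visitation probabilities of a restart walk from ``seeds``.

    The restart vector is uniform over the seeds retained in the network
    (absent seeds are dropped with a warning). Returns a gene -> probability
    map summing to one.
    """
    _check_walk_params(restart, tol)
    retained = _retained_seeds(net, _as_gene_list(seeds))
    w, nodes = transition_matrix(net)
    s = _restart_vector(nodes, retained)
    p, _ = _power_iteration(w, s, restart, tol, max_iter)
    return dict(zip(nodes, p.tolist()))


def reference_distribution(
    net: Interactome,
    restart: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> dict[str, float]:
    """Degree-driven baseline: the walk restarted uniformly at every node."""
    _check_walk_params(restart, tol)
    w, nodes = transition_matrix(net)
    s = np.full(len(nodes), 1.0 / len(nodes))
    p, _ = _power_iteration(w, s, restart, tol, max_iter)
    return dict(zip(nodes, p.tolist()))


def degree_adjusted_scores(
    p: Mapping[str, float], p_ref: Mapping[str, float]
) -> dict[str, float]:
    """Log-ratio of seeded versus reference visitation, per gene.

    Positive scores mark genes visited more often than their connectivity
    alone predicts, i.e. genuine proximity to the seeds.
    """
    if set(p) != set(p_ref):
        raise ValidationError("p and p_ref must cover the same genes")
    scores = {}
    for gene, prob in p.items():
        ref = p_ref[gene]
        if ref <= 0:
            raise ValidationError(
                f"reference probability for {gene} is {ref}; cannot form log-ratio"
            )
        scores[gene] = math.log(prob / ref) if prob > 0 else -math.inf
    return scores


def rank_candidates(
    scores: Mapping[str, float],
    candidates: Iterable[str],
    seeds: SeedSet | Iterable[str],
) -> tuple[list[tuple[str, int]], frozenset[str]]:
    """Sort candidates by descending score; ties break lexicographically.

    Seed genes are excluded from the ranking; candidates without a score
    (absent from the network) come back separately as ``unrankable``.
    Returns ``(ranking, unrankable)`` with ranks 1..K, no gaps.
    """
    seed_set = set(_as_gene_list(seeds))
    candidates = set(candidates)
    rankable = sorted(candidates & set(scores) - seed_set)
    unrankable = frozenset(candidates - set(scores))
    ordered = sorted(rankable, key=lambda g: (-scores[g], g))
    return [(g, i + 1) for i, g in enumerate(ordered)], unrankable


def prioritize(
    net: Interactome,
    seeds: SeedSet | Iterable[str],
    candidates: Iterable[str],
    restart: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PropagationResult:
    """Full ranking pipeline: walk, reference walk, adjustment, ranking."""
    _check_walk_params(restart, tol)
    retained = _retained_seeds(net, _as_gene_list(seeds))
    w, nodes = transition_matrix(net)
    s = _restart_vector(nodes, retained)
    p_vec, iters = _power_iteration(w, s, restart, tol, max_iter)
    ref_vec, _ = _power_iteration(
        w, np.full(len(nodes), 1.0 / len(nodes)), restart, tol, max_iter
    )
    p = dict(zip(nodes, p_vec.tolist()))
    p_ref = dict(zip(nodes, ref_vec.tolist()))
    adjusted = degree_adjusted_scores(p, p_ref)
    ranks, unrankable = rank_candidates(adjusted, candidates, retained)
    return PropagationResult(
        probabilities=p,
        reference=p_ref,
        adjusted_score=adjusted,
        candidate_ranks=ranks,
        unrankable=unrankable,
        restart=restart,
        iterations_used=iters,
    )


def leave_one_out_control(
    net: Interactome,
    seeds: SeedSet,
    heldout: str,
    candidates: Iterable[str],
    restart: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LeaveOneOutResult:
    """Positive-control protocol: demote a known seed to candidate status.

    Runs the ranking with ``seeds`` minus ``heldout`` and ``candidates``
    plus ``heldout``; a working prioritizer recovers the held-out disease
    gene near the top.
    """
    if heldout not in seeds:
        raise ValidationError(f"{heldout} is not in the seed set")
    if heldout not in net:
        raise ValidationError(f"{heldout} is not in the network")
    result = prioritize(
        net,
        seeds.drop(heldout),
        set(candidates) | {heldout},
        restart=restart,
        tol=tol,
        max_iter=max_iter,
    )
    rank = result.rank_of(heldout)
    if rank is None:  # pragma: no cover - heldout is in the network by precondition
        raise ValidationError(f"held-out gene {heldout} could not be ranked")
    return LeaveOneOutResult(
        heldout=heldout, rank=rank, n_ranked=len(result.candidate_ranks)
    )


# -- seed list input/output --------------------------------------------


def load_seeds(path: str | Path) -> SeedSet:
    """Read a seed TSV with columns ``gene`` and ``category``."""
    genes: list[str] = []
    categories: dict[str, str] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            genes.append(row["gene"].strip())
            categories[row["gene"].strip()] = row.get("category", "unknown").strip()
    return SeedSet(genes=tuple(genes), categories=categories)


def save_seeds(seeds: SeedSet, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write("gene\tcategory\n")
        for gene in seeds.genes:
            fh.write(f"{gene}\t{seeds.categories.get(gene, 'unknown')}\n")
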