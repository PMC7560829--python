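"""Empirical significance of propagation probabilities via random seed sets.

The null model re-runs the restart walk from many random seed sets of the
same size as the real one. For each candidate gene,

    theta = number of random sets whose walk assigns the gene a strictly
            larger probability than the real seed set does
    p     = theta / n_sets

Ties do not increment theta. Random sets are drawn uniformly without
replacement from the network's nodes: genes outside the network have zero
visitation probability under any seed set and cannot contribute to the
null. Significance is declared at p strictly below alpha (default 0.05).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .exceptions import ValidationError
from .interactome import Interactome, transition_matrix
from .propagation import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    _power_iteration,
)

__all__ = [
    "PermutationResult",
    "sample_seed_sets",
    "empirical_pvalues",
    "significant_genes",
    "write_permutation_tsv",
]


@dataclass
class PermutationResult:
    """Per-gene permutation counts and p-values on the lattice k/n_sets."""

    n_sets: int
    set_size: int
    theta: dict[str, int]
    p_value: dict[str, float]
    rng_seed: Optional[int] = None

    def __post_init__(self):
        for gene, t in self.theta.items():
            if not (0 <= t <= self.n_sets):
                raise ValidationError(f"theta for {gene} outside [0, n_sets]")
            if self.p_value[gene] != t / self.n_sets:
                raise ValidationError(f"p_value for {gene} is not theta/n_sets")


def sample_seed_sets(
    net: Interactome,
    set_size: int,
    n_sets: int,
    rng_seed: int,
    exclude: Iterable[str] = (),
    degree_matched: Optional[Iterable[str]] = None,
    n_degree_bins: int = 10,
) -> list[tuple[str, ...]]:
    """Draw ``n_sets`` random node sets of exactly ``set_size`` genes.

    Sampling is uniform without replacement within a set and independent
    across sets, fully reproducible from ``rng_seed``. ``exclude`` removes
    genes (e.g. the real seeds) from the sampling universe. When
    ``degree_matched`` is a gene list, each draw instead matches that
    list's degree profile bin-by-bin (quantile bins of log-degree), a
    sensitivity analysis for hub-driven nulls.
    """
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    universe = sorted(set(net.nodes) - set(exclude))
    if set_size > len(universe):
        raise ValidationError(
            f"set_size={set_size} exceeds the {len(universe)} available nodes"
        )
    rng = np.random.default_rng(rng_seed)

    if degree_matched is None:
        return [
            tuple(
                sorted(
                    universe[i]
                    for i in rng.choice(len(universe), size=set_size, replace=False)
                )
            )
            for _ in range(n_sets)
        ]

    template = [g for g in degree_matched if g in net]
    if len(template) != set_size:
        raise ValidationError("degree_matched template size must equal set_size")
    degrees = np.array([net.degree(g) for g in universe], dtype=float)
    edges = np.quantile(np.log1p(degrees), np.linspace(0, 1, n_degree_bins + 1))
    edges[-1] += 1e-9
    bin_of = np.digitize(np.log1p(degrees), edges[1:-1])
    by_bin: dict[int, list[str]] = {}
    for gene, b in zip(universe, bin_of):
        by_bin.setdefault(int(b), []).append(gene)
    template_bins = np.digitize(
        np.log1p([net.degree(g) for g in template]), edges[1:-1]
    )
    need: dict[int, int] = {}
    for b in template_bins:
        need[int(b)] = need.get(int(b), 0) + 1
    sets = []
    for _ in range(n_sets):
        picked: list[str] = []
        for b, k in sorted(need.items()):
            pool = by_bin.get(b, [])
            if len(pool) < k:
                raise ValidationError(f"degree bin {b} has only {len(pool)} genes")
            picked.extend(pool[i] for i in rng.choice(len(pool), size=k, replace=False))
        sets.append(tuple(sorted(picked)))
    return sets


def _batched_rwr(
    net: Interactome,
    seed_sets: Sequence[Sequence[str]],
    restart: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[str]]:
    """Stack one restart vector per set and power-iterate them jointly."""
    w, nodes = transition_matrix(net)
    index = {g: i for i, g in enumerate(nodes)}
    s = np.zeros((len(nodes), len(seed_sets)))
    for j, seeds in enumerate(seed_sets):
        idx = [index[g] for g in seeds if g in index]
        if not idx:
            raise ValidationError(f"random set {j} has no overlap with the network")
        s[idx, j] = 1.0 / len(idx)
    p, _ = _power_iteration(w, s, restart, tol, max_iter)
    return p, nodes


def empirical_pvalues(
    net: Interactome,
    true_probs: Mapping[str, float],
    random_sets: Sequence[Sequence[str]],
    restart: float = DEFAULT_RESTART,
    candidates: Optional[Iterable[str]] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    rng_seed: Optional[int] = None,
    tie_eps: float = 1e-9,
) -> PermutationResult:
    """Permutation p-values for candidate genes against random seed sets.

    ``true_probs`` must come from :func:`netprio.propagation.rwr` with the
    real seed set at the same restart value. ``candidates`` defaults to
    every network gene.

    theta counts random sets whose probability exceeds the true one by
    more than ``tie_eps``: exceedance is strict, and probabilities equal
    up to solver precision are ties, which never increment theta.
    """
    if candidates is None:
        genes = [g for g in net.nodes if g in true_probs]
    else:
        genes = sorted(set(candidates) & net.node_set & set(true_probs))
    p_matrix, nodes = _batched_rwr(net, random_sets, restart, tol, max_iter)
    index = {g: i for i, g in enumerate(nodes)}
    n_sets = len(random_sets)
    theta = {}
    pval = {}
    for gene in genes:
        t = int(np.sum(p_matrix[index[gene], :] > true_probs[gene] + tie_eps))
        theta[gene] = t
        pval[gene] = t / n_sets
    set_sizes = {len(s) for s in random_sets}
    return PermutationResult(
        n_sets=n_sets,
        set_size=set_sizes.pop() if len(set_sizes) == 1 else -1,
        theta=theta,
        p_value=pval,
        rng_seed=rng_seed,
    )


def significant_genes(result: PermutationResult, alpha: float = 0.05) -> set[str]:
    """Genes with p strictly below ``alpha``."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    return {g for g, p in result.p_value.items() if p < alpha}


def write_permutation_tsv(
    result: PermutationResult,
    true_probs: Mapping[str, float],
    path: str | Path,
    alpha: float = 0.05,
) -> None:
    """Gene, raw probability, theta, p-value and significance flag."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "probability", "theta", "p_value", "significant"])
        for gene in sorted(result.p_value):
            writer.writerow(
                [
                    gene,
                    f"{true_probs.get(gene, float('nan')):.6e}",
                    result.theta[gene],
                    f"{result.p_value[gene]:.6g}",
                    int(result.p_value[gene] < alpha),
                ]
            )
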