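"""Synthetic benchmark scenarios with known ground truth.

Real familial exome data and the licensed interactomes cannot ship with
the package, so every pipeline stage is exercised on generated stand-ins
that reproduce the *structure* of the study design:

* a connected scale-free interactome (preferential attachment), the
  canonical degree-heterogeneous model of PPI networks;
* a connected "disease module" of seed genes grown by random BFS,
  mimicking the observation that genes underlying similar phenotypes
  cluster in the interactome;
* candidate genes split into seed-proximal true positives (within
  ``hop_radius`` of a seed) and topologically distant decoys (strictly
  farther than ``hop_radius`` from every seed);
* a per-family variant table in which every record carries a designed
  fate — pass all filters, or fail exactly one named filter — so that
  filtering the table recovers exactly the designed candidate genes.

Default scale mirrors a familial sequencing study of modest size:
27 families with 3-5 sequenced cases each (~100 patients), private
mutations (each candidate gene in one family), and a 47-gene-sized seed
list trimmed to the generated network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .exceptions import GenerationError, ValidationError
from .interactome import Interactome, load_edgelist, save_edgelist
from .propagation import SeedSet, load_seeds, save_seeds
from .variant_filter import (
    FilterConfig,
    VariantRecord,
    read_variants_tsv,
    write_variants_tsv,
    filter_variants,
)

__all__ = [
    "ScenarioParams",
    "SyntheticScenario",
    "FATES",
    "generate_network",
    "plant_seeds_and_candidates",
    "generate_variant_table",
    "generate_scenario",
    "write_scenario",
    "read_scenario",
    "roc_auc",
]

#: designed fates for variant records
FATES = (
    "pass",
    "fail_population",
    "fail_inhouse",
    "fail_cosegregation",
    "fail_consequence",
    "fail_blacklist",
    "fail_deleteriousness",
    "fail_qc",
)

#: default mix of failing background records, a realistic attrition shape
#: (population frequency and consequence class remove the most variants)
DEFAULT_NOISE_DESIGN: dict[str, int] = {
    "fail_population": 40,
    "fail_inhouse": 10,
    "fail_cosegregation": 30,
    "fail_consequence": 60,
    "fail_blacklist": 5,
    "fail_deleteriousness": 35,
    "fail_qc": 20,
}


@dataclass(frozen=True)
class ScenarioParams:
    """Generator configuration; defaults define the benchmark conditions."""

    n_nodes: int = 1000
    attachment: int = 2
    n_seeds: int = 20
    n_true: int = 15
    n_decoys: int = 50
    hop_radius: int = 2
    n_families: int = 27
    min_cases: int = 3
    max_cases: int = 5
    noise_design: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_DESIGN)
    )


@dataclass
class SyntheticScenario:
    network: Interactome
    seeds: SeedSet
    true_candidates: frozenset[str]
    decoy_candidates: frozenset[str]
    variant_table: list[VariantRecord]
    blacklist: frozenset[str]
    total_cases: int
    rng_seed: int
    params: ScenarioParams

    @property
    def candidate_genes(self) -> frozenset[str]:
        return self.true_candidates | self.decoy_candidates


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(
    n_nodes: int, attachment: int, rng_seed: int
) -> Interactome:
    """Connected scale-free interactome by preferential attachment.

    Node labels are synthetic gene symbols G0000..; the same ``rng_seed``
    reproduces the identical edge set.
    """
    if not (n_nodes > attachment >= 1):
        raise ValidationError(
            f"need n_nodes > attachment >= 1, got {n_nodes}, {attachment}"
        )
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(rng_seed))
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})
    return Interactome.from_edges((u, v, 1.0) for u, v in g.edges)


def plant_seeds_and_candidates(
    net: Interactome,
    n_seeds: int,
    n_true: int,
    n_decoys: int,
    hop_radius: int,
    rng_seed: int,
) -> tuple[SeedSet, frozenset[str], frozenset[str]]:
    """Plant a connected seed module plus proximal/distant candidate labels.

    Seeds grow by random BFS from a random start node, so they form a
    connected subgraph. True candidates are sampled from non-seed nodes
    within ``hop_radius`` of a seed; decoys from nodes strictly farther
    away from every seed.
    """
    rng = np.random.default_rng(rng_seed)
    nodes = net.nodes
    if n_seeds > len(nodes):
        raise GenerationError("more seeds requested than network nodes")
    start = nodes[int(rng.integers(len(nodes)))]
    seeds = {start}
    frontier = set(net.neighbors(start))
    while len(seeds) < n_seeds:
        if not frontier:
            raise GenerationError("seed module exhausted its component")
        pick = sorted(frontier)[int(rng.integers(len(frontier)))]
        seeds.add(pick)
        frontier |= set(net.neighbors(pick))
        frontier -= seeds
    dist = nx.multi_source_dijkstra_path_length(net.graph, seeds)
    near = sorted(g for g, d in dist.items() if 1 <= d <= hop_radius)
    far = sorted(g for g, d in dist.items() if d > hop_radius)
    if len(near) < n_true or len(far) < n_decoys:
        raise GenerationError(
            f"infeasible labels: {len(near)} near / {len(far)} far nodes "
            f"available for {n_true} true / {n_decoys} decoys; "
            "use a larger network or smaller hop_radius"
        )
    true = frozenset(
        near[i] for i in rng.choice(len(near), size=n_true, replace=False)
    )
    decoys = frozenset(
        far[i] for i in rng.choice(len(far), size=n_decoys, replace=False)
    )
    # a risk-category mix resembling a curated disease gene list
    cats = ["high", "low_and_high", "intermediate", "low", "driver"]
    ordered = sorted(seeds)
    categories = {g: cats[i % len(cats)] for i, g in enumerate(ordered)}
    return SeedSet(genes=tuple(ordered), categories=categories), true, decoys


def _passing_record(
    rng: np.random.Generator,
    gene: str,
    family_id: str,
    cases: int,
    config: FilterConfig,
) -> VariantRecord:
    consequence = ("missense", "stop_gain", "frameshift", "splicing", "inframe_indel")[
        int(rng.integers(5))
    ]
    if consequence == "missense":
        metasvm, metalr = "D", "D"
        cadd = float(rng.uniform(config.cadd_min + 1, 40.0))
    else:
        metasvm = metalr = None
        cadd = None

    def maybe_rare() -> Optional[float]:
        return (
            None
            if rng.random() < 0.5
            else float(rng.uniform(0.0, config.maf_max * 0.9))
        )

    return VariantRecord(
        family_id=family_id,
        gene=gene,
        chrom=str(int(rng.integers(1, 23))),
        pos=int(rng.integers(1, 250_000_000)),
        ref="A",
        alt="T",
        consequence=consequence,
        maf_1kg=maybe_rare(),
        maf_esp=maybe_rare(),
        maf_exac=maybe_rare(),
        inhouse_family_count=int(rng.integers(0, config.inhouse_max + 1)),
        carriers_in_family=int(rng.integers(config.min_carriers, cases + 1)),
        cases_sequenced=cases,
        metasvm=metasvm,
        metalr=metalr,
        cadd=cadd,
        qc_flagged=False,
        depth=int(rng.integers(config.min_depth + 5, 120)),
        abhet=None if rng.random() < 0.3 else float(rng.uniform(0.35, 0.65)),
        caller_count=int(rng.integers(config.min_callers, 4)),
    )


def _apply_fate(
    rec: VariantRecord, fate: str, rng: np.random.Generator, config: FilterConfig
) -> VariantRecord:
    """Break exactly the field(s) the named filter checks."""
    if fate == "pass":
        return rec
    if fate == "fail_population":
        return replace(rec, maf_exac=float(rng.uniform(config.maf_max * 2, 0.05)))
    if fate == "fail_inhouse":
        return replace(
            rec, inhouse_family_count=int(rng.integers(config.inhouse_max + 1, 10))
        )
    if fate == "fail_cosegregation":
        return replace(rec, carriers_in_family=config.min_carriers - 1)
    if fate == "fail_consequence":
        return replace(rec, consequence="other", metasvm=None, metalr=None, cadd=None)
    if fate == "fail_blacklist":
        return rec  # caller puts the gene on the blacklist
    if fate == "fail_deleteriousness":
        # the contentious single-vote case: tolerated calls but high CADD
        return replace(
            rec,
            consequence="missense",
            metasvm="T",
            metalr="T",
            cadd=float(rng.uniform(config.cadd_min, config.cadd_min + 10)),
        )
    if fate == "fail_qc":
        breaker = int(rng.integers(4))
        if breaker == 0:
            return replace(rec, depth=int(rng.integers(0, config.min_depth)))
        if breaker == 1:
            return replace(rec, abhet=float(rng.uniform(config.abhet_hi + 0.01, 1.0)))
        if breaker == 2:
            return replace(rec, caller_count=1)
        return replace(rec, qc_flagged=True)
    raise ValidationError(f"unknown fate {fate!r}")


def generate_variant_table(
    candidate_genes: Sequence[str],
    noise_genes: Sequence[str],
    noise_design: Mapping[str, int],
    n_families: int,
    min_cases: int,
    max_cases: int,
    rng_seed: int,
    config: FilterConfig | None = None,
) -> tuple[list[VariantRecord], frozenset[str], int]:
    """Variant records with designed per-record fates.

    Every candidate gene receives exactly one all-passing record in a
    random family (private mutations). ``noise_design`` maps failing
    fates to record counts; those records land on genes drawn without
    replacement from ``noise_genes``. Returns the table, the blacklist
    implied by ``fail_blacklist`` records, and the total sequenced cases.
    """
    config = config or FilterConfig()
    bad = set(noise_design) - set(FATES) | {"pass"} & set(noise_design)
    if bad:
        raise ValidationError(f"invalid noise fates: {sorted(bad)}")
    n_noise = sum(noise_design.values())
    if n_noise > len(noise_genes):
        raise ValidationError(
            f"noise design needs {n_noise} genes, only {len(noise_genes)} supplied"
        )
    if min_cases < 1 or max_cases < min_cases:
        raise ValidationError("need 1 <= min_cases <= max_cases")
    rng = np.random.default_rng(rng_seed)
    family_ids = [f"F{i + 1:02d}" for i in range(n_families)]
    cases = {
        fid: int(rng.integers(min_cases, max_cases + 1)) for fid in family_ids
    }
    records: list[VariantRecord] = []
    for gene in candidate_genes:
        fid = family_ids[int(rng.integers(n_families))]
        records.append(_passing_record(rng, gene, fid, cases[fid], config))
    blacklist: set[str] = set()
    pool = list(noise_genes)
    rng.shuffle(pool)
    cursor = 0
    for fate in sorted(noise_design):
        for _ in range(noise_design[fate]):
            gene = pool[cursor]
            cursor += 1
            fid = family_ids[int(rng.integers(n_families))]
            rec = _passing_record(rng, gene, fid, cases[fid], config)
            rec = _apply_fate(rec, fate, rng, config)
            if fate == "fail_blacklist":
                blacklist.add(gene)
            records.append(rec)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, frozenset(blacklist), sum(cases.values())


def generate_scenario(
    params: ScenarioParams | None = None, rng_seed: int = 0
) -> SyntheticScenario:
    """Generate a full benchmark scenario and verify its design closure.

    The returned scenario guarantees that filtering its variant table
    with the default thresholds (plus its blacklist) yields exactly the
    designed candidate genes.
    """
    params = params or ScenarioParams()
    rng = np.random.default_rng(rng_seed)
    sub = [int(x) for x in rng.integers(0, 2**31 - 1, size=3)]
    net = generate_network(params.n_nodes, params.attachment, sub[0])
    seeds, true, decoys = plant_seeds_and_candidates(
        net, params.n_seeds, params.n_true, params.n_decoys, params.hop_radius, sub[1]
    )
    candidates = sorted(true | decoys)
    reserved = set(candidates) | set(seeds.genes)
    noise_pool = [g for g in net.nodes if g not in reserved]
    table, blacklist, total_cases = generate_variant_table(
        candidates,
        noise_pool,
        params.noise_design,
        params.n_families,
        params.min_cases,
        params.max_cases,
        sub[2],
    )
    config = FilterConfig(blacklist=blacklist)
    survivors, _ = filter_variants(table, config)
    got = {r.gene for r in survivors}
    if got != set(candidates):  # pragma: no cover - design closure guard
        raise GenerationError(
            f"design closure violated: {sorted(got ^ set(candidates))[:5]}"
        )
    return SyntheticScenario(
        network=net,
        seeds=seeds,
        true_candidates=true,
        decoy_candidates=decoys,
        variant_table=table,
        blacklist=blacklist,
        total_cases=total_cases,
        rng_seed=rng_seed,
        params=params,
    )


def write_scenario(scenario: SyntheticScenario, directory: str | Path) -> None:
    """Serialize to the same TSV formats the pipeline reads."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_edgelist(scenario.network, d / "network.tsv")
    save_seeds(scenario.seeds, d / "seeds.tsv")
    write_variants_tsv(scenario.variant_table, d / "variants.tsv")
    (d / "blacklist.txt").write_text(
        "".join(f"{g}\n" for g in sorted(scenario.blacklist))
    )
    labels = [("true", g) for g in sorted(scenario.true_candidates)] + [
        ("decoy", g) for g in sorted(scenario.decoy_candidates)
    ]
    with (d / "labels.tsv").open("w") as fh:
        fh.write("label\tgene\n")
        for label, gene in labels:
            fh.write(f"{label}\t{gene}\n")
    meta = {
        "rng_seed": scenario.rng_seed,
        "total_cases": scenario.total_cases,
        "params": {**asdict(scenario.params), "noise_design": dict(scenario.params.noise_design)},
    }
    (d / "scenario.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_scenario(directory: str | Path) -> SyntheticScenario:
    d = Path(directory)
    meta = json.loads((d / "scenario.json").read_text())
    params = ScenarioParams(**meta["params"])
    true: set[str] = set()
    decoys: set[str] = set()
    with (d / "labels.tsv").open() as fh:
        next(fh)
        for line in fh:
            label, gene = line.split()
            (true if label == "true" else decoys).add(gene)
    blacklist = frozenset(
        line.strip() for line in (d / "blacklist.txt").read_text().splitlines() if line.strip()
    )
    return SyntheticScenario(
        network=load_edgelist(d / "network.tsv"),
        seeds=load_seeds(d / "seeds.tsv"),
        true_candidates=frozenset(true),
        decoy_candidates=frozenset(decoys),
        variant_table=read_variants_tsv(d / "variants.tsv"),
        blacklist=blacklist,
        total_cases=int(meta["total_cases"]),
        rng_seed=int(meta["rng_seed"]),
        params=params,
    )


def roc_auc(positive: Sequence[float], negative: Sequence[float]) -> float:
    """AUROC of separating positives from negatives by score (rank-based)."""
    from scipy.stats import rankdata

    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score groups must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
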