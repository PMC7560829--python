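"""End-to-end orchestration: filter -> propagate -> permute -> consensus -> modules.

:class:`RunConfig` gathers every path and threshold; :func:`run_pipeline`
executes the stages, writing each stage's TSV plus a machine-readable
``summary.json`` and a ``run.log`` into the output directory. Runs are
deterministic: the same configuration and ``rng_seed`` produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from . import module_detect, permutation
from .consensus import build_consensus, write_consensus_tsv
from .exceptions import NetprioError, ValidationError
from .interactome import (
    Interactome,
    largest_connected_component,
    load_edgelist,
    write_graphml,
)
from .propagation import DEFAULT_RESTART, SeedSet, load_seeds, prioritize
from .variant_filter import (
    FilterConfig,
    aggregate_to_genes,
    filter_variants,
    read_variants_tsv,
    write_attrition_tsv,
    write_candidates_tsv,
    write_variants_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    networks: dict[str, str] = field(default_factory=dict)  # name -> edge list path
    seeds: str = ""
    variants: str = ""
    blacklist: Optional[str] = None
    total_cases: Optional[int] = None  # defaults to sum of per-family cases

    # variant filtering
    maf_max: float = 0.001
    inhouse_max: int = 2
    min_carriers: int = 3
    cadd_min: float = 20.0
    min_votes: int = 2
    min_depth: int = 10
    abhet_lo: float = 0.2
    abhet_hi: float = 0.8
    min_callers: int = 2

    # propagation
    restart: float = DEFAULT_RESTART
    tol: float = 1e-10
    max_iter: int = 1000

    # permutation
    n_sets: int = 1000
    set_size: Optional[int] = None  # default: number of retained seeds
    alpha: float = 0.05
    rng_seed: int = 0

    # module detection
    module_n_perm: int = 100
    seed_score: Optional[float] = None
    module_min_networks: int = 2

    # consensus
    top_k: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def filter_config(self, blacklist: frozenset[str]) -> FilterConfig:
        return FilterConfig(
            maf_max=self.maf_max,
            inhouse_max=self.inhouse_max,
            min_carriers=self.min_carriers,
            cadd_min=self.cadd_min,
            min_votes=self.min_votes,
            min_depth=self.min_depth,
            abhet_lo=self.abhet_lo,
            abhet_hi=self.abhet_hi,
            min_callers=self.min_callers,
            blacklist=blacklist,
        )

    def validate(self) -> None:
        if not self.networks:
            raise ValidationError("config lists no interactome networks")
        for name, path in self.networks.items():
            if not Path(path).exists():
                raise ValidationError(f"network {name!r}: no such file {path}")
        for label, path in (("seeds", self.seeds), ("variants", self.variants)):
            if not path or not Path(path).exists():
                raise ValidationError(f"{label} file missing: {path!r}")
        if self.blacklist and not Path(self.blacklist).exists():
            raise ValidationError(f"blacklist file missing: {self.blacklist!r}")


def _write_ranking_tsv(result, pvalues: Mapping[str, float], path: Path) -> None:
    with path.open("w") as fh:
        fh.write("gene\trank\traw_probability\tadjusted_score\tp_value\n")
        for gene, rank in result.candidate_ranks:
            p = pvalues.get(gene)
            fh.write(
                f"{gene}\t{rank}\t{result.probabilities[gene]:.6e}\t"
                f"{result.adjusted_score[gene]:.6f}\t"
                f"{'' if p is None else f'{p:.6g}'}\n"
            )


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage; returns the run directory.

    On a stage failure the partial outputs are kept and an empty
    ``FAILED`` marker names the stage that broke.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("netprio")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    config.to_yaml(out / "config.yaml")
    summary: dict = {"stages": {}}
    stage = "setup"
    try:
        # ---- load inputs
        stage = "load"
        networks: dict[str, Interactome] = {}
        for name in sorted(config.networks):
            net = load_edgelist(config.networks[name])
            lcc = largest_connected_component(net)
            logger.info(
                "network %s: %d/%d nodes in largest component",
                name, lcc.n_nodes, net.n_nodes,
            )
            networks[name] = lcc
        seeds: SeedSet = load_seeds(config.seeds)
        records = read_variants_tsv(config.variants)
        blacklist = frozenset()
        if config.blacklist:
            blacklist = frozenset(
                line.strip()
                for line in Path(config.blacklist).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            )
        summary["stages"]["load"] = {
            "networks": {n: networks[n].n_nodes for n in networks},
            "n_seeds": len(seeds),
            "n_variant_records": len(records),
        }

        # ---- variant filtering
        stage = "filter"
        fconfig = config.filter_config(blacklist)
        survivors, attrition = filter_variants(records, fconfig)
        per_family: dict[str, int] = {}
        for rec in records:
            per_family[rec.family_id] = max(
                per_family.get(rec.family_id, 0), rec.cases_sequenced
            )
        total_cases = config.total_cases or sum(per_family.values())
        candidates = aggregate_to_genes(survivors, total_cases)
        candidate_genes = {c.gene for c in candidates}
        write_variants_tsv(survivors, out / "survivors.tsv")
        write_candidates_tsv(candidates, out / "candidate_genes.tsv")
        write_attrition_tsv(attrition, out / "attrition.tsv")
        summary["stages"]["filter"] = {
            "n_survivors": len(survivors),
            "n_candidate_genes": len(candidate_genes),
            "attrition": attrition,
            "total_cases": total_cases,
        }

        # ---- per-network propagation + permutation
        stage = "propagate"
        rankings: dict[str, list[str]] = {}
        pvalues: dict[str, dict[str, float]] = {}
        results = {}
        for i, (name, net) in enumerate(sorted(networks.items())):
            result = prioritize(
                net, seeds, candidate_genes,
                restart=config.restart, tol=config.tol, max_iter=config.max_iter,
            )
            results[name] = result
            retained = [g for g in seeds.genes if g in net]
            set_size = config.set_size or len(retained)
            random_sets = permutation.sample_seed_sets(
                net, set_size, config.n_sets, rng_seed=config.rng_seed + i
            )
            perm = permutation.empirical_pvalues(
                net,
                result.probabilities,
                random_sets,
                restart=config.restart,
                candidates=candidate_genes,
                tol=config.tol,
                max_iter=config.max_iter,
                rng_seed=config.rng_seed + i,
            )
            permutation.write_permutation_tsv(
                perm, result.probabilities, out / f"permutation_{name}.tsv",
                alpha=config.alpha,
            )
            _write_ranking_tsv(result, perm.p_value, out / f"ranking_{name}.tsv")
            rankings[name] = [g for g, _ in result.candidate_ranks]
            pvalues[name] = perm.p_value
            summary["stages"].setdefault("propagate", {})[name] = {
                "n_ranked": len(result.candidate_ranks),
                "n_unrankable": len(result.unrankable),
                "iterations": result.iterations_used,
                "n_significant": len(
                    permutation.significant_genes(perm, config.alpha)
                ),
            }

        # ---- consensus
        stage = "consensus"
        table = build_consensus(
            rankings, pvalues, top_k=config.top_k, alpha=config.alpha
        )
        write_consensus_tsv(table, out / "consensus.tsv")
        summary["stages"]["consensus"] = {
            "n_genes": int(len(table)),
            "n_multi_network": int(
                (table["n_networks_significant"] >= 2).sum()
            ) if len(table) else 0,
        }

        # ---- module detection
        stage = "modules"
        scores = module_detect.vertex_scores(
            candidates, seeds, seed_score=config.seed_score
        )
        per_net_sig: dict[str, module_detect.ModuleSignificance] = {}
        for i, (name, net) in enumerate(sorted(networks.items())):
            in_net = {g: v for g, v in scores.items() if g in net}
            sig = module_detect.significance(
                net,
                in_net,
                restart=config.restart,
                n_perm=config.module_n_perm,
                rng_seed=config.rng_seed + 100 + i,
            )
            per_net_sig[name] = sig
            module_detect.write_clusters_tsv(sig, out / f"clusters_{name}.tsv")
            if sig.clusters:
                sub = net.subgraph(sorted(set().union(*sig.clusters)))
                write_graphml(sub, out / f"clusters_{name}.graphml")
            summary["stages"].setdefault("modules", {})[name] = {
                "p_value": sig.p_value,
                "selected_delta": sig.selected_delta,
                "n_clusters": len(sig.clusters),
                "largest_cluster": max((len(c) for c in sig.clusters), default=0),
            }
        consensus_genes = module_detect.consensus_module_genes(
            per_net_sig, min_networks=config.module_min_networks, alpha=config.alpha
        )
        (out / "module_consensus_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(consensus_genes))
        )
        summary["stages"]["modules"]["consensus_genes"] = len(consensus_genes)

        # ---- first-neighbor extraction
        stage = "first_neighbors"
        fn_counts = {}
        for name, net in sorted(networks.items()):
            module = module_detect.first_neighbor_module(net, seeds, candidate_genes)
            module_detect.write_first_neighbor_tsv(
                module, out / f"first_neighbors_{name}.tsv"
            )
            fn_counts[name] = module_detect.count_seed_candidate_interactions(module)
        summary["stages"]["first_neighbors"] = fn_counts

        summary["ok"] = True
    except NetprioError as exc:
        summary["ok"] = False
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        raise NetprioError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(log_handler)
        log_handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
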