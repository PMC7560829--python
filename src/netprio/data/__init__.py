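"""Packaged fixtures: curated gene lists and a toy variant table.

``cmm_seed_genes.tsv`` transcribes the curated cutaneous-malignant-
melanoma seed list used for propagation: 47 genes spanning high-,
intermediate- and low-risk susceptibility loci plus somatic drivers.

``high_risk_first_neighbors.tsv`` transcribes the direct-interaction
neighborhood of the seven high-risk CMM genes (ACD, TPP1, BAP1, CDKN2A,
CDK4, POT1, TERF2IP) inside the interconnected module, with partners
found in the exome candidate list flagged.

``toy_variants.tsv`` is a synthetic 20-record variant table designed by
hand so that every inclusion filter uniquely rejects at least one record
and exactly 7 records survive the full conjunction.
"""

from __future__ import annotations

import csv
from importlib import resources

from ..interactome import Interactome
from ..propagation import SeedSet
from ..variant_filter import VariantRecord, read_variants_tsv

__all__ = [
    "load_cmm_seed_genes",
    "load_high_risk_neighbor_fixture",
    "load_toy_variants",
    "load_toy_blacklist",
]


def _path(name: str):
    return resources.files(__package__) / name


def load_cmm_seed_genes() -> SeedSet:
    """The curated 47-gene melanoma seed list with risk categories."""
    genes: list[str] = []
    categories: dict[str, str] = {}
    with _path("cmm_seed_genes.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            genes.append(row["gene"])
            categories[row["gene"]] = row["category"]
    return SeedSet(genes=tuple(genes), categories=categories)


def load_high_risk_neighbor_fixture() -> tuple[Interactome, tuple[str, ...], frozenset[str]]:
    """First-neighbor fixture: (network, high-risk seeds, candidate genes).

    The network holds the transcribed seed-partner edges; seeds are the
    table's subject genes; candidates are the partners flagged as coming
    from the exome candidate list.
    """
    edges: list[tuple[str, str]] = []
    seeds: list[str] = []
    candidates: set[str] = set()
    with _path("high_risk_first_neighbors.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            edges.append((row["seed"], row["partner"]))
            if row["seed"] not in seeds:
                seeds.append(row["seed"])
            if row["partner_is_candidate"] == "1":
                candidates.add(row["partner"])
    return Interactome.from_edges(edges), tuple(seeds), frozenset(candidates)


def load_toy_variants() -> list[VariantRecord]:
    """The hand-designed 20-record variant fixture."""
    with resources.as_file(_path("toy_variants.tsv")) as p:
        return read_variants_tsv(p)


def load_toy_blacklist() -> frozenset[str]:
    """Highly-variable-gene blacklist paired with the toy variant table."""
    text = _path("toy_blacklist.txt").read_text()
    return frozenset(line.strip() for line in text.splitlines() if line.strip())
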