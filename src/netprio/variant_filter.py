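"""Familial rare-variant filtering and per-gene aggregation.

A variant observation (one variant seen in one family) survives when it
jointly satisfies seven predicates:

1. population rarity — every non-missing MAF (1000 Genomes, ESP6500,
   ExAC) is strictly below ``maf_max`` (default 0.001);
2. in-house recurrence — seen in at most ``inhouse_max`` families of an
   internal exome database (default 2);
3. cosegregation — carried by at least ``min_carriers`` sequenced cases
   or obligate carriers within the family (default 3);
4. consequence — non-synonymous: frameshift, stop-gain, inframe indel,
   missense, or splicing-site;
5. blacklist — the gene is not on a user-supplied list of highly
   variable genes;
6. deleteriousness — missense variants need at least ``min_votes`` of
   the three in-silico calls {MetaLR = D, MetaSVM = D, CADD ≥ 20};
   non-missense classes pass unconditionally;
7. quality control — not pipeline-flagged, read depth ≥ 10, ABHet (if
   present) within [0.2, 0.8], and called by ≥ 2 of 3 variant callers.

The predicates form an unordered conjunction; the attrition report counts,
for each predicate alone, how many input records it rejects, so the
numbers do not depend on evaluation order.

Surviving variants aggregate into one :class:`CandidateGene` per gene
with the set of contributing families and the pooled carrier fraction
(total carriers across families divided by all sequenced cases), the
vertex score used later by hot-subnetwork detection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .exceptions import ParseError, ValidationError

__all__ = [
    "VariantRecord",
    "CandidateGene",
    "FilterConfig",
    "CONSEQUENCES",
    "DAMAGING_CONSEQUENCES",
    "passes_population_filter",
    "passes_inhouse_filter",
    "passes_cosegregation_filter",
    "passes_consequence_filter",
    "passes_blacklist_filter",
    "passes_deleteriousness_filter",
    "passes_qc_filter",
    "filter_variants",
    "aggregate_to_genes",
    "read_variants_tsv",
    "write_variants_tsv",
    "write_candidates_tsv",
    "read_candidates_tsv",
    "write_attrition_tsv",
]

CONSEQUENCES = frozenset(
    {"frameshift", "stop_gain", "inframe_indel", "missense", "splicing", "other"}
)
#: consequence classes treated as non-synonymous / potentially damaging
DAMAGING_CONSEQUENCES = frozenset(
    {"frameshift", "stop_gain", "inframe_indel", "missense", "splicing"}
)

MISSING = "."


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant observed in one family."""

    family_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    maf_1kg: Optional[float]
    maf_esp: Optional[float]
    maf_exac: Optional[float]
    inhouse_family_count: int
    carriers_in_family: int
    cases_sequenced: int
    metasvm: Optional[str]  # "D" or "T"
    metalr: Optional[str]
    cadd: Optional[float]
    qc_flagged: bool = False
    depth: int = 30
    abhet: Optional[float] = None
    caller_count: int = 3

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"unknown consequence {self.consequence!r} for {self.gene}"
            )
        if self.carriers_in_family > self.cases_sequenced:
            raise ValidationError(
                f"{self.gene} in {self.family_id}: carriers_in_family "
                f"({self.carriers_in_family}) exceeds cases_sequenced "
                f"({self.cases_sequenced})"
            )
        if self.pos < 1:
            raise ValidationError(f"position must be 1-based positive, got {self.pos}")
        for name in ("maf_1kg", "maf_esp", "maf_exac", "abhet"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValidationError(f"{name}={val} outside [0, 1]")
        if not (0 <= self.caller_count <= 3):
            raise ValidationError(f"caller_count={self.caller_count} outside [0, 3]")

    @property
    def mafs(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        return (self.maf_1kg, self.maf_esp, self.maf_exac)


@dataclass(frozen=True)
class CandidateGene:
    """A gene carrying at least one surviving variant, with family support."""

    gene: str
    families: frozenset[str]
    patient_carrier_fraction: float

    @property
    def n_families(self) -> int:
        return len(self.families)

    def __post_init__(self):
        if not self.families:
            raise ValidationError(f"candidate gene {self.gene} has no families")
        if not (0.0 <= self.patient_carrier_fraction <= 1.0):
            raise ValidationError(
                f"carrier fraction {self.patient_carrier_fraction} outside [0, 1]"
            )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the seven inclusion predicates (documented defaults)."""

    maf_max: float = 0.001
    inhouse_max: int = 2
    min_carriers: int = 3
    cadd_min: float = 20.0
    min_votes: int = 2
    min_depth: int = 10
    abhet_lo: float = 0.2
    abhet_hi: float = 0.8
    min_callers: int = 2
    blacklist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not (0.0 < self.maf_max < 1.0):
            raise ValidationError("maf_max must lie in (0, 1)")
        if self.inhouse_max < 0 or self.min_carriers < 1:
            raise ValidationError("inhouse_max >= 0 and min_carriers >= 1 required")
        object.__setattr__(self, "blacklist", frozenset(self.blacklist))


# -- predicates --------------------------------------------------------


def passes_population_filter(v: VariantRecord, maf_max: float = 0.001) -> bool:
    """Every non-missing population MAF strictly below ``maf_max``.

    Missing frequencies pass: absence from a population database implies
    the allele is at least as rare as anything observed there.
    """
    return all(m is None or m < maf_max for m in v.mafs)


def passes_inhouse_filter(v: VariantRecord, max_families: int = 2) -> bool:
    """Observed in at most ``max_families`` families of the in-house database."""
    return v.inhouse_family_count <= max_families


def passes_cosegregation_filter(v: VariantRecord, min_carriers: int = 3) -> bool:
    """Carried by at least ``min_carriers`` sequenced cases/obligate carriers."""
    return v.carriers_in_family >= min_carriers


def passes_consequence_filter(v: VariantRecord) -> bool:
    """Non-synonymous consequence class."""
    return v.consequence in DAMAGING_CONSEQUENCES


def passes_blacklist_filter(v: VariantRecord, blacklist: Iterable[str]) -> bool:
    """Gene not on the highly-variable-gene blacklist."""
    return v.gene not in set(blacklist)


def passes_deleteriousness_filter(
    v: VariantRecord, cadd_min: float = 20.0, min_votes: int = 2
) -> bool:
    """Missense variants need ``min_votes`` of {MetaLR=D, MetaSVM=D, CADD>=cadd_min}.

    Non-missense classes pass unconditionally. A missing predictor is a
    non-vote, never counted as deleterious.
    """
    if v.consequence != "missense":
        return True
    votes = 0
    votes += v.metalr == "D"
    votes += v.metasvm == "D"
    votes += v.cadd is not None and v.cadd >= cadd_min
    return votes >= min_votes


def passes_qc_filter(
    v: VariantRecord,
    min_depth: int = 10,
    abhet_lo: float = 0.2,
    abhet_hi: float = 0.8,
    min_callers: int = 2,
) -> bool:
    """Call-quality gate: unflagged, adequate depth, balanced ABHet, multi-caller.

    ABHet is only defined for heterozygous calls, so a missing value
    passes the balance bounds.
    """
    if v.qc_flagged:
        return False
    if v.depth < min_depth:
        return False
    if v.abhet is not None and not (abhet_lo <= v.abhet <= abhet_hi):
        return False
    return v.caller_count >= min_callers


def _predicates(config: FilterConfig) -> dict[str, Callable[[VariantRecord], bool]]:
    return {
        "population": lambda v: passes_population_filter(v, config.maf_max),
        "inhouse": lambda v: passes_inhouse_filter(v, config.inhouse_max),
        "cosegregation": lambda v: passes_cosegregation_filter(v, config.min_carriers),
        "consequence": passes_consequence_filter,
        "blacklist": lambda v: passes_blacklist_filter(v, config.blacklist),
        "deleteriousness": lambda v: passes_deleteriousness_filter(
            v, config.cadd_min, config.min_votes
        ),
        "qc": lambda v: passes_qc_filter(
            v, config.min_depth, config.abhet_lo, config.abhet_hi, config.min_callers
        ),
    }


def filter_variants(
    records: Sequence[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the full conjunction of inclusion predicates.

    Returns ``(survivors, attrition)`` where ``attrition[name]`` is the
    number of input records that predicate *alone* rejects (a record
    failing several predicates is counted by each).
    """
    config = config or FilterConfig()
    preds = _predicates(config)
    attrition = {name: 0 for name in preds}
    survivors: list[VariantRecord] = []
    for rec in records:
        ok = True
        for name, pred in preds.items():
            if not pred(rec):
                attrition[name] += 1
                ok = False
        if ok:
            survivors.append(rec)
    return survivors, attrition


def aggregate_to_genes(
    survivors: Sequence[VariantRecord], total_cases: int
) -> list[CandidateGene]:
    """Collapse surviving variants into per-gene candidate records.

    ``patient_carrier_fraction`` pools carriers over all families:
    sum of ``carriers_in_family`` divided by ``total_cases`` (all
    sequenced cases in the study).
    """
    per_family_max: dict[str, int] = {}
    for rec in survivors:
        prev = per_family_max.get(rec.family_id, 0)
        per_family_max[rec.family_id] = max(prev, rec.cases_sequenced)
    if total_cases < sum(per_family_max.values()):
        raise ValidationError(
            f"total_cases={total_cases} is smaller than the sum of per-family "
            f"sequenced cases ({sum(per_family_max.values())})"
        )
    by_gene: dict[str, list[VariantRecord]] = {}
    for rec in survivors:
        by_gene.setdefault(rec.gene, []).append(rec)
    out = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        families = frozenset(r.family_id for r in recs)
        carriers = sum(r.carriers_in_family for r in recs)
        out.append(
            CandidateGene(
                gene=gene,
                families=families,
                patient_carrier_fraction=carriers / total_cases,
            )
        )
    return out


# -- TSV input/output ---------------------------------------------------

_STR_FIELDS = {"family_id", "gene", "chrom", "ref", "alt", "consequence"}
_OPT_FLOAT_FIELDS = {"maf_1kg", "maf_esp", "maf_exac", "cadd", "abhet"}
_OPT_STR_FIELDS = {"metasvm", "metalr"}
_INT_FIELDS = {
    "pos",
    "inhouse_family_count",
    "carriers_in_family",
    "cases_sequenced",
    "depth",
    "caller_count",
}

VARIANT_COLUMNS = [f.name for f in dc_fields(VariantRecord)]


def _parse_cell(name: str, raw: str, path: Path, lineno: int):
    raw = raw.strip()
    try:
        if name in _STR_FIELDS:
            return raw
        if name in _OPT_STR_FIELDS:
            return None if raw == MISSING or raw == "" else raw
        if name in _OPT_FLOAT_FIELDS:
            return None if raw == MISSING or raw == "" else float(raw)
        if name in _INT_FIELDS:
            return int(raw)
        if name == "qc_flagged":
            if raw in {"1", "true", "True", "yes"}:
                return True
            if raw in {"0", "false", "False", "no"}:
                return False
            raise ValueError(raw)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad value {raw!r} for {name}") from exc
    raise ParseError(f"{path}:{lineno}: unknown column {name!r}")


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read an annotated variant table (header required, '.' = missing)."""
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing_cols = set(VARIANT_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
        for lineno, row in enumerate(reader, start=2):
            kwargs = {
                name: _parse_cell(name, row[name], path, lineno)
                for name in VARIANT_COLUMNS
            }
            records.append(VariantRecord(**kwargs))
    return records


def _format_cell(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # shortest representation that round-trips exactly
    return str(value)


def write_variants_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for rec in records:
            writer.writerow(
                [_format_cell(getattr(rec, name)) for name in VARIANT_COLUMNS]
            )


def write_candidates_tsv(
    candidates: Sequence[CandidateGene], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "n_families", "families", "patient_carrier_fraction"])
        for cand in sorted(candidates, key=lambda c: c.gene):
            writer.writerow(
                [
                    cand.gene,
                    cand.n_families,
                    ",".join(sorted(cand.families)),
                    f"{cand.patient_carrier_fraction:.6g}",
                ]
            )


def read_candidates_tsv(path: str | Path) -> list[CandidateGene]:
    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                CandidateGene(
                    gene=row["gene"],
                    families=frozenset(row["families"].split(",")),
                    patient_carrier_fraction=float(row["patient_carrier_fraction"]),
                )
            )
    return out


def write_attrition_tsv(attrition: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write("filter\tn_rejected_alone\n")
        for name, count in attrition.items():
            fh.write(f"{name}\t{count}\n")
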