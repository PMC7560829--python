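"""Cross-interactome consensus of rankings and permutation significance.

Each interactome yields its own candidate ranking and permutation
p-values. A gene enters a network's column of the consensus table when it
is both inside that network's top ``top_k`` (default 30) *and*
permutation-significant there (p < alpha, default 0.05). Genes appearing
in two or more networks' columns are the reproducible, headline calls.

``aggregate_rank`` is the mean of the gene's ranks over the networks
where it appears — chosen over a rank product for interpretability — and
the table sorts by (descending number of significant networks, ascending
aggregate rank, symbol).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["build_consensus", "write_consensus_tsv"]


def build_consensus(
    rankings: Mapping[str, Sequence[str]],
    pvalues: Mapping[str, Mapping[str, float]],
    top_k: int = 30,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Build the cross-network prioritization table.

    Parameters
    ----------
    rankings
        Per-network ordered gene lists, best first (rank = 1-based
        position). Lists are truncated to ``top_k`` *after* checking the
        significance filter, i.e. membership requires rank <= top_k and
        p < alpha simultaneously.
    pvalues
        Per-network gene -> permutation p-value maps.
    """
    if not rankings:
        raise ValidationError("at least one network ranking is required")
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    names = list(rankings)
    rows: dict[str, dict[str, float]] = {}
    for name in names:
        pv = pvalues.get(name, {})
        for pos, gene in enumerate(rankings[name], start=1):
            if pos > top_k:
                break
            p = pv.get(gene)
            if p is None or p >= alpha:
                continue
            row = rows.setdefault(gene, {})
            row[f"{name}_rank"] = pos
            row[f"{name}_p"] = p

    records = []
    for gene, row in rows.items():
        ranks = [row[f"{n}_rank"] for n in names if f"{n}_rank" in row]
        rec = {"gene": gene}
        for n in names:
            rec[f"{n}_rank"] = row.get(f"{n}_rank", np.nan)
            rec[f"{n}_p"] = row.get(f"{n}_p", np.nan)
        rec["n_networks_significant"] = len(ranks)
        rec["aggregate_rank"] = float(np.mean(ranks))
        rec["rank_product"] = float(np.prod(ranks) ** (1.0 / len(ranks)))
        records.append(rec)

    columns = (
        ["gene"]
        + [f"{n}_{suffix}" for n in names for suffix in ("rank", "p")]
        + ["n_networks_significant", "aggregate_rank", "rank_product"]
    )
    table = pd.DataFrame.from_records(records, columns=columns)
    table = table.sort_values(
        by=["n_networks_significant", "aggregate_rank", "gene"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def write_consensus_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
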