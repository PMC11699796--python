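"""Cluster-specific transcriptomic signatures (CSS).

A CSS candidate is a DEG with a strong fold-change (|log2FC| > 1.6, about
3-fold) whose adjusted p-value ranks in the top half of same-direction DEGs
for its contrast.  Candidates present in more than one subpopulation are
then filtered out, leaving genes uniquely over- or under-expressed in a
single subpopulation.

Ranking detail: within each (contrast x direction), *all* DEGs of that
direction are ordered by ascending adjusted p (ties broken by larger
|log2FC|, then gene ID); a gene is a candidate when its rank does not
exceed ``ceil(rank_fraction * n_direction)`` and it additionally passes the
fold-change filter.  Ranking before filtering keeps the rule monotone in
the fold-change threshold.  An alternative pooled-across-direction ranking
is available via ``per_direction=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class CSSCandidate:
    gene_id: str
    subpopulation: str
    direction: str
    log2fc: float
    padj: float
    rank: int


def css_candidates(
    de_tables: dict[str, pd.DataFrame],
    lfc_min: float = 1.6,
    rank_fraction: float = 0.5,
    per_direction: bool = True,
) -> list[CSSCandidate]:
    """Strong, low-adjusted-p DEGs retained per contrast."""
    candidates: list[CSSCandidate] = []
    for subpop, table in de_tables.items():
        degs = table[table["direction"].isin(["up", "down"])]
        if degs.empty:
            continue
        if per_direction:
            groups = [degs[degs["direction"] == d] for d in ("up", "down")]
        else:
            groups = [degs]
        for group in groups:
            if group.empty:
                continue
            n_direction = len(group)
            cutoff = math.ceil(rank_fraction * n_direction)
            ranked = group.copy()
            ranked["_abs_lfc"] = ranked["log2FC"].abs()
            ranked["_gene"] = ranked.index
            ranked = ranked.sort_values(
                ["padj", "_abs_lfc", "_gene"], ascending=[True, False, True]
            )
            for rank, (gene, row) in enumerate(ranked.iterrows(), start=1):
                if rank > cutoff:
                    break
                if abs(row["log2FC"]) <= lfc_min:
                    continue
                candidates.append(
                    CSSCandidate(
                        gene_id=str(gene),
                        subpopulation=subpop,
                        direction=str(row["direction"]),
                        log2fc=float(row["log2FC"]),
                        padj=float(row["padj"]),
                        rank=rank,
                    )
                )
    return candidates


def unique_css(candidates: list[CSSCandidate]) -> pd.DataFrame:
    """Keep genes that are candidates in exactly one subpopulation.

    Uniqueness is at the gene level: a gene up in one subpopulation and down
    in another counts as present in two and is removed.  Returns a table
    with one row per candidate entry and a ``unique_flag`` column; the CSS
    set is the flagged subset.
    """
    rows = [
        {
            "gene_id": c.gene_id,
            "subpopulation": c.subpopulation,
            "direction": c.direction,
            "log2FC": c.log2fc,
            "padj": c.padj,
            "rank": c.rank,
        }
        for c in candidates
    ]
    table = pd.DataFrame(
        rows, columns=["gene_id", "subpopulation", "direction", "log2FC", "padj", "rank"]
    )
    if table.empty:
        table["unique_flag"] = pd.Series(dtype=bool)
        return table
    n_subpops = table.groupby("gene_id")["subpopulation"].nunique()
    table["unique_flag"] = table["gene_id"].map(n_subpops == 1)
    return table


def css_counts(css_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subpopulation unique-CSS counts plus the dataset total."""
    unique = css_table[css_table.get("unique_flag", pd.Series(dtype=bool)) == True]  # noqa: E712
    counts = (
        unique.groupby("subpopulation")["gene_id"].nunique()
        if len(unique)
        else pd.Series(dtype=int)
    )
    rows = [{"subpopulation": k, "n_css": int(v)} for k, v in counts.items()]
    rows.append({"subpopulation": "total", "n_css": int(counts.sum()) if len(counts) else 0})
    return pd.DataFrame(rows, columns=["subpopulation", "n_css"])
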