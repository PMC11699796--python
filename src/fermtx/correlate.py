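"""Spearman correlations, significant-edge networks, gene-set enrichment and
accumulated fold-change statistics.

The focal-gene analysis correlates a small set of genes of interest (the
three lactate-dehydrogenase-coding genes in the motivating application)
against the rest of the transcriptome or against pathway gene sets;
significant pairs (unadjusted p < 0.05, matching the network rule of the
underlying study design) become edges of an undirected correlation network.
Gene-set enrichment uses the one-sided hypergeometric upper tail with BH
adjustment across sets, and the accumulated fold-change of a set in a
contrast is the sum of log2 fold-changes over that contrast's DEGs
belonging to the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .errors import ValidationError


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with pairwise-complete observations.

    Average ranks for ties; the p-value uses the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 df (p = 0 at |rho| = 1).
    Constant inputs give a missing rho.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("inputs must have equal length")
    complete = ~(np.isnan(x) | np.isnan(y))
    n = int(complete.sum())
    if n < 3:
        raise ValidationError(f"need >= 3 pairwise-complete pairs, got {n}")
    xc, yc = x[complete], y[complete]
    if np.all(xc == xc[0]) or np.all(yc == yc[0]):
        return SpearmanResult(np.nan, np.nan, n)
    rho, pvalue = stats.spearmanr(xc, yc)
    if abs(rho) >= 1.0 - 1e-15:
        pvalue = 0.0
    return SpearmanResult(float(rho), float(pvalue), n)


def _spearman_matrix(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Spearman rho and t-approximation p for complete columns.

    ``matrix`` is observations x variables with no missing values; returns
    (rho, p) square matrices.
    """
    n, _ = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, matrix)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - np.square(rho), 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0 - 1e-15] = 0.0
    return rho, p


def focal_gene_correlations(
    expression: pd.DataFrame,
    focal_ids: list[str],
    target_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each focal gene against each target gene.

    ``expression`` is genes x samples.  Targets default to all non-focal
    genes.  P-values are unadjusted, matching the p < 0.05 edge rule.
    """
    missing = [g for g in focal_ids if g not in expression.index]
    if missing:
        raise ValidationError(f"focal gene IDs absent from expression: {missing}")
    if target_ids is None:
        target_ids = [g for g in expression.index if g not in set(focal_ids)]
    else:
        missing = [g for g in target_ids if g not in expression.index]
        if missing:
            raise ValidationError(f"target gene IDs absent from expression: {missing}")
    if not target_ids:
        return pd.DataFrame(columns=["focal", "target", "rho", "pvalue", "n"])

    genes = list(focal_ids) + [g for g in target_ids if g not in set(focal_ids)]
    sub = expression.loc[genes].to_numpy(float).T  # samples x genes
    n = sub.shape[0]
    rho, p = _spearman_matrix(sub)
    pos = {g: i for i, g in enumerate(genes)}
    rows = []
    for f in focal_ids:
        for t in target_ids:
            i, j = pos[f], pos[t]
            rows.append(
                {"focal": f, "target": t, "rho": rho[i, j], "pvalue": p[i, j], "n": n}
            )
    return pd.DataFrame(rows, columns=["focal", "target", "rho", "pvalue", "n"])


def build_network(
    correlations: pd.DataFrame,
    p_threshold: float = 0.05,
    adjust: bool = False,
) -> nx.Graph:
    """Undirected network of significant correlation pairs.

    Nodes are genes incident to at least one significant edge; edges carry
    rho and the p-value.  ``adjust=True`` applies BH before thresholding.
    """
    graph = nx.Graph()
    if correlations.empty:
        return graph
    pvals = correlations["pvalue"].to_numpy(float)
    if adjust:
        pvals = bh_adjust(pvals)
    for (_, row), p in zip(correlations.iterrows(), pvals):
        a, b = str(row["focal"]), str(row["target"])
        if a == b or np.isnan(p) or p >= p_threshold:
            continue
        graph.add_edge(a, b, rho=float(row["rho"]), pvalue=float(p))
    return graph


def network_edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {"gene_a": a, "gene_b": b, "rho": d["rho"], "pvalue": d["pvalue"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "pvalue"])


def enrich(
    query_genes,
    universe,
    gene_sets,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric gene-set enrichment with BH across sets.

    For each set the overlap k between the query and the set (both
    intersected with the universe) is tested with p = P(X >= k) under the
    hypergeometric distribution with population U = |universe|, K = |set|,
    draws n = |query|.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    query = set(query_genes) & universe
    outside = set(query_genes) - universe
    if outside:
        raise ValidationError(
            f"query genes outside the universe: {sorted(outside)[:5]}"
        )
    U, n = len(universe), len(query)
    rows = []
    for set_id, members in gene_sets:
        members_in = set(members) & universe
        K = len(members_in)
        if K == 0:
            continue
        k = len(query & members_in)
        p = float(stats.hypergeom.sf(k - 1, U, K, n))
        rows.append({"set_id": set_id, "k": k, "K": K, "n": n, "U": U, "pvalue": p})
    result = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "U", "pvalue"])
    if len(result):
        result["padj"] = bh_adjust(result["pvalue"].to_numpy())
        result["significant"] = result["padj"] < padj_max
    else:
        result["padj"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result


def accumulated_fc(de_table: pd.DataFrame, gene_set) -> tuple[float, int]:
    """Sum of log2FC over the contrast's DEGs belonging to the gene set.

    Returns (accumulated log2FC, number of contributing genes); (0.0, 0)
    when no member of the set is a DEG.
    """
    members = [g for g in gene_set if g in de_table.index]
    sub = de_table.loc[members]
    degs = sub[sub["direction"].isin(["up", "down"])]
    return float(degs["log2FC"].sum()), int(len(degs))


def accumulated_fc_table(
    de_tables: dict[str, pd.DataFrame], gene_sets
) -> pd.DataFrame:
    """Accumulated fold-change of every gene set in every contrast."""
    rows = []
    for subpop, table in de_tables.items():
        for set_id, members in gene_sets:
            total, count = accumulated_fc(table, members)
            rows.append(
                {
                    "subpopulation": subpop,
                    "set_id": set_id,
                    "accumulated_log2FC": total,
                    "n_degs": count,
                }
            )
    return pd.DataFrame(
        rows, columns=["subpopulation", "set_id", "accumulated_log2FC", "n_degs"]
    )


def metabolite_correlations(
    metabolites: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations between metabolite columns.

    Missing values are handled pairwise-complete; returns symmetric rho and
    p matrices plus the per-pair complete-observation counts.
    """
    cols = list(metabolites.columns)
    m = len(cols)
    rho = np.full((m, m), np.nan)
    pval = np.full((m, m), np.nan)
    nobs = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i, m):
            x = metabolites[cols[i]].to_numpy(float)
            y = metabolites[cols[j]].to_numpy(float)
            complete = ~(np.isnan(x) | np.isnan(y))
            nobs[i, j] = nobs[j, i] = int(complete.sum())
            if nobs[i, j] < 3:
                continue
            try:
                result = spearman(x, y)
            except ValidationError:
                continue
            rho[i, j] = rho[j, i] = result.rho
            pval[i, j] = pval[j, i] = result.pvalue
    idx = pd.Index(cols)
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(pval, index=idx, columns=idx),
        pd.DataFrame(nobs, index=idx, columns=idx),
    )
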