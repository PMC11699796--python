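"""One-vs-rest negative-binomial Wald tests for subpopulation contrasts.

For each contrast the focal subpopulation's samples are compared against the
pooled samples of all other subpopulations.  Per gene we fit an NB GLM with
log link, design ``intercept + focal indicator``, per-sample offsets
``log(size_factor)`` and a fixed gene-wise dispersion, by Fisher scoring
vectorised across genes (the two-column design admits a closed-form weighted
least-squares update).  The Wald statistic is coefficient / SE with the SE
taken from the information matrix at convergence, referred to the standard
normal; BH adjustment runs over genes with a defined p-value.

A gene is called differentially expressed (direction up/down) when
BH-adjusted p < 0.05 and |log2 fold-change| > 1; everything else is ``ns``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import CountMatrix, SampleTable
from .normalize import DispersionEstimates, SizeFactors

LN2 = np.log(2.0)

DE_COLUMNS = [
    "base_mean",
    "log2FC",
    "lfcSE",
    "stat",
    "pvalue",
    "padj",
    "direction",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Focal subpopulation vs the union of all other samples."""

    focal: str

    def indicator(self, samples: SampleTable) -> np.ndarray:
        ind = samples.group_indicator(self.focal)
        n_focal = int(ind.sum())
        n_rest = int((~ind).sum())
        if n_focal < 2:
            raise ValidationError(
                f"focal group {self.focal!r} has {n_focal} samples; need >= 2"
            )
        if n_rest < 2:
            raise ValidationError(
                f"reference group for {self.focal!r} has {n_rest} samples; need >= 2"
            )
        return ind.astype(float)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are excluded from m."""
    p = np.asarray(pvalues, dtype=float)
    defined = ~np.isnan(p)
    if defined.any() and ((p[defined] < 0) | (p[defined] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = np.full(p.shape, np.nan)
    if defined.any():
        adjusted[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return adjusted


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB deviance per gene (rows), summed over samples."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        term2 = (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
    return 2.0 * (term1 - term2).sum(axis=1)


def nb_wald_fit(
    counts: np.ndarray,
    indicator: np.ndarray,
    size_factors: np.ndarray,
    dispersions: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """Vectorised Fisher-scoring fit of the two-group NB GLM per gene.

    Returns (beta0, beta1, se1, converged) with beta on the natural-log scale.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(indicator, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    phi = np.asarray(dispersions, dtype=float)[:, None]
    n_genes = y.shape[0]
    offset = np.log(s)[None, :]

    focal = x == 1.0
    rest = ~focal
    eps = 0.5
    q1 = (y[:, focal] / s[focal]).mean(axis=1)
    q0 = (y[:, rest] / s[rest]).mean(axis=1)
    beta0 = np.log(q0 + eps)
    beta1 = np.log(q1 + eps) - np.log(q0 + eps)

    eta = np.clip(beta0[:, None] + beta1[:, None] * x[None, :] + offset, -30.0, 30.0)
    mu = np.exp(eta)
    dev = _nb_deviance(y, mu, phi)
    active = np.ones(n_genes, dtype=bool)
    converged = np.zeros(n_genes, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = active
        mu_a = mu[idx]
        phi_a = phi[idx]
        w = mu_a / (1.0 + phi_a * mu_a)
        # working response on the linear-predictor scale (offset removed)
        z = (
            beta0[idx][:, None]
            + beta1[idx][:, None] * x[None, :]
            + (y[idx] - mu_a) / np.maximum(mu_a, 1e-12)
        )
        w1 = w[:, focal].sum(axis=1)
        w0 = w[:, rest].sum(axis=1)
        z1 = (w[:, focal] * z[:, focal]).sum(axis=1) / np.maximum(w1, 1e-300)
        z0 = (w[:, rest] * z[:, rest]).sum(axis=1) / np.maximum(w0, 1e-300)
        beta0_new = z0
        beta1_new = z1 - z0
        beta0[idx] = beta0_new
        beta1[idx] = np.clip(beta1_new, -30.0, 30.0)
        eta_idx = np.clip(
            beta0[idx][:, None] + beta1[idx][:, None] * x[None, :] + offset, -30.0, 30.0
        )
        mu[idx] = np.exp(eta_idx)
        dev_new = _nb_deviance(y[idx], mu[idx], phi[idx])
        done = np.abs(dev_new - dev[idx]) / (np.abs(dev_new) + 0.1) < tol
        dev[idx] = dev_new
        converged_idx = np.where(idx)[0][done]
        converged[converged_idx] = True
        active = active & ~converged

    w = mu / (1.0 + phi * mu)
    w1 = w[:, focal].sum(axis=1)
    w0 = w[:, rest].sum(axis=1)
    with np.errstate(divide="ignore"):
        se1 = np.sqrt(1.0 / np.maximum(w1, 1e-300) + 1.0 / np.maximum(w0, 1e-300))
    return beta0, beta1, se1, converged


def de_contrast(
    counts: CountMatrix,
    samples: SampleTable,
    contrast: ContrastSpec,
    dispersions: DispersionEstimates,
    size_factors: SizeFactors,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Per-gene one-vs-rest Wald test; returns the DE table for one contrast.

    Columns: base_mean, log2FC, lfcSE, stat, pvalue, padj, direction.
    Non-converged genes get a missing p-value and are excluded from BH.
    """
    if list(counts.sample_ids) != list(samples.sample_ids):
        raise ValidationError("counts and sample table must be sample-aligned")
    indicator = contrast.indicator(samples)
    mat = counts.counts.to_numpy(float)
    s = size_factors.to_numpy()
    phi = dispersions.shrunken.loc[counts.counts.index].to_numpy(float)

    beta0, beta1, se1, conv = nb_wald_fit(mat, indicator, s, phi)
    stat = np.where(se1 > 0, beta1 / se1, np.nan)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.where(conv, pvalue, np.nan)
    padj = bh_adjust(pvalue)
    log2fc = beta1 / LN2
    lfc_se = se1 / LN2
    base_mean = (mat / s[None, :]).mean(axis=1)

    direction = np.full(mat.shape[0], "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        sig = (padj < padj_max) & (np.abs(log2fc) > lfc_min) & ~np.isnan(padj)
    direction[sig & (log2fc > 0)] = "up"
    direction[sig & (log2fc < 0)] = "down"

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2FC": log2fc,
            "lfcSE": lfc_se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "direction": direction,
        },
        index=counts.counts.index,
    )


def _round_half_away(value: float) -> int:
    return int(np.floor(value + 0.5)) if value >= 0 else -int(np.floor(-value + 0.5))


def summarize_deg_counts(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Reporting-layer summary from per-subpopulation (up, down) DEG counts.

    Totals are up + down; the final ``mean`` row holds the dataset means
    rounded to the nearest integer, half away from zero.
    """
    rows = [
        {"subpopulation": subpop, "up": int(up), "down": int(down),
         "total": int(up) + int(down)}
        for subpop, (up, down) in counts.items()
    ]
    summary = pd.DataFrame(rows, columns=["subpopulation", "up", "down", "total"])
    if len(summary):
        mean_row = {
            "subpopulation": "mean",
            "up": _round_half_away(summary["up"].mean()),
            "down": _round_half_away(summary["down"].mean()),
            "total": _round_half_away(summary["total"].mean()),
        }
        summary = pd.concat([summary, pd.DataFrame([mean_row])], ignore_index=True)
    return summary


def summarize_degs(de_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-subpopulation up/down/total DEG counts plus dataset means."""
    counts = {
        subpop: (
            int((table["direction"] == "up").sum()),
            int((table["direction"] == "down").sum()),
        )
        for subpop, table in de_tables.items()
    }
    return summarize_deg_counts(counts)
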