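"""Quantitative trait transcripts (QTTs) for lactic acid production.

For every gene j the model

    E_ij = mu_j + alpha_j * LA_i + sum_k beta_jk PC_ik + sum_k gamma_jk HF_ik + e_ij

is fitted by ordinary least squares, where ``LA_i`` is the lactic acid
concentration of sample i at the RNA sampling time, the ``PC_ik`` are scores
of expression principal components (population-structure correction,
default 3) and the ``HF_ik`` are hidden factors estimated by surrogate
variable analysis (SVA).  ``alpha_j`` is tested two-sided against zero with
a t reference on ``n - (2 + K + N)`` degrees of freedom; genes with
BH-adjusted p <= 0.001 are QTTs, classified positive or negative by the
sign of ``alpha_j``.

Hidden factors follow the two-step surrogate variable approach: the data
are residualized on the primary model matrix (intercept + phenotype by
default), the number of factors N is chosen by comparing the singular-value
variance shares of the residual matrix against a permutation null, and each
surrogate's sample scores are then re-estimated from the *original*
expression of the genes most associated with the corresponding residual
eigenvector.  Re-estimating on the original scale lets a surrogate retain
any incidental sample-level correlation with the phenotype, which is what
allows it to absorb confounding instead of silently re-injecting it.

A guard protects against self-collinearity of the design: a principal
component whose sample scores are nearly collinear with the phenotype
(|r| above ``pc_phenotype_corr_max``) would absorb the very signal being
mapped, so such components are skipped and the next-ranked ones used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .de import bh_adjust
from .errors import ValidationError
from .normalize import NormalizedExpression
from .overview import _pca_samples


def _as_sample_matrix(expression) -> tuple[np.ndarray, list[str], list[str]]:
    """Return (samples x genes array, sample_ids, gene_ids)."""
    if isinstance(expression, NormalizedExpression):
        df = expression.values
    elif isinstance(expression, pd.DataFrame):
        df = expression
    else:
        raise ValidationError("expression must be NormalizedExpression or DataFrame")
    return df.to_numpy(float).T, list(df.columns), list(df.index)


@dataclass(frozen=True)
class HiddenFactors:
    """Estimated surrogate variables: samples x N unit-variance scores."""

    scores: pd.DataFrame
    variance_shares: np.ndarray
    permutation_thresholds: np.ndarray

    @property
    def n_factors(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class QTTModelFit:
    """Per-gene OLS fit of the phenotype model."""

    coefficients: pd.DataFrame   # genes x design columns
    se_alpha: pd.Series
    t_alpha: pd.Series
    pvalue_alpha: pd.Series
    df_resid: int
    design: pd.DataFrame         # samples x design columns

    @property
    def alpha(self) -> pd.Series:
        return self.coefficients["phenotype"]


def compute_pcs(expression, n_components: int = 3) -> pd.DataFrame:
    """First principal-component scores of gene-centered expression.

    Samples are observations; returns a samples x K frame (possibly K = 0).
    """
    matrix, sample_ids, _ = _as_sample_matrix(expression)
    n = matrix.shape[0]
    if n_components > n - 1:
        raise ValidationError(f"n_components={n_components} exceeds n_samples-1={n - 1}")
    if n_components == 0:
        return pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    scores, _, _ = _pca_samples(matrix, n_components)
    return pd.DataFrame(
        scores,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
    )


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return abs(float(np.corrcoef(x, y)[0, 1]))


def select_pcs(
    pcs: pd.DataFrame,
    phenotype: np.ndarray,
    n_keep: int,
    max_abs_corr: float = 0.8,
    hidden_factors: pd.DataFrame | None = None,
    dedupe_r2: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep the first ``n_keep`` PCs usable as covariates next to the phenotype.

    Two exclusion rules, both needed for a well-conditioned design at small n:

    * a PC nearly collinear with the phenotype (|r| > ``max_abs_corr``)
      would absorb the signal being mapped (with a coherent
      phenotype-linked module, the leading PC *is* the phenotype);
    * a PC largely explained by the already-estimated surrogate variables
      plus the phenotype (joint R-squared > ``dedupe_r2``) adds little
      structure, and a near-duplicate regressor pair can amplify small
      phenotype contamination of either copy until the design
      reconstructs the phenotype outright.

    Returns (kept frame, list of excluded component names).
    """
    kept: list[str] = []
    excluded: list[str] = []
    phen = np.asarray(phenotype, float)
    n = len(phen)
    base = [np.ones(n), phen]
    if hidden_factors is not None:
        base += [hidden_factors[h].to_numpy(float) for h in hidden_factors.columns]
    base_matrix = np.column_stack(base)
    for col in pcs.columns:
        if len(kept) == n_keep:
            break
        scores = pcs[col].to_numpy()
        if _abs_corr(scores, phen) > max_abs_corr:
            excluded.append(col)
            continue
        if base_matrix.shape[1] > 1:
            proj, *_ = np.linalg.lstsq(base_matrix, scores, rcond=None)
            resid = scores - base_matrix @ proj
            total = np.square(scores - scores.mean()).sum()
            if total > 0 and 1.0 - np.square(resid).sum() / total > dedupe_r2:
                excluded.append(col)
                continue
        kept.append(col)
    return pcs[kept], excluded


def _residualize(matrix: np.ndarray, model_matrix: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(model_matrix, matrix, rcond=None)
    return matrix - model_matrix @ coef


def _variance_shares(matrix: np.ndarray) -> np.ndarray:
    s = np.linalg.svd(matrix, compute_uv=False)
    total = np.square(s).sum()
    return np.square(s) / total if total > 0 else np.zeros_like(s)


def estimate_hidden_factors(
    expression,
    model_matrix: np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
    max_factors: int | None = None,
    association_fraction: float = 0.1,
) -> HiddenFactors:
    """Two-step surrogate variable analysis.

    1. Residualize every gene on ``model_matrix`` (must include an intercept
       and the phenotype; metabolite covariates may be appended).
    2. Choose N: the number of leading residual singular values whose
       variance share exceeds the 95th percentile of shares obtained from
       ``n_permutations`` within-gene permutations of the residuals
       (re-residualized before decomposition), stopping at the first factor
       that fails.
    3. For each retained factor, re-estimate its sample scores from the
       original (centered) expression of the genes whose residual profiles
       are most correlated with the residual eigenvector.

    Scores are scaled to unit variance.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    matrix, sample_ids, _ = _as_sample_matrix(expression)
    X = np.asarray(model_matrix, float)
    if X.ndim != 2 or X.shape[0] != matrix.shape[0]:
        raise ValidationError("model matrix must be samples x covariates")
    n, p = X.shape
    if n < p + 2:
        raise ValidationError(
            f"need at least {p + 2} samples for {p} model-matrix columns, got {n}"
        )
    rng = np.random.default_rng(seed)

    resid = _residualize(matrix, X)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    total = np.square(s).sum()
    shares = np.square(s) / total if total > 0 else np.zeros_like(s)

    perm_shares = np.empty((n_permutations, len(shares)))
    for b in range(n_permutations):
        permuted = np.take_along_axis(
            resid, rng.permuted(np.broadcast_to(np.arange(n)[:, None], resid.shape), axis=0), axis=0
        )
        perm_shares[b] = _variance_shares(_residualize(permuted, X))
    thresholds = np.percentile(perm_shares, 95, axis=0)

    limit = len(shares) if max_factors is None else min(max_factors, len(shares))
    n_factors = 0
    for k in range(limit):
        if shares[k] > thresholds[k]:
            n_factors += 1
        else:
            break

    centered = matrix - matrix.mean(axis=0, keepdims=True)
    surrogates = np.empty((n, n_factors))
    n_genes = matrix.shape[1]
    n_select = max(25, int(np.ceil(association_fraction * n_genes)))
    n_select = min(n_select, n_genes)
    for k in range(n_factors):
        eigenvector = u[:, k]
        resid_c = resid - resid.mean(axis=0, keepdims=True)
        ev_c = eigenvector - eigenvector.mean()
        denom = np.sqrt(np.square(resid_c).sum(axis=0)) * np.sqrt(np.square(ev_c).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            assoc = np.abs(resid_c.T @ ev_c) / np.where(denom > 0, denom, np.inf)
        selected = np.argsort(-assoc)[:n_select]
        sub = centered[:, selected]
        u_sub, s_sub, _ = np.linalg.svd(sub, full_matrices=False)
        n_cand = min(n_factors + 2, u_sub.shape[1])
        cand_corr = [
            abs(float(np.corrcoef(u_sub[:, j], eigenvector)[0, 1]))
            if u_sub[:, j].std() > 0
            else 0.0
            for j in range(n_cand)
        ]
        best = int(np.argmax(cand_corr))
        surrogate = u_sub[:, best]
        if np.corrcoef(surrogate, eigenvector)[0, 1] < 0:
            surrogate = -surrogate
        surrogates[:, k] = surrogate / surrogate.std(ddof=1)

    scores = pd.DataFrame(
        surrogates,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"HF{k + 1}" for k in range(n_factors)],
    )
    return HiddenFactors(scores, shares, thresholds)


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify which columns are linearly explained by the others
    offenders = []
    for j, name in enumerate(design.columns):
        others = np.delete(X, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ proj
        denom = np.square(X[:, j] - X[:, j].mean()).sum()
        if denom == 0 or np.square(resid).sum() / max(denom, 1e-300) < 1e-10:
            offenders.append(name)
    raise ValidationError(f"design matrix is rank deficient; collinear columns: {offenders}")


def fit_qtt_model(
    expression,
    phenotype: np.ndarray,
    pcs: pd.DataFrame | None = None,
    hidden_factors: HiddenFactors | pd.DataFrame | None = None,
) -> QTTModelFit:
    """Per-gene OLS of expression on phenotype, PCs and hidden factors."""
    matrix, sample_ids, gene_ids = _as_sample_matrix(expression)
    n = matrix.shape[0]
    phen = np.asarray(phenotype, float)
    if phen.shape != (n,):
        raise ValidationError("phenotype length must equal the number of samples")
    if not np.all(np.isfinite(phen)):
        raise ValidationError("phenotype must be finite")

    columns = {"intercept": np.ones(n), "phenotype": phen}
    if pcs is not None and pcs.shape[1]:
        if pcs.shape[0] != n:
            raise ValidationError("PC matrix not sample-aligned with expression")
        for col in pcs.columns:
            columns[col] = pcs[col].to_numpy(float)
    hf_frame = (
        hidden_factors.scores if isinstance(hidden_factors, HiddenFactors) else hidden_factors
    )
    if hf_frame is not None and hf_frame.shape[1]:
        if hf_frame.shape[0] != n:
            raise ValidationError("hidden-factor matrix not sample-aligned with expression")
        for col in hf_frame.columns:
            columns[col] = hf_frame[col].to_numpy(float)

    design = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    _check_full_rank(design)
    X = design.to_numpy(float)
    p = X.shape[1]
    df_resid = n - p
    if df_resid < 1:
        raise ValidationError(f"no residual degrees of freedom (n={n}, p={p})")

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ matrix          # p x genes
    resid = matrix - X @ coef
    sigma2 = np.square(resid).sum(axis=0) / df_resid
    alpha_idx = list(design.columns).index("phenotype")
    se_alpha = np.sqrt(sigma2 * xtx_inv[alpha_idx, alpha_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_alpha = np.where(se_alpha > 0, coef[alpha_idx] / se_alpha, np.nan)
    pvalue = 2.0 * stats.t.sf(np.abs(t_alpha), df=df_resid)

    gene_index = pd.Index(gene_ids, name="gene_id")
    return QTTModelFit(
        coefficients=pd.DataFrame(coef.T, index=gene_index, columns=design.columns),
        se_alpha=pd.Series(se_alpha, index=gene_index, name="se"),
        t_alpha=pd.Series(t_alpha, index=gene_index, name="t"),
        pvalue_alpha=pd.Series(pvalue, index=gene_index, name="pvalue"),
        df_resid=df_resid,
        design=design,
    )


def call_qtts(fit: QTTModelFit, alpha: float = 0.001) -> pd.DataFrame:
    """BH-adjust the per-gene phenotype p-values and classify QTTs.

    The threshold is inclusive: padj == alpha is called.  Classes are
    ``positive``/``negative`` by the sign of the phenotype coefficient,
    ``none`` otherwise.
    """
    padj = bh_adjust(fit.pvalue_alpha.to_numpy())
    alpha_hat = fit.alpha.to_numpy()
    qtt_class = np.full(len(alpha_hat), "none", dtype=object)
    with np.errstate(invalid="ignore"):
        called = ~np.isnan(padj) & (padj <= alpha)
    qtt_class[called & (alpha_hat > 0)] = "positive"
    qtt_class[called & (alpha_hat < 0)] = "negative"
    return pd.DataFrame(
        {
            "alpha": alpha_hat,
            "se": fit.se_alpha.to_numpy(),
            "t": fit.t_alpha.to_numpy(),
            "pvalue": fit.pvalue_alpha.to_numpy(),
            "padj": padj,
            "qtt_class": qtt_class,
        },
        index=fit.pvalue_alpha.index,
    )


@dataclass(frozen=True)
class QTTResult:
    table: pd.DataFrame
    pcs: pd.DataFrame
    hidden_factors: HiddenFactors
    excluded_pcs: list[str] = field(default_factory=list)


def qtt_analysis(
    expression,
    phenotype: np.ndarray,
    config: AnalysisConfig | None = None,
    use_sva: bool = True,
) -> QTTResult:
    """End-to-end QTT calling: PCs, hidden factors, per-gene model, BH.

    ``use_sva=False`` drops the hidden-factor terms (for sensitivity
    analyses of the confounder correction).
    """
    config = config or AnalysisConfig()
    matrix, sample_ids, _ = _as_sample_matrix(expression)
    n = matrix.shape[0]
    phen = np.asarray(phenotype, float)

    if use_sva:
        model_matrix = np.column_stack([np.ones(n), phen])
        hfs = estimate_hidden_factors(
            expression,
            model_matrix,
            n_permutations=config.sva_permutations,
            seed=config.seed,
            max_factors=max(0, (n - 2 - config.n_pcs) // 2),
        )
    else:
        hfs = HiddenFactors(
            pd.DataFrame(index=pd.Index(sample_ids, name="sample_id")),
            np.array([]),
            np.array([]),
        )

    n_candidates = min(n - 1, config.n_pcs + 5)
    all_pcs = compute_pcs(expression, n_candidates)
    pcs, excluded = select_pcs(
        all_pcs,
        phen,
        config.n_pcs,
        config.pc_phenotype_corr_max,
        hidden_factors=hfs.scores if hfs.n_factors else None,
    )

    fit = fit_qtt_model(expression, phen, pcs, hfs)
    table = call_qtts(fit, alpha=config.qtt_padj_max)
    return QTTResult(table=table, pcs=pcs, hidden_factors=hfs, excluded_pcs=excluded)
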