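"""Global expression overviews: sample PCA and sample-sample correlation.

The PCA treats samples as observations and genes as (centered) features, as
is standard for whole-transcriptome overviews, and fixes the component signs
deterministically so repeated runs are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .normalize import NormalizedExpression


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame          # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame        # genes x components


def _pca_samples(matrix: np.ndarray, n_components: int):
    """PCA of a samples x features matrix with a deterministic sign convention.

    Each component is oriented so that its largest-magnitude feature loading
    is positive.  Returns (scores, explained_variance_ratio, loadings).
    """
    n, p = matrix.shape
    if n_components > min(n, p):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={min(n, p)}"
        )
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = np.square(s).sum()
    ratio = np.square(s) / total if total > 0 else np.zeros_like(s)
    for k in range(min(n_components, vt.shape[0])):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u[:, :n_components] * s[None, :n_components]
    loadings = vt[:n_components].T
    return scores, ratio[:n_components], loadings


def pca_overview(expression: NormalizedExpression, n_components: int = 3) -> PCAResult:
    """Sample-level PCA of normalized expression (genes as features)."""
    df = expression.values
    if df.shape[1] < 2:
        raise ValidationError("PCA requires >= 2 samples")
    scores, ratio, loadings = _pca_samples(df.to_numpy(float).T, n_components)
    comp_names = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.columns, columns=comp_names),
        explained_variance_ratio=ratio,
        loadings=pd.DataFrame(loadings, index=df.index, columns=comp_names),
    )


def sample_correlation_matrix(
    expression: NormalizedExpression, method: str = "pearson"
) -> pd.DataFrame:
    """Symmetric sample-sample correlation of whole-transcriptome profiles.

    Constant sample profiles have undefined correlation and are reported
    missing; defined diagonal entries are exactly 1.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    df = expression.values
    if df.shape[0] < 3:
        raise ValidationError("sample correlation requires >= 3 genes")
    corr = df.corr(method=method)
    constant = df.std(axis=0).to_numpy() == 0
    diag = np.where(constant, np.nan, 1.0)
    values = corr.to_numpy()
    np.fill_diagonal(values, diag)
    return pd.DataFrame(values, index=corr.index, columns=corr.columns)
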