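"""Library-size normalization and negative-binomial dispersion estimation.

Two per-sample scalings are supported: counts per million on the raw library
size (for global overviews such as PCA) and the median-of-ratios size factors
familiar from count-based differential expression, where sample j's factor is
the median over reference genes of ``count_ij / geomean_i`` and reference
genes are those expressed in every sample.

Dispersion follows the NB variance function ``var = mu + phi * mu**2``.
Per-gene dispersions are method-of-moments estimates on size-factor
normalized counts, shrunk in log space toward a log-linear mean-dispersion
trend with a fixed weight.  This is a deliberately simple, fully specified
engine; bit-equality with any particular DE package is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix

DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive scale factors, aligned with count columns."""

    factors: pd.Series

    def __post_init__(self):
        values = self.factors.to_numpy(float)
        if not np.all(np.isfinite(values)) or not np.all(values > 0):
            raise ValidationError("size factors must be finite and > 0")

    def to_numpy(self) -> np.ndarray:
        return self.factors.to_numpy(float)


@dataclass(frozen=True)
class NormalizedExpression:
    """Genes x samples real-valued expression on a stated log2 scale."""

    values: pd.DataFrame
    mode: str  # "cpm_log2" or "mor_log2"

    def __post_init__(self):
        if self.mode not in ("cpm_log2", "mor_log2"):
            raise ValidationError(f"unknown normalization mode {self.mode!r}")
        arr = self.values.to_numpy(float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("normalized expression must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class DispersionEstimates:
    """Per-gene NB dispersions: raw method-of-moments, trend, and shrunken."""

    raw: pd.Series
    trend: pd.Series
    shrunken: pd.Series
    trend_intercept: float
    trend_slope: float

    def __post_init__(self):
        for series in (self.raw, self.trend, self.shrunken):
            if (series.to_numpy(float) < DISPERSION_FLOOR - 1e-16).any():
                raise ValidationError("dispersions below floor")


def size_factors_median_ratios(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Reference genes are those with nonzero counts in every sample (positive
    geometric mean); each sample's factor is the median of its counts over
    the reference genes divided by their geometric means.
    """
    mat = counts.counts.to_numpy(float)
    reference = (mat > 0).all(axis=1)
    if not reference.any():
        raise ValidationError(
            "no gene is expressed in every sample; median-of-ratios undefined "
            "(use raw library-size normalization instead)"
        )
    log_geomean = np.log(mat[reference]).mean(axis=1)
    log_ratios = np.log(mat[reference]) - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return SizeFactors(pd.Series(factors, index=counts.counts.columns, name="size_factor"))


def normalize(
    counts: CountMatrix,
    mode: str = "cpm_log2",
    size_factors: SizeFactors | None = None,
) -> NormalizedExpression:
    """log2-scale normalized expression.

    ``cpm_log2``: log2(1 + 1e6 * count / library_size)
    ``mor_log2``: log2(1 + count / size_factor)
    """
    df = counts.counts
    if mode == "cpm_log2":
        libsize = df.sum(axis=0).to_numpy(float)
        if (libsize == 0).any():
            bad = df.columns[libsize == 0].tolist()
            raise ValidationError(f"zero library size for samples {bad}")
        values = np.log2(1.0 + 1e6 * df.to_numpy(float) / libsize[None, :])
    elif mode == "mor_log2":
        if size_factors is None:
            size_factors = size_factors_median_ratios(counts)
        values = np.log2(1.0 + df.to_numpy(float) / size_factors.to_numpy()[None, :])
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    return NormalizedExpression(
        pd.DataFrame(values, index=df.index, columns=df.columns), mode
    )


def estimate_dispersions(
    counts: CountMatrix,
    size_factors: SizeFactors,
    floor: float = DISPERSION_FLOOR,
    shrink_weight: float = 0.5,
) -> DispersionEstimates:
    """Method-of-moments dispersions with log-space shrinkage to a trend.

    phi_raw = max(floor, (var - mean) / mean^2) on normalized counts; the
    trend log(phi) = a + b*log(mean) is least-squares fitted over genes with
    phi_raw above the floor, and the final estimate is
    exp(w*log(phi_trend) + (1-w)*log(phi_raw)) with w = ``shrink_weight``.
    """
    df = counts.counts
    if df.shape[1] < 2:
        raise ValidationError("dispersion estimation requires >= 2 samples")
    norm = df.to_numpy(float) / size_factors.to_numpy()[None, :]
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mean > 0, (var - mean) / np.square(mean), floor)
    raw = np.maximum(floor, np.nan_to_num(raw, nan=floor))

    informative = (raw > floor) & (mean > 0)
    if informative.sum() >= 2:
        x = np.log(mean[informative])
        y = np.log(raw[informative])
        slope, intercept = np.polyfit(x, y, 1)
    else:
        # no mean-dispersion signal: flat trend at the typical dispersion
        slope = 0.0
        intercept = float(np.log(np.median(raw)))
    with np.errstate(divide="ignore"):
        trend = np.where(
            mean > 0, np.exp(intercept + slope * np.log(np.maximum(mean, 1e-300))), floor
        )
    trend = np.maximum(floor, trend)
    shrunken = np.exp(
        shrink_weight * np.log(trend) + (1.0 - shrink_weight) * np.log(raw)
    )
    shrunken = np.maximum(floor, shrunken)
    idx = df.index
    return DispersionEstimates(
        raw=pd.Series(raw, index=idx, name="dispersion_raw"),
        trend=pd.Series(trend, index=idx, name="dispersion_trend"),
        shrunken=pd.Series(shrunken, index=idx, name="dispersion"),
        trend_intercept=float(intercept),
        trend_slope=float(slope),
    )
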