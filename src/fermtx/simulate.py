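"""Synthetic fermentation-transcriptome generator with ground truth.

The generator emulates the statistical structure the analysis assumes: 23
samples in six subpopulations (one group of three), negative-binomial counts
with a log-normal baseline and per-sample size factors, group-specific
spiked fold-changes (the DEGs), a phenotype-linked gene module whose log2
mean tracks lactic acid (the QTTs, including three designated focal
"LDH-like" genes), sparse hidden batch factors, and an end-point metabolite
table whose rank correlations hit configured targets (lactic-glycerol
-0.85, glycerol-ethanol 0.66) through a Gaussian copula on the normal
scores of the realized lactic acid values.

Counts follow the mean/dispersion NB parameterization used everywhere in
this package: ``var = mu + phi * mu**2``.  All randomness flows from a
single seed through one ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import CountMatrix, GeneSetCollection, SampleTable

DEFAULT_SUBPOPULATIONS = (
    "Asia",
    "Americas",
    "Canada-trees",
    "Europe-Domestic-1",
    "Europe-Domestic-2",
    "Europe-Mix",
)


@dataclass
class GeneratorConfig:
    """Study-scale defaults: 23 samples, six subpopulations, ~5000 genes.

    Lactic acid group means follow the three production tiers of the study
    system (about 1 g/L for the Asian subpopulation, 3.5 g/L for the other
    wild groups and Europe/Domestic-1, 7.5 g/L for the high-producing
    anthropized groups); the within-group standard deviation of 0.6 g/L
    reflects strain-to-strain spread around each tier.
    """

    n_genes: int = 5000
    subpopulations: tuple[str, ...] = DEFAULT_SUBPOPULATIONS
    group_sizes: tuple[int, ...] = (3, 4, 4, 4, 4, 4)
    # phenotype (lactic acid, g/L)
    la_group_means: tuple[float, ...] = (1.0, 3.5, 3.5, 3.5, 7.5, 7.5)
    la_within_sd: float = 0.6
    # baseline expression and noise
    log2_baseline_mean: float = 7.0
    log2_baseline_sd: float = 1.8
    dispersion: float = 0.05
    size_factor_log_sd: float = 0.25
    # spiked differential expression
    n_de_per_group: int = 60
    de_lfc_range: tuple[float, float] = (1.0, 4.0)
    de_down_fraction: float = 0.7
    # phenotype-linked (QTT) module
    qtt_fraction: float = 0.05
    qtt_alpha: float = 1.0
    n_focal_genes: int = 3
    # hidden batch factors
    n_hidden_factors: int = 1
    hf_loading_fraction: float = 0.3
    hf_loading_sd: float = 0.5
    hf_phenotype_corr: float = 0.0
    # end-point metabolites (rank-correlation targets and marginals)
    lactic_glycerol_rho: float = -0.85
    glycerol_ethanol_rho: float = 0.66
    glycerol_mean: float = 6.0
    glycerol_sd: float = 1.2
    ethanol_mean: float = 8.0
    ethanol_sd: float = 0.8
    residual_sugars_mean: float = 25.0
    residual_sugars_sd: float = 12.0

    def validate(self) -> None:
        if len(self.subpopulations) != len(self.group_sizes):
            raise ValidationError("subpopulations and group_sizes length mismatch")
        if len(self.la_group_means) != len(self.group_sizes):
            raise ValidationError("la_group_means and group_sizes length mismatch")
        if any(size < 2 for size in self.group_sizes):
            raise ValidationError("every subpopulation needs >= 2 samples")
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10")
        for name in ("la_within_sd", "log2_baseline_sd", "glycerol_sd", "ethanol_sd",
                     "residual_sugars_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not 0 <= self.qtt_fraction < 1:
            raise ValidationError("qtt_fraction must be in [0, 1)")
        if not 0 <= self.de_down_fraction <= 1:
            raise ValidationError("de_down_fraction must be in [0, 1]")
        for rho in (self.lactic_glycerol_rho, self.glycerol_ethanol_rho,
                    self.hf_phenotype_corr):
            if not -1 < rho < 1:
                raise ValidationError("correlation targets must lie in (-1, 1)")
        n_special = (
            len(self.group_sizes) * self.n_de_per_group
            + int(np.ceil(self.qtt_fraction * self.n_genes))
        )
        if n_special > self.n_genes:
            raise ValidationError("spiked gene lists exceed n_genes")

    def large_n(self, factor: int = 4) -> "GeneratorConfig":
        """Scaled-up profile (group sizes x factor) for power checks."""
        clone = GeneratorConfig(**asdict(self))
        clone.group_sizes = tuple(int(s * factor) for s in self.group_sizes)
        return clone

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("subpopulations", "group_sizes", "la_group_means", "de_lfc_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated dataset, keyed by gene ID."""

    de_genes: pd.DataFrame          # gene_id, subpopulation, true_log2fc
    qtt_genes: pd.DataFrame         # gene_id, true_alpha
    focal_genes: tuple[str, ...]
    hidden_factor_scores: pd.DataFrame    # samples x factors
    hidden_factor_loadings: pd.DataFrame  # loaded genes x factors
    size_factors: pd.Series
    la_true: pd.Series


@dataclass(frozen=True)
class SyntheticDataset:
    counts: CountMatrix
    samples: SampleTable
    truth: SyntheticTruth

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation giving a target Spearman under a Gaussian copula."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def simulate_dataset(config: GeneratorConfig, seed: int = 0) -> SyntheticDataset:
    """Draw one dataset plus its ground truth from a single seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    n_groups = len(config.group_sizes)
    n = int(sum(config.group_sizes))
    G = config.n_genes

    sample_ids = [f"Lt{i + 1:03d}" for i in range(n)]
    group_labels = np.repeat(np.arange(n_groups), config.group_sizes)
    subpop = [config.subpopulations[g] for g in group_labels]
    gene_ids = [f"SYNG{i + 1:05d}" for i in range(G)]

    # phenotype: lactic acid at sampling, group tier + strain-level spread
    la = np.array(
        [config.la_group_means[g] for g in group_labels]
    ) + rng.normal(0.0, config.la_within_sd, size=n)
    la = np.maximum(la, 0.05)
    la_centered = la - la.mean()

    # baseline log2 means and per-sample size factors
    log2_base = rng.normal(config.log2_baseline_mean, config.log2_baseline_sd, size=G)
    size_factors = np.exp(rng.normal(0.0, config.size_factor_log_sd, size=n))
    size_factors /= np.exp(np.mean(np.log(size_factors)))

    # disjoint spiked gene sets: per-group DE spikes, then the QTT module
    n_qtt = int(np.ceil(config.qtt_fraction * G))
    n_special = n_groups * config.n_de_per_group + n_qtt
    special = rng.choice(G, size=n_special, replace=False)
    de_idx = special[: n_groups * config.n_de_per_group].reshape(
        n_groups, config.n_de_per_group
    )
    qtt_idx = special[n_groups * config.n_de_per_group:]

    log2_mu = np.tile(log2_base[:, None], (1, n))

    de_rows = []
    lo, hi = config.de_lfc_range
    for g in range(n_groups):
        magnitudes = rng.uniform(lo, hi, size=config.n_de_per_group)
        signs = np.where(
            rng.random(config.n_de_per_group) < config.de_down_fraction, -1.0, 1.0
        )
        lfcs = magnitudes * signs
        members = group_labels == g
        for gi, lfc in zip(de_idx[g], lfcs):
            log2_mu[gi, members] += lfc
            de_rows.append(
                {
                    "gene_id": gene_ids[gi],
                    "subpopulation": config.subpopulations[g],
                    "true_log2fc": float(lfc),
                }
            )

    # phenotype-linked module: log2 mean tracks centered lactic acid
    qtt_rows = []
    for gi in qtt_idx:
        log2_mu[gi] += config.qtt_alpha * la_centered
        qtt_rows.append({"gene_id": gene_ids[gi], "true_alpha": config.qtt_alpha})
    focal = tuple(
        gene_ids[gi] for gi in qtt_idx[: min(config.n_focal_genes, len(qtt_idx))]
    )

    # hidden batch factors: sparse gene loadings, optional phenotype correlation
    hf_scores = np.zeros((n, config.n_hidden_factors))
    hf_loading_rows = {}
    if config.n_hidden_factors:
        la_std = (la - la.mean()) / la.std()
        for k in range(config.n_hidden_factors):
            noise = rng.normal(size=n)
            noise = (noise - noise.mean()) / noise.std()
            rho = config.hf_phenotype_corr if k == 0 else 0.0
            h = rho * la_std + np.sqrt(1.0 - rho**2) * noise
            hf_scores[:, k] = h
            loaded = rng.random(G) < config.hf_loading_fraction
            loadings = np.where(loaded, rng.normal(0.0, config.hf_loading_sd, size=G), 0.0)
            log2_mu += np.outer(loadings, h)
            for gi in np.nonzero(loaded)[0]:
                hf_loading_rows.setdefault(gene_ids[gi], {})[f"HF{k + 1}"] = float(
                    loadings[gi]
                )

    # NB sampling: gamma-Poisson mixture with var = mu + phi * mu^2
    mu = np.exp2(np.clip(log2_mu, -20.0, 26.0)) * size_factors[None, :]
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    # end-point metabolites via a Gaussian copula anchored on realized lactic
    lactic_final = la * (7.5 / 4.5) + rng.normal(0.0, 0.2, size=n)
    order = np.argsort(np.argsort(lactic_final))
    z_la = _normal_scores(order, n)
    r_lg = _spearman_to_pearson(config.lactic_glycerol_rho)
    r_ge = _spearman_to_pearson(config.glycerol_ethanol_rho)
    r_le = r_lg * r_ge  # conditional independence given glycerol
    cov = np.array([[1.0, r_lg, r_le], [r_lg, 1.0, r_ge], [r_le, r_ge, 1.0]])
    chol = np.linalg.cholesky(cov)
    eps = rng.normal(size=(2, n))
    z_gly = chol[1, 0] * z_la + chol[1, 1] * eps[0]
    z_eth = chol[2, 0] * z_la + chol[2, 1] * eps[0] + chol[2, 2] * eps[1]
    glycerol = config.glycerol_mean + config.glycerol_sd * z_gly
    ethanol = config.ethanol_mean + config.ethanol_sd * z_eth

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "strain": sample_ids,
            "subpopulation": subpop,
            "lactic_acid_30h": np.round(la, 3),
            "lactic_acid_final": np.round(lactic_final, 3),
            "glycerol": np.round(glycerol, 3),
            "ethanol": np.round(ethanol, 3),
            "residual_sugars": np.round(
                np.maximum(
                    rng.normal(config.residual_sugars_mean, config.residual_sugars_sd, n),
                    0.0,
                ),
                2,
            ),
            "acetic_acid": np.round(np.maximum(rng.normal(0.3, 0.1, n), 0.0), 3),
            "ph": np.round(rng.normal(3.4, 0.12, n), 2),
            "total_acidity": np.round(np.maximum(rng.normal(5.0, 1.0, n), 0.5), 2),
            "pan": np.round(np.maximum(rng.normal(25.0, 6.0, n), 15.0), 1),
            "ammonia": np.round(np.maximum(rng.normal(10.0, 3.0, n), 0.0), 1),
        }
    )

    loadings_frame = (
        pd.DataFrame.from_dict(hf_loading_rows, orient="index").fillna(0.0).sort_index()
        if hf_loading_rows
        else pd.DataFrame()
    )
    truth = SyntheticTruth(
        de_genes=pd.DataFrame(
            de_rows, columns=["gene_id", "subpopulation", "true_log2fc"]
        ),
        qtt_genes=pd.DataFrame(qtt_rows, columns=["gene_id", "true_alpha"]),
        focal_genes=focal,
        hidden_factor_scores=pd.DataFrame(
            hf_scores,
            index=pd.Index(sample_ids, name="sample_id"),
            columns=[f"HF{k + 1}" for k in range(config.n_hidden_factors)],
        ),
        hidden_factor_loadings=loadings_frame,
        size_factors=pd.Series(size_factors, index=sample_ids, name="size_factor"),
        la_true=pd.Series(la, index=sample_ids, name="lactic_acid_30h"),
    )
    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    )
    return SyntheticDataset(count_matrix, SampleTable(samples), truth)


def _normal_scores(rank_zero_based: np.ndarray, n: int) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf((rank_zero_based + 0.5) / n)


def synthetic_gene_sets(dataset: SyntheticDataset, seed: int = 0) -> GeneSetCollection:
    """Four pathway-style gene sets over the synthetic gene universe.

    The glycolysis and fermentation sets are seeded with phenotype-linked
    module genes, the TCA and electron-transport sets with group-spiked DEGs,
    so enrichment and accumulated-FC statistics have planted signal.
    """
    rng = np.random.default_rng(seed)
    genes = dataset.counts.gene_ids
    qtt = list(dataset.truth.qtt_genes["gene_id"])
    de = list(dict.fromkeys(dataset.truth.de_genes["gene_id"]))
    background = [g for g in genes if g not in set(qtt) | set(de)]

    def build(signal: list[str], n_signal: int, n_background: int) -> tuple[str, ...]:
        picked_signal = list(
            rng.choice(signal, size=min(n_signal, len(signal)), replace=False)
        )
        picked_bg = list(
            rng.choice(background, size=min(n_background, len(background)), replace=False)
        )
        return tuple(picked_signal + picked_bg)

    sets = {
        "glycolysis": build(qtt, 15, 10),
        "fermentation_superpathway": build(qtt, 20, 15),
        "tca_cycle": build(de, 15, 10),
        "electron_transport_chain": build(de, 20, 15),
    }
    descriptions = {
        "glycolysis": "synthetic glycolysis-like set seeded with phenotype-linked genes",
        "fermentation_superpathway": "synthetic fermentation set seeded with phenotype-linked genes",
        "tca_cycle": "synthetic TCA-like set seeded with spiked DEGs",
        "electron_transport_chain": "synthetic respiratory-chain set seeded with spiked DEGs",
    }
    return GeneSetCollection(sets, descriptions)


def empirical_diagnostics(dataset: SyntheticDataset, config: GeneratorConfig) -> dict:
    """Realized-versus-configured summaries of a simulated dataset.

    Reports the median method-of-moments dispersion (mean-variance check),
    per-group phenotype means, and realized metabolite rank correlations
    against their copula targets.
    """
    from .correlate import spearman
    from .errors import ValidationError as _VE
    from .normalize import size_factors_median_ratios

    counts = dataset.counts.counts.to_numpy(float)
    try:
        factors = size_factors_median_ratios(dataset.counts).to_numpy()
        counts = counts / factors[None, :]
    except _VE:
        pass  # no reference gene: fall back to raw counts
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mean > 0, (var - mean) / np.square(mean), np.nan)
    median_phi = float(np.nanmedian(phi))

    table = dataset.samples.table
    group_means = (
        table.groupby("subpopulation", sort=False)["lactic_acid_30h"].mean().to_dict()
    )
    lac_gly = spearman(table["lactic_acid_final"], table["glycerol"])
    gly_eth = spearman(table["glycerol"], table["ethanol"])
    return {
        "median_mom_dispersion": median_phi,
        "configured_dispersion": config.dispersion,
        "la_group_means": {k: float(v) for k, v in group_means.items()},
        "lactic_glycerol_rho": lac_gly.rho,
        "lactic_glycerol_target": config.lactic_glycerol_rho,
        "glycerol_ethanol_rho": gly_eth.rho,
        "glycerol_ethanol_target": config.glycerol_ethanol_rho,
    }
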