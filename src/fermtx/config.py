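"""Analysis thresholds and run-level settings.

Defaults are the thresholds used throughout the study design this package
implements: a gene is differentially expressed at BH-adjusted p < 0.05 and
|log2 fold-change| > 1 (a 2-fold change); cluster-specific signatures
additionally require |log2FC| > 1.6 (about 3-fold) and an adjusted-p rank in
the top half of same-direction DEGs; quantitative trait transcripts are
called at BH-adjusted p <= 0.001; correlation-network edges at unadjusted
p < 0.05; gene-set enrichment at BH-adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ValidationError


@dataclass
class AnalysisConfig:
    # differential expression
    de_padj_max: float = 0.05
    de_lfc_min: float = 1.0
    # cluster-specific signatures
    css_lfc_min: float = 1.6
    css_rank_fraction: float = 0.5
    # quantitative trait transcripts
    qtt_padj_max: float = 0.001
    n_pcs: int = 3
    pc_phenotype_corr_max: float = 0.8
    sva_permutations: int = 100
    phenotype_column: str = "lactic_acid_30h"
    # correlation networks
    network_p_max: float = 0.05
    network_adjust: bool = False
    # enrichment
    enrichment_padj_max: float = 0.05
    # expression scales: PCA overview uses cpm_log2, the QTT model mor_log2
    overview_mode: str = "cpm_log2"
    qtt_expression_mode: str = "mor_log2"
    seed: int = 17

    def __post_init__(self):
        positive = {
            "de_padj_max": self.de_padj_max,
            "de_lfc_min": self.de_lfc_min,
            "css_lfc_min": self.css_lfc_min,
            "css_rank_fraction": self.css_rank_fraction,
            "qtt_padj_max": self.qtt_padj_max,
            "network_p_max": self.network_p_max,
            "enrichment_padj_max": self.enrichment_padj_max,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.n_pcs < 0:
            raise ValidationError("n_pcs must be >= 0")
        if self.sva_permutations < 1:
            raise ValidationError("sva_permutations must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
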