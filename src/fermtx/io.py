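"""Dataset containers and readers for the tabular formats every stage touches.

The pipeline works on three inputs: a gene-level count matrix (plain TSV or
featureCounts-style output), a sample metadata table (strain, subpopulation,
lactic acid at the RNA sampling time, optional end-point metabolites), and
gene sets in GMT format.  All containers are thin wrappers around pandas
objects that enforce the structural invariants the downstream statistics
rely on (unique IDs, integral non-negative counts, matching sample sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: annotation columns emitted by featureCounts before the per-sample counts
FEATURECOUNTS_ANNOTATION = ("Chr", "Start", "End", "Strand", "Length")

#: metadata columns recognised as numeric metabolite measurements
METABOLITE_COLUMNS = (
    "lactic_acid_30h",
    "lactic_acid_final",
    "residual_sugars",
    "glycerol",
    "ethanol",
    "acetic_acid",
    "ph",
    "total_acidity",
    "pan",
    "ammonia",
)


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples matrix of raw, non-negative, integral read counts."""

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if values.size:
            if np.isnan(values.astype(float)).any():
                raise ValidationError("counts contain missing values")
            if (values < 0).any():
                gi, sj = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at gene {df.index[gi]!r}, sample {df.columns[sj]!r}"
                )
            if not np.allclose(values, np.round(values)):
                gi, sj = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise ValidationError(
                    f"non-integral count at gene {df.index[gi]!r}, sample {df.columns[sj]!r}"
                )
        if not np.issubdtype(values.dtype, np.integer):
            object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def drop_all_zero_genes(self) -> "CountMatrix":
        """Remove genes with zero counts in every sample (undefined statistics)."""
        keep = self.counts.sum(axis=1) > 0
        return CountMatrix(self.counts.loc[keep])

    def reorder_samples(self, sample_ids: list[str]) -> "CountMatrix":
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise ValidationError(f"unknown sample IDs: {sorted(missing)}")
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def __eq__(self, other):
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: strain, subpopulation, phenotype and metabolites."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        for col in ("sample_id", "subpopulation"):
            if col not in df.columns:
                raise ValidationError(f"sample table missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        la = df.get("lactic_acid_30h")
        if la is not None and (pd.to_numeric(la, errors="coerce").dropna() < 0).any():
            raise ValidationError("lactic_acid_30h must be non-negative")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def subpopulations(self) -> list[str]:
        """Subpopulation labels in first-appearance order."""
        return list(dict.fromkeys(self.table["subpopulation"]))

    def group_sizes(self) -> dict[str, int]:
        return self.table["subpopulation"].value_counts().to_dict()

    def group_indicator(self, subpopulation: str) -> np.ndarray:
        return (self.table["subpopulation"] == subpopulation).to_numpy()

    def phenotype(self, column: str = "lactic_acid_30h") -> np.ndarray:
        if column not in self.table.columns:
            raise ValidationError(
                f"phenotype column {column!r} absent from sample table; "
                f"available columns: {list(self.table.columns)}"
            )
        values = pd.to_numeric(self.table[column], errors="coerce").to_numpy(float)
        if np.isnan(values).any():
            raise ValidationError(f"phenotype column {column!r} has missing values")
        return values

    def metabolite_frame(self) -> pd.DataFrame:
        """Numeric metabolite columns (missing values allowed), indexed by sample."""
        cols = [c for c in METABOLITE_COLUMNS if c in self.table.columns]
        out = self.table[cols].apply(pd.to_numeric, errors="coerce")
        out.index = pd.Index(self.table["sample_id"], name="sample_id")
        return out

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. glycolysis, TCA) with per-set deduplicated members."""

    sets: Mapping[str, tuple[str, ...]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def restrict_to(self, universe: set[str]) -> "GeneSetCollection":
        kept = {
            name: tuple(g for g in members if g in universe)
            for name, members in self.sets.items()
        }
        kept = {name: members for name, members in kept.items() if members}
        return GeneSetCollection(kept, dict(self.descriptions))

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *members]) + "\n")


@dataclass(frozen=True)
class ValidatedDataset:
    """Count matrix and sample table with matched, identically ordered samples."""

    counts: CountMatrix
    samples: SampleTable


def read_counts(path, dialect: str = "plain_tsv") -> CountMatrix:
    """Read a gene-level count matrix.

    ``plain_tsv``: header row of sample IDs, first column gene IDs.
    ``featurecounts``: optional leading ``#`` comment line, then a header
    ``Geneid  Chr  Start  End  Strand  Length  <sample...>``; the five
    annotation columns are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"counts file not found: {path}")
    if dialect not in ("plain_tsv", "featurecounts"):
        raise ValueError(f"unknown counts dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected gene ID column plus >=1 sample column")
    gene_col = df.columns[0]
    if dialect == "featurecounts":
        missing = [c for c in FEATURECOUNTS_ANNOTATION if c not in df.columns]
        if missing:
            raise ParseError(
                f"{path}: featurecounts dialect missing annotation columns {missing}"
            )
        df = df.drop(columns=list(FEATURECOUNTS_ANNOTATION))
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    parsed = pd.DataFrame(index=df.index)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
        if numeric.isna().any():
            gene = df.index[numeric.isna().to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: missing count at gene {gene!r}, sample {col!r}")
        if (numeric < 0).any():
            gene = df.index[(numeric < 0).to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: negative count {numeric[gene]} at gene {gene!r}, sample {col!r}"
            )
        parsed[col] = numeric
    try:
        return CountMatrix(parsed)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_sample_table(path) -> SampleTable:
    """Read the sample metadata TSV (required: sample_id, subpopulation)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"sample table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "subpopulation") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if col in METABOLITE_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleTable(df)


def read_gene_sets(path) -> GeneSetCollection:
    """Read gene sets from a GMT file: set_id, description, then member IDs."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"gene set file not found: {path}")
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            sets[name] = tuple(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def validate_dataset(counts: CountMatrix, samples: SampleTable) -> ValidatedDataset:
    """Match the two sample ID sets and reorder count columns to table order.

    The sample table is the single source of truth for sample order, so the
    design matrices built downstream always align with the count columns.
    """
    count_ids = set(counts.sample_ids)
    table_ids = set(samples.sample_ids)
    if count_ids != table_ids:
        diff = sorted(count_ids.symmetric_difference(table_ids))
        raise ValidationError(
            f"sample IDs of counts and sample table differ; symmetric difference: {diff}"
        )
    ordered = counts.reorder_samples(samples.sample_ids)
    logger.info(
        "validated dataset: %d genes, %d samples, %d subpopulations",
        ordered.shape[0],
        ordered.shape[1],
        len(samples.subpopulations),
    )
    return ValidatedDataset(ordered, samples)
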