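"""End-to-end orchestration: normalize -> DE -> enrichment -> CSS -> focal
correlations -> QTT -> metabolite correlations, with a machine-readable run
manifest.

Stages communicate through files so any stage can be re-run or inspected in
isolation; the manifest records the configuration snapshot, the seed, and
every output with its row count, which is enough to re-execute the run.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .correlate import (
    accumulated_fc_table,
    build_network,
    enrich,
    focal_gene_correlations,
    metabolite_correlations,
    network_edge_table,
)
from .css import css_candidates, css_counts, unique_css
from .de import ContrastSpec, de_contrast, summarize_degs
from .errors import PipelineStageError, ValidationError
from .io import CountMatrix, GeneSetCollection, SampleTable, validate_dataset
from .normalize import estimate_dispersions, normalize, size_factors_median_ratios
from .qtt import qtt_analysis

logger = logging.getLogger(__name__)


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", label)


@dataclass
class RunManifest:
    config: dict
    stages: list
    version: str
    started: float
    finished: float | None = None
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "tool": "fermtx",
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "started": self.started,
            "finished": self.finished,
            "failed_stage": self.failed_stage,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool) -> dict:
    frame.to_csv(path, sep="\t", index=index)
    return {"path": path.name, "rows": int(len(frame))}


def run_pipeline(
    counts: CountMatrix,
    samples: SampleTable,
    outdir,
    gene_sets: GeneSetCollection | None = None,
    focal_genes: list[str] | None = None,
    config: AnalysisConfig | None = None,
) -> RunManifest:
    """Execute every stage on an in-memory dataset, writing TSVs to outdir."""
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(), stages=[], version=__version__, started=time.time()
    )
    manifest_path = outdir / "manifest.json"

    def stage(name):
        def decorator(fn):
            try:
                outputs = fn()
            except Exception as exc:
                manifest.failed_stage = name
                manifest.finished = time.time()
                manifest.write(manifest_path)
                raise PipelineStageError(name, str(exc)) from exc
            manifest.stages.append({"stage": name, "outputs": outputs})
            logger.info("stage %s: %s", name, outputs)

        return decorator

    state: dict = {}

    @stage("validate")
    def _validate():
        dataset = validate_dataset(counts, samples)
        filtered = dataset.counts.drop_all_zero_genes()
        state["counts"] = filtered
        state["samples"] = dataset.samples
        return [
            {
                "genes": filtered.shape[0],
                "samples": filtered.shape[1],
                "subpopulations": len(dataset.samples.subpopulations),
            }
        ]

    @stage("normalize")
    def _normalize():
        sf = size_factors_median_ratios(state["counts"])
        state["size_factors"] = sf
        state["cpm"] = normalize(state["counts"], "cpm_log2")
        state["mor"] = normalize(state["counts"], "mor_log2", sf)
        state["dispersions"] = estimate_dispersions(state["counts"], sf)
        frame = sf.factors.rename_axis("sample_id").reset_index()
        return [_write_tsv(frame, outdir / "size_factors.tsv", index=False)]

    @stage("differential_expression")
    def _de():
        outputs = []
        tables = {}
        for subpop in state["samples"].subpopulations:
            table = de_contrast(
                state["counts"],
                state["samples"],
                ContrastSpec(subpop),
                state["dispersions"],
                state["size_factors"],
                padj_max=config.de_padj_max,
                lfc_min=config.de_lfc_min,
            )
            tables[subpop] = table
            outputs.append(
                _write_tsv(
                    table.rename_axis("gene_id").reset_index(),
                    outdir / f"de_{_safe_name(subpop)}.tsv",
                    index=False,
                )
            )
        state["de_tables"] = tables
        summary = summarize_degs(tables)
        outputs.append(_write_tsv(summary, outdir / "deg_summary.tsv", index=False))
        return outputs

    @stage("enrichment")
    def _enrich():
        if gene_sets is None or len(gene_sets) == 0:
            return [{"skipped": "no gene sets supplied"}]
        outputs = []
        universe = set(state["counts"].gene_ids)
        restricted = gene_sets.restrict_to(universe)
        for subpop, table in state["de_tables"].items():
            degs = table.index[table["direction"].isin(["up", "down"])]
            result = enrich(
                degs, universe, restricted, padj_max=config.enrichment_padj_max
            )
            outputs.append(
                _write_tsv(
                    result, outdir / f"enrichment_{_safe_name(subpop)}.tsv", index=False
                )
            )
        acc = accumulated_fc_table(state["de_tables"], restricted)
        outputs.append(_write_tsv(acc, outdir / "accumulated_fc.tsv", index=False))
        return outputs

    @stage("css")
    def _css():
        candidates = css_candidates(
            state["de_tables"],
            lfc_min=config.css_lfc_min,
            rank_fraction=config.css_rank_fraction,
        )
        table = unique_css(candidates)
        counts_table = css_counts(table)
        return [
            _write_tsv(table, outdir / "css.tsv", index=False),
            _write_tsv(counts_table, outdir / "css_counts.tsv", index=False),
        ]

    @stage("focal_correlations")
    def _corr():
        if not focal_genes:
            return [{"skipped": "no focal genes supplied"}]
        corr = focal_gene_correlations(state["mor"].values, list(focal_genes))
        graph = build_network(
            corr, p_threshold=config.network_p_max, adjust=config.network_adjust
        )
        edges = network_edge_table(graph)
        nx.write_graphml(graph, outdir / "network.graphml")
        return [
            _write_tsv(corr, outdir / "focal_correlations.tsv", index=False),
            _write_tsv(edges, outdir / "network_edges.tsv", index=False),
            {"path": "network.graphml", "rows": graph.number_of_edges()},
        ]

    @stage("qtt")
    def _qtt():
        table = state["samples"].table
        if config.phenotype_column not in table.columns:
            return [
                {"skipped": f"phenotype column {config.phenotype_column!r} absent"}
            ]
        expression = state["mor"] if config.qtt_expression_mode == "mor_log2" else state["cpm"]
        phenotype = state["samples"].phenotype(config.phenotype_column)
        result = qtt_analysis(expression, phenotype, config)
        outputs = [
            _write_tsv(
                result.table.rename_axis("gene_id").reset_index(),
                outdir / "qtt.tsv",
                index=False,
            ),
            _write_tsv(
                result.pcs.reset_index(), outdir / "qtt_pc_scores.tsv", index=False
            ),
            _write_tsv(
                result.hidden_factors.scores.reset_index(),
                outdir / "qtt_hf_scores.tsv",
                index=False,
            ),
        ]
        if result.excluded_pcs:
            outputs.append({"excluded_pcs": result.excluded_pcs})
        return outputs

    @stage("metabolite_correlations")
    def _metab():
        metab = state["samples"].metabolite_frame()
        if metab.shape[1] < 2:
            return [{"skipped": "fewer than two metabolite columns"}]
        rho, pval, nobs = metabolite_correlations(metab)
        return [
            _write_tsv(rho, outdir / "metabolite_rho.tsv", index=True),
            _write_tsv(pval, outdir / "metabolite_pvalues.tsv", index=True),
            _write_tsv(nobs, outdir / "metabolite_n.tsv", index=True),
        ]

    manifest.finished = time.time()
    manifest.write(manifest_path)
    return manifest


def run_pipeline_from_files(
    counts_path,
    samples_path,
    outdir,
    gene_sets_path=None,
    focal_genes: list[str] | None = None,
    config: AnalysisConfig | None = None,
    counts_dialect: str = "plain_tsv",
) -> RunManifest:
    from .io import read_counts, read_gene_sets, read_sample_table

    if not Path(counts_path).exists():
        raise PipelineStageError("read_inputs", f"counts file not found: {counts_path}")
    counts = read_counts(counts_path, dialect=counts_dialect)
    samples = read_sample_table(samples_path)
    gene_sets = read_gene_sets(gene_sets_path) if gene_sets_path else None
    return run_pipeline(
        counts,
        samples,
        outdir,
        gene_sets=gene_sets,
        focal_genes=focal_genes,
        config=config,
    )
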