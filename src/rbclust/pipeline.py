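"""End-to-end pipeline: annotate-utrs -> scan -> classify -> overlap ->
enrich -> isoform-assoc, with a JSON summary of the headline tallies.

Outputs are written deterministically (sorted records, fixed float
formatting), so re-running with an identical configuration and seed
yields byte-identical TSV/BED/JSON files.  On any stage failure the
partial outputs of the run are removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import classify, enrichment, isoforms, peaks as peaks_mod, scanner
from .annotation import read_annotation, write_gff3
from .genome import read_fasta, write_fasta
from .params import AnalysisParameters
from .simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    simulate_peaks,
    write_expression_tsv,
    write_peaks_bed,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("annotate-utrs", "scan", "classify", "overlap", "enrich", "isoform-assoc")


@dataclass
class RunConfig:
    """Paths + parameters describing one pipeline run."""

    outdir: Path
    fasta: Optional[Path] = None
    annotation: Optional[Path] = None
    annotation_dialect: str = "gff3"
    peaks: Optional[Path] = None
    peaks_format: str = "bed6+2"
    expression: Optional[Path] = None
    stages: Sequence[str] = ALL_STAGES
    params: AnalysisParameters = field(default_factory=AnalysisParameters)
    simulation: Optional[SimulationConfig] = None
    background_mode: str = "introns"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.simulation is None:
            for name in ("fasta", "annotation"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} path required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} input not found: {p}")
            for name in ("peaks", "expression"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name} input not found: {p}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; return the summary dictionary."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    summary: dict = {"parameters": config.params.to_dict(), "stages": list(config.stages)}
    stage = "setup"
    try:
        if config.simulation is not None:
            stage = "simulate"
            genome, genes, truth = simulate_genome(config.simulation)
            write_fasta(genome, out("genome.fa"))
            write_gff3(genes, out("annotation.gff3"))
            truth_peaks = simulate_peaks(genes, truth, config.simulation)
            write_peaks_bed(truth_peaks, out("peaks.bed"))
            expr = simulate_expression(truth.genes, truth.strata, config.simulation)
            write_expression_tsv(expr, out("expression.tsv"))
            truth.to_json(out("truth.json"))
            peaks_path: Optional[Path] = outdir / "peaks.bed"
            expr_path: Optional[Path] = outdir / "expression.tsv"
        else:
            stage = "load"
            genome = read_fasta(config.fasta)
            genes = read_annotation(config.annotation, config.annotation_dialect)
            peaks_path = config.peaks
            expr_path = config.expression

        logger.info("loaded %d genes, %d chromosomes", len(genes), len(list(genome)))
        summary["n_genes"] = len(genes)

        if "annotate-utrs" in config.stages:
            stage = "annotate-utrs"
            write_gff3(genes, out("annotation_with_utrs.gff3"))

        clusters = None
        if {"scan", "classify", "overlap", "enrich"} & set(config.stages):
            stage = "scan"
            result = scanner.scan_genome_for_clusters(genes, genome, config.params)
            clusters = result.clusters
            summary["n_clusters"] = len(clusters)
            summary["n_genes_with_clusters"] = len(result.genes_with_clusters)
            logger.info("called %d clusters in %d genes", len(clusters),
                        len(result.genes_with_clusters))

        if "classify" in config.stages:
            stage = "classify"
            tally = classify.classify_clusters(clusters, genes, config.params)
            summary["location_class_counts"] = tally

        if "scan" in config.stages or "classify" in config.stages:
            scanner.write_clusters_bed(clusters, out("clusters.bed"))
            scanner.write_clusters_tsv(clusters, out("clusters.tsv"))

        strata_labels = None
        if "overlap" in config.stages:
            stage = "overlap"
            if peaks_path is None:
                raise ValueError("overlap stage requires a peaks file")
            raw_peaks = peaks_mod.read_peaks(peaks_path, config.params, config.peaks_format)
            assigned = peaks_mod.assign_peaks_to_genes(raw_peaks, genes)
            result_strata = peaks_mod.stratify_peaks_on_clusters(assigned, clusters)
            venn = peaks_mod.overlap_gene_sets(
                result_strata.genes_with_clusters, result_strata.genes_with_peaks
            )
            peaks_mod.write_strata_tsv(result_strata, out("strata.tsv"))
            peaks_mod.write_venn_json(venn, out("venn.json"))
            strata_labels = result_strata.labels()
            summary["venn"] = venn.to_dict()
            summary["strata_sizes"] = {
                k: len(v)
                for k, v in {
                    "peaks_on_clusters": result_strata.genes_peaks_on_clusters,
                    "peaks_off_clusters": result_strata.genes_peaks_off_clusters,
                    "peaks_no_clusters": result_strata.genes_peaks_no_clusters,
                }.items()
            }

        if "enrich" in config.stages:
            stage = "enrich"
            df = enrichment.run_enrichment(
                clusters, genes, genome, config.params,
                background_mode=config.background_mode,
            )
            df = df.sort_values(["set", "motif"]).reset_index(drop=True)
            df.to_csv(out("enrichment.tsv"), sep="\t", index=False,
                      float_format="%.6g")
            summary["n_enriched_motifs"] = int(
                (df["significant"] & (df["log2_fold_change"] > 0)).sum()
            )

        if "isoform-assoc" in config.stages:
            stage = "isoform-assoc"
            if expr_path is None:
                raise ValueError("isoform-assoc stage requires an expression table")
            if strata_labels is None:
                raise ValueError("isoform-assoc stage requires the overlap stage")
            records = isoforms.read_isoform_table(expr_path)
            summaries = isoforms.percent_change_curve(records, strata_labels)
            report = isoforms.compare_strata(records, strata_labels, config.params)
            isoforms.write_stratum_summaries(summaries, out("stratum_summary.tsv"))
            with open(out("isoform_report.json"), "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
            summary["stratum_means"] = {
                s: report["strata"][s]["mean_abs_log2fc"] for s in report["strata"]
            }

        stage = "summary"
        with open(out("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:  # pragma: no cover
                pass
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
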