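"""CLIP-peak filtering, gene assignment and peaks-on-cluster strata.

Peaks are retained when log2 fold enrichment >= 3 and p-value <= 0.001
(boundaries inclusive, both configurable).  A gene whose peaks touch at
least one of its motif clusters by >= 1 bp falls in the
"peaks on clusters" stratum; genes with peaks and clusters that never
intersect are "peaks off clusters"; genes with peaks but no clusters
form the third stratum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .annotation import GeneModel
from .params import AnalysisParameters
from .scanner import MotifCluster

logger = logging.getLogger(__name__)


@dataclass
class Peak:
    """A CLIP peak interval with enrichment statistics."""

    chrom: str
    start: int
    end: int
    strand: str
    log2_fold_enrichment: float
    p_value: float
    name: str = "."
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty peak interval [{self.start}, {self.end})")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"peak p-value {self.p_value} outside (0, 1]")


def read_peaks(
    path: str | Path,
    params: AnalysisParameters | None = None,
    fmt: str = "bed6+2",
) -> list[Peak]:
    """Read and filter peaks from a BED6+2 or narrowPeak file.

    BED6+2: columns 7-8 are log2 fold enrichment and p-value.
    narrowPeak: column 7 (signalValue) is taken as log2 fold enrichment
    and column 8 (pValue) as -log10(p).
    """
    params = params or AnalysisParameters()
    if fmt not in ("bed6+2", "narrowpeak"):
        raise ValueError(f"unknown peak format {fmt!r}")
    peaks: list[Peak] = []
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}:{ln}: expected >= 8 columns, got {len(cols)}")
            try:
                start, end = int(cols[1]), int(cols[2])
                if fmt == "bed6+2":
                    log2fe, p = float(cols[6]), float(cols[7])
                else:
                    log2fe, p = float(cols[6]), 10.0 ** (-float(cols[7]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed peak line ({exc})") from exc
            peak = Peak(
                chrom=cols[0],
                start=start,
                end=end,
                strand=cols[5],
                log2_fold_enrichment=log2fe,
                p_value=min(p, 1.0),
                name=cols[3],
            )
            if (
                peak.log2_fold_enrichment >= params.peak_min_log2fe
                and peak.p_value <= params.peak_max_p
            ):
                peaks.append(peak)
            else:
                dropped += 1
    logger.info("read_peaks: retained %d peaks, dropped %d", len(peaks), dropped)
    return peaks


def assign_peaks_to_genes(
    peaks: Iterable[Peak],
    genes: Iterable[GeneModel],
    same_strand: bool = True,
) -> list[Peak]:
    """Assign peaks to every gene whose span they intersect.

    A peak overlapping k genes yields k records; peaks touching no gene
    are returned once with ``gene_id=None``.  Strand-matched by default
    because eCLIP is strand-specific.
    """
    trees: dict[str, IntervalTree] = {}
    gene_list = list(genes)
    for gene in gene_list:
        start, end = gene.span
        trees.setdefault(gene.chrom, IntervalTree()).addi(start, end, gene)
    out: list[Peak] = []
    for peak in peaks:
        hits = []
        for iv in trees.get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end):
            gene = iv.data
            if same_strand and gene.strand != peak.strand:
                continue
            hits.append(gene.gene_id)
        if hits:
            for gid in sorted(hits):
                out.append(
                    Peak(
                        peak.chrom,
                        peak.start,
                        peak.end,
                        peak.strand,
                        peak.log2_fold_enrichment,
                        peak.p_value,
                        peak.name,
                        gene_id=gid,
                    )
                )
        else:
            out.append(
                Peak(
                    peak.chrom,
                    peak.start,
                    peak.end,
                    peak.strand,
                    peak.log2_fold_enrichment,
                    peak.p_value,
                    peak.name,
                    gene_id=None,
                )
            )
    return out


@dataclass
class VennCounts:
    only_clusters: int
    only_peaks: int
    both: int

    def to_dict(self) -> dict:
        return {
            "only_clusters": self.only_clusters,
            "only_peaks": self.only_peaks,
            "both": self.both,
        }


def overlap_gene_sets(
    genes_with_clusters: set[str], genes_with_peaks: set[str]
) -> VennCounts:
    """Venn counts between cluster-bearing and peak-bearing gene sets."""
    both = genes_with_clusters & genes_with_peaks
    return VennCounts(
        only_clusters=len(genes_with_clusters - genes_with_peaks),
        only_peaks=len(genes_with_peaks - genes_with_clusters),
        both=len(both),
    )


@dataclass
class GeneStrata:
    """Partition of peak-bearing genes by their cluster relationship."""

    genes_with_clusters: set[str]
    genes_with_peaks: set[str]
    genes_peaks_on_clusters: set[str]
    genes_peaks_off_clusters: set[str]
    genes_peaks_no_clusters: set[str]

    def __post_init__(self) -> None:
        strata = (
            self.genes_peaks_on_clusters,
            self.genes_peaks_off_clusters,
            self.genes_peaks_no_clusters,
        )
        union = set().union(*strata)
        if union != self.genes_with_peaks or sum(map(len, strata)) != len(union):
            raise ValueError("peak strata must partition genes_with_peaks")

    def labels(self) -> dict[str, str]:
        out = {}
        for gid in self.genes_peaks_on_clusters:
            out[gid] = "peaks_on_clusters"
        for gid in self.genes_peaks_off_clusters:
            out[gid] = "peaks_off_clusters"
        for gid in self.genes_peaks_no_clusters:
            out[gid] = "peaks_no_clusters"
        return out

    def percentages(self) -> dict[str, float]:
        n = len(self.genes_with_peaks)
        if n == 0:
            return {"peaks_on_clusters": 0.0, "peaks_off_clusters": 0.0, "peaks_no_clusters": 0.0}
        return {
            "peaks_on_clusters": 100.0 * len(self.genes_peaks_on_clusters) / n,
            "peaks_off_clusters": 100.0 * len(self.genes_peaks_off_clusters) / n,
            "peaks_no_clusters": 100.0 * len(self.genes_peaks_no_clusters) / n,
        }


def stratify_peaks_on_clusters(
    peaks: Iterable[Peak],
    clusters: Iterable[MotifCluster],
    min_overlap_bp: int = 1,
) -> GeneStrata:
    """Partition peak-bearing genes by peak/cluster intersection.

    Expects gene-assigned peaks; unassigned peaks are ignored.  A gene is
    on-cluster iff >= 1 of its peaks intersects >= 1 of its clusters by
    at least ``min_overlap_bp``.
    """
    cluster_by_gene: dict[str, list[MotifCluster]] = {}
    for c in clusters:
        cluster_by_gene.setdefault(c.gene_id, []).append(c)
    genes_with_clusters = set(cluster_by_gene)
    peaks_by_gene: dict[str, list[Peak]] = {}
    for p in peaks:
        if p.gene_id is not None:
            peaks_by_gene.setdefault(p.gene_id, []).append(p)
    on, off, nocl = set(), set(), set()
    for gid, gene_peaks in peaks_by_gene.items():
        gene_clusters = cluster_by_gene.get(gid, [])
        if not gene_clusters:
            nocl.add(gid)
            continue
        hit = any(
            min(p.end, c.end) - max(p.start, c.start) >= min_overlap_bp
            for p in gene_peaks
            for c in gene_clusters
        )
        (on if hit else off).add(gid)
    return GeneStrata(
        genes_with_clusters=genes_with_clusters,
        genes_with_peaks=set(peaks_by_gene),
        genes_peaks_on_clusters=on,
        genes_peaks_off_clusters=off,
        genes_peaks_no_clusters=nocl,
    )


def write_strata_tsv(strata: GeneStrata, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstratum\n")
        for gid, label in sorted(strata.labels().items()):
            fh.write(f"{gid}\t{label}\n")


def read_strata_tsv(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gid, label = line.rstrip("\n").split("\t")
            labels[gid] = label
    return labels


def write_venn_json(venn: VennCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(venn.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
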