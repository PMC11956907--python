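"""Genomic-context classification of clusters.

Each cluster receives one of six categories: exon, proximal intron
(within ``proximal_intron_bp`` of the nearest exon boundary), distal
intron, 5'UTR, 3'UTR, or mixed when its member sites straddle two or
more base-level categories.  Classification is by member-site position,
not by the full cluster span: a long extended cluster may bridge a
short exon while every motif is intronic.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable

from .annotation import GeneModel
from .intervals import contains_point
from .params import AnalysisParameters
from .scanner import MotifCluster


class RegionClass(str, Enum):
    EXON = "exon"
    PROXIMAL_INTRON = "proximal_intron"
    DISTAL_INTRON = "distal_intron"
    UTR5 = "utr5"
    UTR3 = "utr3"
    MIXED = "mixed"


def classify_position(
    gene: GeneModel,
    position: int,
    params: AnalysisParameters | None = None,
) -> RegionClass:
    """Base-level class of one genomic position inside ``gene``.

    UTR labels (from any transcript) take precedence over plain exon;
    5'UTR is checked before 3'UTR for the rare base labelled both ways
    across transcripts.  Intronic distance to the nearest exon counts
    the first intronic base as distance 1.
    """
    params = params or AnalysisParameters()
    span = gene.span
    if not (span[0] <= position < span[1]):
        raise ValueError(
            f"position {position} outside gene {gene.gene_id} span {span}"
        )
    for tx in gene.transcripts:
        if contains_point(tx.utr5, position):
            return RegionClass.UTR5
    for tx in gene.transcripts:
        if contains_point(tx.utr3, position):
            return RegionClass.UTR3
    if contains_point(gene.merged_exons, position):
        return RegionClass.EXON
    # intronic: distance to nearest merged-exon boundary
    dist = None
    for start, end in gene.merged_exons:
        if end <= position:
            d = position - end + 1
        elif start > position:
            d = start - position
        else:  # pragma: no cover - exonic handled above
            d = 0
        dist = d if dist is None else min(dist, d)
    assert dist is not None
    if dist <= params.proximal_intron_bp:
        return RegionClass.PROXIMAL_INTRON
    return RegionClass.DISTAL_INTRON


def classify_cluster(
    cluster: MotifCluster,
    gene: GeneModel,
    params: AnalysisParameters | None = None,
) -> RegionClass:
    """Class of a cluster: unanimous member-site class, else mixed."""
    if cluster.gene_id != gene.gene_id:
        raise ValueError(
            f"cluster of gene {cluster.gene_id} classified against {gene.gene_id}"
        )
    classes = {
        classify_position(gene, site.genomic_start, params)
        for site in cluster.sites
    }
    result = classes.pop() if len(classes) == 1 else RegionClass.MIXED
    cluster.location_class = result.value
    return result


def classify_clusters(
    clusters: Iterable[MotifCluster],
    genes: Iterable[GeneModel],
    params: AnalysisParameters | None = None,
) -> dict[str, int]:
    """Classify every cluster in place; return the category tally."""
    by_id = {g.gene_id: g for g in genes}
    tally: dict[str, int] = {rc.value: 0 for rc in RegionClass}
    for cluster in clusters:
        rc = classify_cluster(cluster, by_id[cluster.gene_id], params)
        tally[rc.value] += 1
    return tally
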