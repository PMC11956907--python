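"""(T)GCATG motif scanning and seed-and-extend cluster calling.

A cluster is seeded by at least ``min_sites_seed`` GCATG sites whose
first-to-last span (5-mer footprint included) is at most ``window_bp``;
any further site whose footprint lies strictly closer than
``extension_bp`` to the cluster interval is absorbed, iterated to a
fixpoint, and overlapping clusters are merged into one extended cluster.
The leading T of the hexamer TGCATG is recorded per site but not
required for membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotation import GeneModel
from .genome import GenomeSequences
from .params import AnalysisParameters

MOTIF = "GCATG"
MOTIF_LEN = len(MOTIF)
_MOTIF_RC = "CATGC"  # reverse complement of GCATG


@dataclass(frozen=True)
class MotifSite:
    """One GCATG occurrence on a gene's transcribed strand.

    ``genomic_start`` is the leftmost genomic coordinate of the 5-mer
    footprint regardless of strand; the footprint is
    ``[genomic_start, genomic_start + 5)``.
    """

    chrom: str
    genomic_start: int
    strand: str
    has_leading_T: bool
    gene_id: str

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.genomic_start, self.genomic_start + MOTIF_LEN)


@dataclass
class MotifCluster:
    """A called cluster of motif sites, footprints included in the span."""

    chrom: str
    strand: str
    start: int
    end: int
    sites: list[MotifSite]
    gene_id: str
    location_class: Optional[str] = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_hexamer_sites(self) -> int:
        return sum(1 for s in self.sites if s.has_leading_T)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)  # overlapping occurrences all count
    return out


def scan_motifs(
    gene: GeneModel,
    genome: GenomeSequences,
    hexamer_only: bool = False,
) -> list[MotifSite]:
    """All GCATG occurrences on ``gene``'s sense strand within its span.

    Returned in genomic order.  ``has_leading_T`` inspects the preceding
    strand-correct base (which may lie just outside the gene span but is
    read from the chromosome; a site flush with the chromosome edge has
    no leading base and gets ``False``).
    """
    start, end = gene.span
    if end > genome.length(gene.chrom):
        raise ValueError(
            f"gene {gene.gene_id} span exceeds chromosome {gene.chrom} length"
        )
    forward = genome.fetch(gene.chrom, start, end, "+")
    chrom_len = genome.length(gene.chrom)
    chrom_seq = genome[gene.chrom]
    sites: list[MotifSite] = []
    if gene.strand == "+":
        for i in _find_all(forward, MOTIF):
            pos = start + i
            leading = pos > 0 and chrom_seq[pos - 1] == "T"
            sites.append(MotifSite(gene.chrom, pos, "+", leading, gene.gene_id))
    else:
        for i in _find_all(forward, _MOTIF_RC):
            pos = start + i
            # transcript-5' neighbour of a '-' site is the genomic base at pos+5
            leading = pos + MOTIF_LEN < chrom_len and chrom_seq[pos + MOTIF_LEN] == "A"
            sites.append(MotifSite(gene.chrom, pos, "-", leading, gene.gene_id))
    if hexamer_only:
        sites = [s for s in sites if s.has_leading_T]
    return sorted(sites, key=lambda s: s.genomic_start)


def call_clusters(
    sites: list[MotifSite],
    params: AnalysisParameters | None = None,
) -> list[MotifCluster]:
    """Seed-and-extend-and-merge cluster calling on one gene's sites.

    Returns maximal, disjoint clusters sorted by coordinate.
    """
    params = params or AnalysisParameters()
    if not sites:
        return []
    gene_ids = {s.gene_id for s in sites}
    if len(gene_ids) != 1:
        raise ValueError(f"call_clusters expects sites of one gene, got {gene_ids}")
    pos = [s.genomic_start for s in sites]
    if pos != sorted(pos):
        raise ValueError("sites must be sorted by genomic_start")
    n = len(sites)
    k = params.min_sites_seed

    # seed windows: k consecutive sites whose footprint-inclusive span <= window
    runs: list[list[int]] = []  # index ranges [lo, hi] of seeded members
    for i in range(n - k + 1):
        if pos[i + k - 1] + MOTIF_LEN - pos[i] <= params.window_bp:
            if runs and i <= runs[-1][1]:
                runs[-1][1] = i + k - 1
            else:
                runs.append([i, i + k - 1])
    if not runs:
        return []

    # greedy bidirectional extension of each run: a neighbouring site is
    # absorbed when its gap to the cluster interval is < extension_bp
    for run in runs:
        lo, hi = run
        changed = True
        while changed:
            changed = False
            while hi + 1 < n and pos[hi + 1] - (pos[hi] + MOTIF_LEN) < params.extension_bp:
                hi += 1
                changed = True
            while lo > 0 and pos[lo] - (pos[lo - 1] + MOTIF_LEN) < params.extension_bp:
                lo -= 1
                changed = True
        run[0], run[1] = lo, hi

    # merge runs that share sites or whose intervals overlap
    merged: list[list[int]] = []
    for lo, hi in sorted(map(tuple, runs)):
        if merged and (
            lo <= merged[-1][1] or pos[lo] < pos[merged[-1][1]] + MOTIF_LEN
        ):
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    clusters = []
    for lo, hi in merged:
        members = sites[lo : hi + 1]
        clusters.append(
            MotifCluster(
                chrom=members[0].chrom,
                strand=members[0].strand,
                start=pos[lo],
                end=pos[hi] + MOTIF_LEN,
                sites=members,
                gene_id=members[0].gene_id,
            )
        )
    return clusters


@dataclass
class ScanResult:
    """Genome-wide scan output: all clusters plus the gene-level summary."""

    clusters: list[MotifCluster]
    genes_with_clusters: set[str] = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def scan_genome_for_clusters(
    genes: Iterable[GeneModel],
    genome: GenomeSequences,
    params: AnalysisParameters | None = None,
    hexamer_only: bool = False,
) -> ScanResult:
    """Per-gene motif scan + cluster calling over a whole annotation."""
    params = params or AnalysisParameters()
    clusters: list[MotifCluster] = []
    genes_hit: set[str] = set()
    for gene in genes:
        sites = scan_motifs(gene, genome, hexamer_only=hexamer_only)
        called = call_clusters(sites, params)
        if called:
            genes_hit.add(gene.gene_id)
            clusters.extend(called)
    clusters.sort(key=lambda c: (c.chrom, c.start, c.gene_id))
    return ScanResult(clusters=clusters, genes_with_clusters=genes_hit)


def write_clusters_bed(clusters: list[MotifCluster], path) -> None:
    """BED6: name = gene_id:cluster_index, score = n_sites."""
    counter: dict[str, int] = {}
    with open(path, "w") as fh:
        for c in clusters:
            idx = counter.get(c.gene_id, 0)
            counter[c.gene_id] = idx + 1
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.gene_id}:{idx}\t{c.n_sites}\t{c.strand}\n"
            )


def write_clusters_tsv(clusters: list[MotifCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\tgene_id\tn_sites\tn_hexamer_sites\tlocation_class\n"
        )
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.gene_id}\t"
                f"{c.n_sites}\t{c.n_hexamer_sites}\t{c.location_class or 'NA'}\n"
            )
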