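"""Gene annotation model: transcripts, genes, UTR inference, introns.

GFF3/GTF files (1-based inclusive) are converted to the internal 0-based
half-open convention at the boundary.  RefSeq-style annotations often
lack explicit UTR records; :func:`infer_utr_exons` reconstructs them as
the per-base difference exons minus CDS, split at the CDS by strand
orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import gffutils

from .intervals import (
    Interval,
    contained_in,
    gaps_between,
    merge_intervals,
    subtract_intervals,
    total_length,
)

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed or inconsistent gene annotation."""


@dataclass
class TranscriptModel:
    """One transcript: exons, CDS and (possibly inferred) UTR intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        self.exons = merge_intervals(self.exons)
        self.cds = merge_intervals(self.cds)
        if self.cds and not contained_in(self.cds, self.exons):
            raise AnnotationError(
                f"CDS of {self.transcript_id} not contained in its exons"
            )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class GeneModel:
    """A gene: its transcripts plus the merged-exon / intron view."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    merged_exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        if not self.merged_exons:
            self.merged_exons = merge_intervals(
                [iv for tx in self.transcripts for iv in tx.exons]
            )

    @property
    def span(self) -> Interval:
        # hull of the merged exons, so that introns + exons tile the span
        return (self.merged_exons[0][0], self.merged_exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        return derive_introns(self)


def infer_utr_exons(tx: TranscriptModel) -> TranscriptModel:
    """Label non-CDS exonic bases as 5'/3' UTR by strand orientation.

    Non-coding transcripts (empty CDS) carry no UTR labels.  Exonic
    non-CDS bases strictly between the CDS extremes would break the
    exon = CDS + UTR tiling and are rejected.
    """
    if not tx.cds:
        return replace(tx, utr5=[], utr3=[])
    non_cds = subtract_intervals(tx.exons, tx.cds)
    cds_lo = tx.cds[0][0]
    cds_hi = tx.cds[-1][1]
    left: list[Interval] = []
    right: list[Interval] = []
    for start, end in non_cds:
        if end <= cds_lo:
            left.append((start, end))
        elif start >= cds_hi:
            right.append((start, end))
        else:
            raise AnnotationError(
                f"transcript {tx.transcript_id}: exonic non-CDS bases inside "
                f"the CDS span [{cds_lo}, {cds_hi})"
            )
    if tx.strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left
    out = replace(tx, utr5=utr5, utr3=utr3)
    assert total_length(out.exons) == (
        total_length(out.cds) + total_length(out.utr5) + total_length(out.utr3)
    )
    return out


def derive_introns(gene: GeneModel) -> list[Interval]:
    """Gaps between consecutive merged exons within the gene span."""
    return gaps_between(gene.merged_exons)


_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def read_annotation(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models from a GFF3 or GTF file.

    The file must carry explicit gene and mRNA/transcript features with
    parent links (GFF3 ``Parent=`` / GTF ``gene_id``/``transcript_id``).
    UTRs are inferred for every coding transcript on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene_feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = gene_feat.id
        transcripts: list[TranscriptModel] = []
        for tx_feat in db.children(gene_feat, featuretype=_TRANSCRIPT_TYPES):
            exons = [
                (f.start - 1, f.end)
                for f in db.children(tx_feat, featuretype="exon", order_by="start")
            ]
            cds = [
                (f.start - 1, f.end)
                for f in db.children(tx_feat, featuretype="CDS", order_by="start")
            ]
            if not exons:
                raise AnnotationError(
                    f"transcript {tx_feat.id} of gene {gene_id} has no exons"
                )
            tx = TranscriptModel(
                transcript_id=tx_feat.id,
                gene_id=gene_id,
                chrom=gene_feat.seqid,
                strand=gene_feat.strand,
                exons=exons,
                cds=cds,
            )
            transcripts.append(infer_utr_exons(tx))
        if not transcripts:
            raise AnnotationError(f"gene {gene_id} has no transcripts")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene_feat.seqid,
                strand=gene_feat.strand,
                transcripts=transcripts,
            )
        )
    logger.info("read %d genes from %s", len(genes), path)
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models (including inferred UTR records) as GFF3."""

    def line(chrom, ftype, start, end, strand, attrs):
        return (
            f"{chrom}\trbclust\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            span = gene.span
            fh.write(
                line(gene.chrom, "gene", span[0], span[1], gene.strand, f"ID={gene.gene_id}")
            )
            for tx in gene.transcripts:
                ts = tx.span
                fh.write(
                    line(
                        gene.chrom,
                        "mRNA",
                        ts[0],
                        ts[1],
                        gene.strand,
                        f"ID={tx.transcript_id};Parent={gene.gene_id}",
                    )
                )
                parent = f"Parent={tx.transcript_id}"
                for start, end in tx.exons:
                    fh.write(line(gene.chrom, "exon", start, end, gene.strand, parent))
                for start, end in tx.cds:
                    fh.write(line(gene.chrom, "CDS", start, end, gene.strand, parent))
                for start, end in tx.utr5:
                    fh.write(
                        line(gene.chrom, "five_prime_UTR", start, end, gene.strand, parent)
                    )
                for start, end in tx.utr3:
                    fh.write(
                        line(gene.chrom, "three_prime_UTR", start, end, gene.strand, parent)
                    )
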