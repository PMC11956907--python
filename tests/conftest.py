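from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rbclust.annotation import GeneModel, TranscriptModel, infer_utr_exons
from rbclust.genome import GenomeSequences
from rbclust.scanner import MotifSite
from rbclust.simulate import canonical_config, simulate_genome


@pytest.fixture(scope="session")
def canonical():
    """The canonical TrkB-like fixture: one '+' gene, two 50 kb introns,
    9- and 7-site clusters planted mid-intron, zero background motifs."""
    genome, genes, truth = simulate_genome(canonical_config(seed=0))
    return genome, genes, truth


@pytest.fixture
def toy_gene():
    """'+' gene, exons [0,100)+[200,300), CDS [50,100)+[200,250)."""
    tx = infer_utr_exons(
        TranscriptModel(
            transcript_id="t1",
            gene_id="g1",
            chrom="chr1",
            strand="+",
            exons=[(0, 100), (200, 300)],
            cds=[(50, 100), (200, 250)],
        )
    )
    return GeneModel("g1", "chr1", "+", [tx])


def make_sites(positions, strand="+", gene_id="g1", chrom="chr1"):
    return [
        MotifSite(chrom, p, strand, False, gene_id) for p in sorted(positions)
    ]


def make_genome(seq, chrom="chr1"):
    return GenomeSequences({chrom: seq})


def single_exon_gene(start, end, strand="+", gene_id="g1", chrom="chr1"):
    tx = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=[(start, end)],
    )
    return GeneModel(gene_id, chrom, strand, [tx])
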