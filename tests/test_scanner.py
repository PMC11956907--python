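import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_genome, make_sites, single_exon_gene
from oracles import naive_call_clusters
from rbclust.genome import reverse_complement
from rbclust.params import AnalysisParameters
from rbclust.scanner import call_clusters, scan_genome_for_clusters, scan_motifs


def test_single_planted_motif_plus_strand():
    genome = make_genome("AATGCATGAA")
    gene = single_exon_gene(0, 10)
    sites = scan_motifs(gene, genome)
    assert [(s.genomic_start, s.has_leading_T) for s in sites] == [(3, True)]


def test_minus_strand_scan_mirrors_plus_scan():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    seq = seq[:100] + "TGCATG" + seq[106:200] + "GCATGC" + seq[206:]
    genome_fwd = make_genome(seq)
    plus = scan_motifs(single_exon_gene(0, len(seq), "+"), genome_fwd)
    genome_rc = make_genome(reverse_complement(seq))
    minus = scan_motifs(single_exon_gene(0, len(seq), "-"), genome_rc)
    L = len(seq)
    mirrored = sorted(L - s.genomic_start - 5 for s in minus)
    assert mirrored == [s.genomic_start for s in plus]
    assert sorted(s.has_leading_T for s in minus) == sorted(
        s.has_leading_T for s in plus
    )


def test_minus_strand_leading_t():
    # forward CATGCA: '-' strand reads TGCATG
    genome = make_genome("AACATGCAAA")
    gene = single_exon_gene(0, 10, "-")
    sites = scan_motifs(gene, genome)
    assert [(s.genomic_start, s.has_leading_T) for s in sites] == [(2, True)]


def test_overlapping_occurrences_both_reported():
    genome = make_genome("GCATGCATG")
    sites = scan_motifs(single_exon_gene(0, 9), genome)
    assert [s.genomic_start for s in sites] == [0, 4]


def test_scan_restricted_to_gene_span():
    genome = make_genome("GCATG" + "A" * 20 + "GCATG" + "A" * 20)
    gene = single_exon_gene(10, 40)
    assert [s.genomic_start for s in scan_motifs(gene, genome)] == [25]


def test_gene_span_exceeding_chromosome_rejected():
    genome = make_genome("ACGT" * 5)
    with pytest.raises(ValueError):
        scan_motifs(single_exon_gene(0, 100), genome)


def _clusters(positions, **kw):
    params = AnalysisParameters(**kw) if kw else None
    called = call_clusters(make_sites(positions), params)
    return [tuple(s.genomic_start for s in c.sites) for c in called]


def test_minimal_seed_forms_one_cluster():
    assert _clusters([0, 100, 200, 400]) == [(0, 100, 200, 400)]


def test_no_seed_when_window_exceeded():
    assert _clusters([0, 200, 400, 600]) == []


def test_extension_absorbs_nearby_site():
    called = call_clusters(make_sites([0, 100, 200, 300, 790]))
    assert len(called) == 1
    assert called[0].n_sites == 5
    assert (called[0].start, called[0].end) == (0, 795)


def test_unsorted_and_multi_gene_inputs_rejected():
    sites = make_sites([100, 0, 200, 300])
    with pytest.raises(ValueError, match="sorted"):
        call_clusters(sorted(sites, key=lambda s: -s.genomic_start))
    mixed = make_sites([0, 100]) + make_sites([200, 300], gene_id="g2")
    with pytest.raises(ValueError, match="one gene"):
        call_clusters(mixed)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    positions=st.lists(st.integers(0, 5000), min_size=0, max_size=30, unique=True),
    window=st.sampled_from([200, 500]),
    min_sites=st.sampled_from([3, 4]),
    ext=st.sampled_from([100, 500]),
)
def test_call_clusters_matches_fixpoint_oracle(positions, window, min_sites, ext):
    positions = sorted(positions)
    params = AnalysisParameters(
        window_bp=window, min_sites_seed=min_sites, extension_bp=ext
    )
    got = [
        tuple(s.genomic_start for s in c.sites)
        for c in call_clusters(make_sites(positions), params)
    ]
    assert sorted(got) == naive_call_clusters(positions, window, min_sites, ext)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    positions=st.lists(st.integers(0, 5000), min_size=4, max_size=20, unique=True),
    extra=st.integers(0, 5000),
    shift=st.integers(0, 10_000),
)
def test_monotonicity_and_shift_invariance(positions, extra, shift):
    positions = sorted(positions)

    def clustered_sites(pos, min_sites=4):
        params = AnalysisParameters(min_sites_seed=min_sites)
        return [
            tuple(s.genomic_start for s in c.sites)
            for c in call_clusters(make_sites(pos), params)
        ]

    base = clustered_sites(positions)
    # adding a site never decreases the number of clustered sites
    grown = clustered_sites(sorted(set(positions) | {extra}))
    assert sum(map(len, grown)) >= sum(map(len, base))
    # lowering the seed threshold never decreases the cluster count
    assert len(clustered_sites(positions, min_sites=3)) >= len(base)
    # shifting all positions shifts clusters by the same constant
    shifted = clustered_sites([p + shift for p in positions])
    assert shifted == [tuple(p + shift for p in cl) for cl in base]


def test_noise_free_recovery(canonical):
    genome, genes, truth = canonical
    result = scan_genome_for_clusters(genes, genome)
    got = [(c.start, c.end, c.n_sites) for c in result.clusters]
    want = [(c.start, c.end, c.n_sites) for c in truth.clusters]
    assert got == want
    assert result.genes_with_clusters == {"gene0000"}


def test_noisy_scan_matches_oracle_on_truth_sites():
    from rbclust.simulate import SimulationConfig, simulate_genome

    cfg = SimulationConfig(rng_seed=7, n_genes=6, background_motif_rate=1 / 2000)
    genome, genes, truth = simulate_genome(cfg)
    result = scan_genome_for_clusters(genes, genome)
    planted = {(c.gene_id, c.start, c.end) for c in truth.clusters}
    called = {(c.gene_id, c.start, c.end) for c in result.clusters}
    assert planted <= called  # every planted cluster recovered exactly
    for gene in genes:  # any extra call agrees with the brute-force oracle
        pos = truth.sites_by_gene[gene.gene_id]
        expect = naive_call_clusters(pos)
        got = sorted(
            tuple(s.genomic_start for s in c.sites)
            for c in result.clusters
            if c.gene_id == gene.gene_id
        )
        assert got == expect


def test_gene_assignment_partitions_cleanly():
    genome = make_genome("T" + "GCATG" * 8 + "T" * 200 + "GCATG" * 4 + "T" * 10)
    g1 = single_exon_gene(0, 45, gene_id="g1")
    g2 = single_exon_gene(241, 261, gene_id="g2")
    result = scan_genome_for_clusters([g1, g2], genome)
    assert {c.gene_id for c in result.clusters} == {"g1", "g2"}
    for c in result.clusters:
        assert all(s.gene_id == c.gene_id for s in c.sites)
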