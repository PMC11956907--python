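import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_sites
from oracles import bh_adjust, brute_count, pearson_chi2
from rbclust.enrichment import (
    HNRNP_C,
    HNRNP_H,
    HNRNP_M,
    MotifSet,
    build_background,
    count_motif_occurrences,
    enrichment_test,
    enumerate_tgca_repeats,
    random_sequences,
    select_enrichment_clusters,
)
from rbclust.genome import GenomeSequences
from rbclust.params import AnalysisParameters
from rbclust.scanner import MotifCluster
from rbclust.simulate import SimulationConfig, simulate_genome


def test_printed_motif_sets():
    assert len(HNRNP_M.motifs) == 14
    assert len(HNRNP_H.motifs) == 7
    assert len(HNRNP_C.motifs) == 7
    assert all(m.k == 5 for m in (HNRNP_M, HNRNP_H, HNRNP_C))


def test_tgca_repeat_enumeration():
    mset = enumerate_tgca_repeats()
    assert len(mset.motifs) == 64
    assert len(set(mset.motifs)) == 64
    assert all(len(m) == 12 for m in mset.motifs)
    assert "TGTGTGTGTGTG" in mset.motifs  # all-TG choice
    assert "TGCATGCATGCA" in mset.motifs  # alternating TG,CA
    assert "CACACACACACA" in mset.motifs
    assert list(mset.motifs) == sorted(mset.motifs)


def test_mixed_length_motif_set_rejected():
    with pytest.raises(ValueError, match="length"):
        MotifSet("bad", ("AAAAA", "AAAA"))


def _cluster(start, end, n_sites, strand="+", gene_id="g1"):
    step = max(6, (end - start - 5) // max(1, n_sites - 1))
    sites = make_sites([start + i * step for i in range(n_sites)], strand=strand,
                       gene_id=gene_id)
    return MotifCluster("chr1", strand, start, end, sites, gene_id)


def test_cluster_selection_threshold_and_flanks():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    genome = GenomeSequences({"chr1": seq})
    small = _cluster(1000, 1300, 4)
    big = _cluster(1000, 1300, 5)
    out = select_enrichment_clusters([small, big], genome)
    assert len(out) == 1
    assert out[0] == seq[950:1350]
    minus = _cluster(1000, 1300, 5, strand="-")
    (rc,) = select_enrichment_clusters([minus], genome)
    from rbclust.genome import reverse_complement

    assert rc == reverse_complement(seq[950:1350])


def test_cluster_flank_clipped_at_chromosome_start():
    genome = GenomeSequences({"chr1": "A" * 200})
    cl = _cluster(20, 80, 5)
    (s,) = select_enrichment_clusters([cl], genome)
    assert len(s) == 80 + 50  # left flank clipped to 0


@pytest.mark.parametrize(
    "seq,motif,expect",
    [
        ("TTTTTT", "TTTTT", 2),
        ("TGTGTGTGTGTGTG", "TGTGTGTGTGTG", 2),
        ("ACACAC", "GGGGG", 0),
    ],
)
def test_overlapping_occurrences_counted(seq, motif, expect):
    mset = MotifSet("x", (motif,))
    counts, opp = count_motif_occurrences([seq], mset)
    assert counts[motif] == expect
    assert opp == len(seq) - len(motif) + 1


def test_no_g_sequence_scores_zero_on_polyg_set():
    counts, _ = count_motif_occurrences(["ATCATTACTA" * 10], HNRNP_H)
    assert all(v == 0 for v in counts.values())


def test_n_windows_count_as_opportunities_but_never_match():
    counts, opp = count_motif_occurrences(["TTNTTTTT"], HNRNP_C)
    assert opp == 4  # every window is an opportunity, N-containing included
    assert counts["TTTTT"] == 1  # only the N-free window at offset 3 matches


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_counting_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    seqs = [
        "".join(rng.choice(list("ACGTN"), p=[0.3, 0.18, 0.18, 0.3, 0.04], size=n))
        for n in rng.integers(3, 120, size=4)
    ]
    for mset in (HNRNP_M, HNRNP_C, enumerate_tgca_repeats()):
        counts, opp = count_motif_occurrences(seqs, mset)
        assert opp == sum(max(0, len(s) - mset.k + 1) for s in seqs)
        for motif in mset.motifs:
            assert counts[motif] == sum(brute_count(s, motif) for s in seqs)


def test_background_trivial_and_deterministic(canonical):
    genome, genes, _ = canonical
    assert build_background(genes, genome, 0, 100, 1) == []
    a = build_background(genes, genome, 50, 400, rng_seed=42)
    b = build_background(genes, genome, 50, 400, rng_seed=42)
    assert a == b
    assert all(len(s) == 400 for s in a)
    c = build_background(genes, genome, 50, 400, rng_seed=43)
    assert a != c


def test_background_sequences_come_from_introns(canonical):
    genome, genes, _ = canonical
    seqs = build_background(genes, genome, 20, 300, rng_seed=5, mode="introns")
    chrom = genome["chrS"]
    from rbclust.genome import reverse_complement

    intron_union = "".join(chrom[s:e] for g in genes for s, e in g.introns)
    for s in seqs:
        assert s in intron_union or reverse_complement(s) in intron_union


def test_background_gc_content_within_binomial_bound():
    seqs = random_sequences(2000, 500, 0.4, np.random.default_rng(9))
    gc = sum(s.count("G") + s.count("C") for s in seqs)
    n = 2000 * 500
    sd = np.sqrt(n * 0.4 * 0.6)
    assert abs(gc - 0.4 * n) < 3 * sd


def test_background_too_short_raises():
    genome = GenomeSequences({"chr1": "ACGT" * 50})
    from conftest import single_exon_gene

    gene = single_exon_gene(0, 200)
    with pytest.raises(ValueError, match="background"):
        build_background([gene], genome, 5, 1000, 0)


def test_null_identity():
    fg = {"AAAAA": 50}
    bg = {"AAAAA": 100}
    df = enrichment_test(fg, bg, 1000, 2000)
    row = df.iloc[0]
    assert row["log2_fold_change"] == 0.0
    assert row["p_value"] == pytest.approx(1.0)


def test_chi_square_matches_textbook_formula():
    df = enrichment_test({"m": 20}, {"m": 10}, 1000, 2000)
    table = [[20, 980], [10, 1990]]
    chi2 = pearson_chi2(table)
    assert df.iloc[0]["chi2"] == pytest.approx(chi2)
    assert df.iloc[0]["p_value"] == pytest.approx(stats.chi2.sf(chi2, 1))


def test_zero_cells_get_pseudocount_only_for_fold_change():
    df = enrichment_test({"m": 0}, {"m": 8}, 1000, 1000)
    assert np.isfinite(df.iloc[0]["log2_fold_change"])
    assert df.iloc[0]["log2_fold_change"] == pytest.approx(np.log2(0.5 / 8))
    both_zero = enrichment_test({"m": 0}, {"m": 0}, 1000, 1000)
    assert both_zero.iloc[0]["p_value"] == 1.0
    assert both_zero.iloc[0]["log2_fold_change"] == 0.0


def test_zero_opportunities_rejected():
    with pytest.raises(ValueError, match="opportunities"):
        enrichment_test({"m": 0}, {"m": 0}, 0, 100)


def test_planted_fourfold_motif_detected():
    """A motif at 4x background frequency reaches FDR < 0.01 with
    log2FC ~ 2 at 1e5 opportunities (binomial occurrence generator)."""
    rng = np.random.default_rng(12)
    n = 100_000
    p0 = 1e-3
    fg, bg = {}, {}
    for motif in HNRNP_M.motifs:
        rate = 4 * p0 if motif == "TGTGT" else p0
        fg[motif] = int(rng.binomial(n, rate))
        bg[motif] = int(rng.binomial(n, p0))
    df = enrichment_test(fg, bg, n, n).set_index("motif")
    assert df.loc["TGTGT", "fdr"] < 0.01
    assert df.loc["TGTGT", "log2_fold_change"] == pytest.approx(2.0, abs=0.3)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
def test_bh_fdr_matches_independent_implementation(pvals):
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(adj, bh_adjust(pvals))
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
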