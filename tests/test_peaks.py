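import numpy as np
import pytest

from conftest import make_sites, single_exon_gene
from rbclust.params import AnalysisParameters
from rbclust.peaks import (
    GeneStrata,
    Peak,
    assign_peaks_to_genes,
    overlap_gene_sets,
    read_peaks,
    stratify_peaks_on_clusters,
)
from rbclust.scanner import MotifCluster


def _bed_line(chrom, start, end, name, strand, log2fe, p):
    return f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{log2fe}\t{p}\n"


def test_filter_boundaries_inclusive(tmp_path):
    p = tmp_path / "p.bed"
    p.write_text(
        _bed_line("chr1", 0, 10, "keep", "+", 3.0, 0.001)
        + _bed_line("chr1", 20, 30, "drop_fe", "+", 2.9, 1e-9)
        + _bed_line("chr1", 40, 50, "drop_p", "+", 8.0, 0.0011)
    )
    peaks = read_peaks(p)
    assert [x.name for x in peaks] == ["keep"]


def test_fixture_of_ten_peaks_four_passing(tmp_path):
    rows = []
    for i in range(10):
        ok = i < 4
        rows.append(
            _bed_line("chr1", i * 100, i * 100 + 50, f"p{i}", "+",
                      3.5 if ok else 1.0, 1e-5 if ok else 0.2)
        )
    p = tmp_path / "p.bed"
    p.write_text("".join(rows))
    assert len(read_peaks(p)) == 4


def test_narrowpeak_pvalue_is_neglog10(tmp_path):
    p = tmp_path / "p.narrowPeak"
    p.write_text("chr1\t0\t10\tn1\t0\t+\t4.0\t3.0\t-1\t5\n")
    peaks = read_peaks(p, fmt="narrowpeak")
    assert len(peaks) == 1
    assert peaks[0].p_value == pytest.approx(0.001)


def test_malformed_peak_lines_rejected(tmp_path):
    p = tmp_path / "p.bed"
    p.write_text("chr1\t0\t10\tx\t0\t+\n")
    with pytest.raises(ValueError, match="columns"):
        read_peaks(p)
    p.write_text("chr1\t0\tten\tx\t0\t+\t3\t0.001\n")
    with pytest.raises(ValueError, match="malformed"):
        read_peaks(p)


def _peak(start, end, strand="+", chrom="chr1", gene_id=None):
    return Peak(chrom, start, end, strand, 4.0, 1e-4, gene_id=gene_id)


def test_peak_gene_assignment():
    outer = single_exon_gene(0, 1000, gene_id="outer")
    nested = single_exon_gene(100, 300, gene_id="nested")
    assigned = assign_peaks_to_genes([_peak(150, 200)], [outer, nested])
    assert sorted(p.gene_id for p in assigned) == ["nested", "outer"]
    intergenic = assign_peaks_to_genes([_peak(5000, 5100)], [outer, nested])
    assert [p.gene_id for p in intergenic] == [None]


def test_strand_matched_assignment_by_default():
    gene = single_exon_gene(0, 1000, strand="-", gene_id="g")
    assert assign_peaks_to_genes([_peak(10, 20, "+")], [gene])[0].gene_id is None
    assert assign_peaks_to_genes([_peak(10, 20, "-")], [gene])[0].gene_id == "g"
    relaxed = assign_peaks_to_genes([_peak(10, 20, "+")], [gene], same_strand=False)
    assert relaxed[0].gene_id == "g"


def test_assignment_matches_all_pairs_oracle():
    rng = np.random.default_rng(17)
    genes = []
    for i in range(60):
        start = int(rng.integers(0, 50_000))
        genes.append(
            single_exon_gene(start, start + int(rng.integers(100, 3000)),
                             strand=rng.choice(["+", "-"]), gene_id=f"g{i}")
        )
    peaks = []
    for _ in range(200):
        start = int(rng.integers(0, 55_000))
        peaks.append(_peak(start, start + int(rng.integers(20, 400)),
                           strand=rng.choice(["+", "-"])))
    got = {
        (p.start, p.end, p.strand, p.gene_id)
        for p in assign_peaks_to_genes(peaks, genes)
    }
    expect = set()
    for p in peaks:
        hits = [
            g.gene_id
            for g in genes
            if g.strand == p.strand
            and min(p.end, g.span[1]) - max(p.start, g.span[0]) > 0
        ]
        for gid in hits or [None]:
            expect.add((p.start, p.end, p.strand, gid))
    assert got == expect


@pytest.mark.parametrize(
    "a,b,expect",
    [
        ({"a", "b"}, {"c"}, (2, 1, 0)),
        ({"a", "b", "c"}, {"a", "b", "c"}, (0, 0, 3)),
    ],
)
def test_overlap_gene_sets_examples(a, b, expect):
    venn = overlap_gene_sets(a, b)
    assert (venn.only_clusters, venn.only_peaks, venn.both) == expect


def test_overlap_gene_sets_planted_intersection():
    rng = np.random.default_rng(2)
    universe = [f"g{i}" for i in range(1000)]
    shared = set(rng.choice(universe, size=37, replace=False))
    rest = [g for g in universe if g not in shared]
    a = shared | set(rest[:163])
    b = shared | set(rest[163 : 163 + 113])
    venn = overlap_gene_sets(a, b)
    assert venn.both == 37
    assert (venn.only_clusters, venn.only_peaks) == (163, 113)


def _cluster(gene_id, start, end, strand="+"):
    sites = make_sites(range(start, end - 5, max(1, (end - start) // 4))[:4],
                       gene_id=gene_id, strand=strand)
    return MotifCluster("chr1", strand, start, end, sites, gene_id)


def test_stratification_examples():
    cl = _cluster("g1", 100, 200)
    on = stratify_peaks_on_clusters([_peak(100, 200, gene_id="g1")], [cl])
    assert on.genes_peaks_on_clusters == {"g1"}
    off = stratify_peaks_on_clusters([_peak(500, 600, gene_id="g1")], [cl])
    assert off.genes_peaks_off_clusters == {"g1"}
    nocl = stratify_peaks_on_clusters([_peak(500, 600, gene_id="g2")], [cl])
    assert nocl.genes_peaks_no_clusters == {"g2"}
    # book-ended (0 bp overlap) does not count
    touch = stratify_peaks_on_clusters([_peak(200, 300, gene_id="g1")], [cl])
    assert touch.genes_peaks_off_clusters == {"g1"}


def test_strata_partition_property_on_random_inputs():
    rng = np.random.default_rng(23)
    for _ in range(25):
        gene_ids = [f"g{i}" for i in range(30)]
        clusters = [
            _cluster(g, int(rng.integers(0, 5000)), int(rng.integers(5000, 6000)))
            for g in rng.choice(gene_ids, size=12, replace=False)
        ]
        peaks = [
            _peak(int(rng.integers(0, 6000)), int(rng.integers(6000, 7000)),
                  gene_id=str(rng.choice(gene_ids)))
            for _ in range(40)
        ]
        strata = stratify_peaks_on_clusters(peaks, clusters)
        parts = (
            strata.genes_peaks_on_clusters,
            strata.genes_peaks_off_clusters,
            strata.genes_peaks_no_clusters,
        )
        assert set().union(*parts) == strata.genes_with_peaks
        assert sum(map(len, parts)) == len(strata.genes_with_peaks)


def test_invalid_partition_rejected():
    with pytest.raises(ValueError, match="partition"):
        GeneStrata(
            genes_with_clusters=set(),
            genes_with_peaks={"a", "b"},
            genes_peaks_on_clusters={"a"},
            genes_peaks_off_clusters={"a"},
            genes_peaks_no_clusters=set(),
        )
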