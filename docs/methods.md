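# Methods

This note documents the models, conventions and design choices behind
`rbclust`, in the spirit of the methods appendices of mature scientific
packages: what each stage assumes, which knobs matter, what the
synthetic cohorts do and do not emulate, and where the design was
genuinely open.

## Coordinates and annotation model

All internal coordinates are 0-based half-open; GFF3/GTF (1-based
inclusive) are converted at the I/O boundary and BED is written
natively. A single convention everywhere removes the usual off-by-one
bug class.

Gene models are the union view over transcripts: `merged_exons` is the
per-base union of all transcript exons, introns are the gaps between
merged exons inside the gene span, and the gene span is the hull of the
merged exons (so exons and introns exactly tile the span). A base is
intronic only if it is exonic in no transcript. Where annotations carry
no UTR records, UTRs are inferred per transcript as the per-base
difference exons \ CDS, split at the CDS extremes by strand
orientation; non-coding transcripts (no CDS) contribute exons but no
UTR labels, since UTR is undefined without a CDS. Exonic non-CDS bases
strictly between the CDS extremes (ultra-rare in curated annotations)
would break the exon = CDS + UTR5 + UTR3 tiling and are rejected
loudly rather than guessed at.

## Cluster calling

The motif unit is the pentamer GCATG on the transcribed strand; the
leading T of the hexamer TGCATG is recorded per site but not required
for membership (a hexamer-only mode exists). Overlapping occurrences
(GCATGCATG) both count; matching is exhaustive. Scanning is restricted
to annotated gene spans on the sense strand — the analysis is per-gene
throughout, and intergenic clusters are out of its scope.

Cluster calling is seed–extend–merge:

1. **Seed:** ≥ `min_sites_seed` (default 4) sites whose first-to-last
   span, 5-mer footprint included, is ≤ `window_bp` (default 500,
   inclusive).
2. **Extend:** any site whose footprint lies strictly closer than
   `extension_bp` (default 500) to the cluster interval is absorbed;
   extension iterates to a fixpoint, since a newly absorbed site can
   recruit further sites.
3. **Merge:** clusters that share a site or overlap merge into one
   extended cluster.

The seed window is measured first-site-to-last-site including the
footprint, the seed bound is inclusive (≤), and the extension bound is
strict (<); all three conventions are explicit in
`AnalysisParameters`. The production caller is a sorted-array sweep;
its contract is written against a literal fixpoint oracle (implemented
independently in the test suite and the acceptance script) and the two
are required to agree exactly on randomized configurations.

## Context classification

Each member site's position receives a base-level class: UTR labels
from any transcript take precedence over plain exon (the taxonomy
treats UTRs as their own categories), 5′UTR is checked before 3′UTR in
the rare base labelled both ways across transcripts; intronic bases are
proximal when the distance to the nearest merged-exon boundary is
≤ `proximal_intron_bp` (default 500; the first intronic base counts as
distance 1), else distal. A cluster whose sites agree takes that
class; otherwise it is *mixed*. Classification is by member sites, not
the cluster span: a long extended cluster can bridge a short exon while
every motif is intronic, and site-level voting is what "in between
categories" should mean for mixed.

## Peak integration

Peaks pass the retention filter when log₂ fold enrichment ≥ 3 **and**
p ≤ 0.001, both boundaries inclusive as printed. Assignment to genes
is by ≥ 1 bp overlap with the gene span, strand-matched by default
because eCLIP libraries are strand-specific (a strand-agnostic flag
exists); a peak overlapping several genes is assigned to each. The
peaks-on-clusters stratum requires ≥ 1 bp intersection between a peak
and a cluster of the same gene — the permissive canonical choice, with
the threshold exposed. The three strata provably partition the
peak-bearing gene set (enforced as an invariant). Absolute genome-wide
gene counts depend entirely on the supplied peak file's upstream peak
caller and are not quantities this package tries to reproduce.

## Repeat-motif enrichment

Foreground sequences are strand-correct cluster sequences with
≥ `enrichment_min_sites` (default 5) sites, extended by
`enrichment_flank_bp` (default 50) on both sides and clipped at
chromosome ends. Background is `n_background` (default 10,000)
sequences of the median foreground length. Because "random sequences"
is underdetermined, two modes exist: the default samples positions
uniformly from gene introns of the same genome (uniform strand), which
preserves genomic composition and is the conservative choice; an
i.i.d.-nucleotide mode with configurable GC exists for calibration
studies.

Counting is exhaustive sliding-window matching; overlapping
occurrences all count; opportunities are Σ(len − k + 1) per sequence,
N-containing windows included as opportunities but unable to match.
Per motif, the 2×2 table [[count_fg, opp_fg − count_fg], [count_bg,
opp_bg − count_bg]] is tested with Pearson chi-square without
continuity correction — per-position occurrence pooling is the simplest
frequency model consistent with a chi-square on counts. The log₂ fold
change of per-opportunity frequencies uses a 0.5 pseudocount for zero
cells only (never for the test), keeping volcano coordinates finite; a
motif absent from both foreground and background reports log2FC = 0
and p = 1. FDR is Benjamini–Hochberg within each motif set (the field
default where "FDR-corrected" is otherwise unspecified), with
significance at FDR ≤ 0.01. One source text describes significance as
p *greater* than 0.01, which contradicts convention; the conventional
reading (≤ 0.01 significant) is implemented.

Null calibration is verified at the count-model level: foreground and
background counts drawn per motif from one shared binomial occurrence
rate, 200 replicates × 20 motifs at 10⁵ opportunities, requiring the
fraction of p < 0.05 to sit within 2 binomial SE of 0.05. Pooling
sequence-level p-values across overlapping k-mers would correlate them
and invalidate that binomial band, so sequence-level counting is
instead verified separately against a brute-force oracle. A motif
planted at 4× background frequency must reach FDR < 0.01 with
log₂FC = 2 ± 0.3.

## Isoform association

Expression tables are consumed as-is (gene_id, isoform_id, log₂ fold
change, adjusted p); differential means p_adjusted ≤ 0.05 by default —
upstream DE calling is out of scope. Percent fold change maps to
log₂FC as percent = (2^|log₂FC| − 1)·100, so |log₂FC| = 1 is exactly a
100 % change; the threshold grid defaults to 5–100 % in steps of 5.
The per-gene modulation statistic is the max |log₂FC| over the gene's
differential isoforms (a mean-based strategy is selectable); means ±
SEM (sd/√n) are reported per stratum. Strata are compared pairwise:
chi-square on changed/unchanged counts at each threshold, and a
two-sided Student *t* test (equal variances, as "Student's t test"
implies) on the per-gene statistic, both at P < 0.01. Strata need ≥ 2
genes with a differential isoform; degenerate inputs raise instead of
silently returning non-statistics.

"Dominance" of one stratum's percent-changed curve is defined as ≥ at
every threshold and strictly > wherever the comparison curve is below
100 %: when every stratum gene carries a differential isoform, low
thresholds saturate all curves at exactly 100 %, where strict
inequality is impossible in any finite sample even though the
underlying normal-model ordering is strict. Null calibration of the
*t* test uses a 3·SE binomial band around the nominal 1 % rejection
rate over 500 simulated cohorts (the standard 99.7 % bound).

## Synthetic cohorts

The generator emulates the geometry that motivates the analysis:
three-exon genes with two 50 kb introns (the length scale of the
long-intron alternative-splicing loci the method targets, e.g. the
*Ntrk2*/TrkB locus), i.i.d. background sequence at GC 0.42, spurious
sense-strand GCATGs at a controlled rate (default 1 per 2 kb — sparse
enough that accidental seeds are rare but present), clusters of 5–9
sites spanning ~300 bp planted mid-intron in two thirds of the genes,
peaks on a configurable fraction (default 25 %) of cluster genes, and
stratum |log₂FC| effects of 1.8 / 1.55 / 1.4 with sd 0.5 — effect
scales chosen to match the separation magnitude the stratified analysis
is meant to resolve, with n = 500 genes per stratum in the calibration
studies. The canonical smoke-test fixture is a single '+' gene with
9- and 7-site clusters planted mid-intron and zero background motifs,
so recovery is exact and deterministic.

Native GCATGs are scrubbed before planting so the spurious rate is
exactly the configured one, and motifs accidentally created at
substitution junctions are scrubbed to a fixpoint, which makes the
planted site list equal the post-scan site list — ground truth is
exact, not approximate. What the generator does **not** emulate:
realistic splice-site sequence, isochore/composition heterogeneity,
repeat families, crosslinking biases in peak placement, or read-level
noise (no FASTQ). Passing tests therefore demonstrate correctness of
the algorithms and calibration of the statistics under controlled
conditions, not performance on real genomes.

Problem sizes in the shipped tests and the acceptance script (1000
random site configurations for oracle equivalence, 200 enrichment
replicates, 500 null cohorts, 120-gene stratification cohorts, 500
genes per stratum for effect recovery) were chosen to give tight
binomial error bands while keeping a full run in the tens of seconds.

## Determinism

Every stochastic step (background sampling, all simulation) flows from
an explicit integer seed; pipeline outputs are written with sorted
records and fixed float formatting, so identical configurations and
seeds produce byte-identical TSV/BED/JSON outputs (plots excluded).

## Known limitations

* Non-canonical / secondary RbFox motifs are not scanned; RNA
  secondary structure is not modelled.
* Gene-level collapsing of overlapping isoforms uses the exon-union
  rule described above; other collapsing rules (longest isoform,
  MANE-style selection) would shift intron boundaries and hence
  proximal/distal calls.
* The chi-square on changed/unchanged counts is asymptotic; at small
  strata the *t* test is the better-behaved of the two (and the one
  used for null calibration).
* `read_annotation` requires explicit gene and mRNA/transcript
  features with parent links; it does not reconstruct missing parents.
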