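"""Repeat-motif enrichment in motif clusters vs randomized background.

Counts LASR-partner binding motifs (hnRNP-M GU-rich, hnRNP-H polyG,
hnRNP-C polyU pentamers and the 64 (TG/CA)6 12-mers) inside
flank-extended clusters holding at least five GCATG sites, and tests
each motif's per-opportunity frequency against 10,000 random background
sequences of the median cluster length with a Pearson chi-square on the
pooled occurrence/opportunity table, Benjamini-Hochberg corrected
within each motif set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel
from .genome import GenomeSequences
from .params import AnalysisParameters
from .scanner import MotifCluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifSet:
    """A named set of distinct same-length DNA motifs."""

    name: str
    motifs: tuple[str, ...]

    def __post_init__(self) -> None:
        lengths = {len(m) for m in self.motifs}
        if len(lengths) != 1:
            raise ValueError(f"motif set {self.name}: mixed motif lengths {lengths}")
        if len(set(self.motifs)) != len(self.motifs):
            raise ValueError(f"motif set {self.name}: duplicate motifs")

    @property
    def k(self) -> int:
        return len(self.motifs[0])


HNRNP_M = MotifSet(
    "hnRNP-M",
    (
        "TGTTG", "GTGTT", "TTGTG", "GTTGT", "TGTGT", "TGGTT", "TTGGT",
        "GTGTG", "GGTGT", "TGTGG", "GTGGT", "GTTGG", "TGGTG", "GGTTG",
    ),
)
HNRNP_H = MotifSet(
    "hnRNP-H", ("GGGGT", "GGGGG", "CGGGG", "AGGGG", "TGGGG", "GGGGC", "GGGGA")
)
HNRNP_C = MotifSet(
    "hnRNP-C", ("ATTTT", "GTTTT", "CTTTT", "TTTTA", "TTTTC", "TTTTG", "TTTTT")
)


def enumerate_tgca_repeats() -> MotifSet:
    """All 12-mers built from six tandem units, each TG or CA (64 total)."""
    motifs = sorted(
        "".join(units) for units in itertools.product(("TG", "CA"), repeat=6)
    )
    return MotifSet("TGCA6", tuple(motifs))


MOTIF_SETS = {
    "hnRNP-M": HNRNP_M,
    "hnRNP-H": HNRNP_H,
    "hnRNP-C": HNRNP_C,
    "TGCA6": enumerate_tgca_repeats(),
}


def select_enrichment_clusters(
    clusters: Iterable[MotifCluster],
    genome: GenomeSequences,
    params: AnalysisParameters | None = None,
) -> list[str]:
    """Strand-correct sequences of flank-extended >= 5-site clusters.

    Flanks are clipped at chromosome bounds (clipping is logged).
    """
    params = params or AnalysisParameters()
    out: list[str] = []
    for c in clusters:
        if c.n_sites < params.enrichment_min_sites:
            continue
        start = c.start - params.enrichment_flank_bp
        end = c.end + params.enrichment_flank_bp
        lo = max(0, start)
        hi = min(genome.length(c.chrom), end)
        if lo != start or hi != end:
            logger.info(
                "cluster %s:%d-%d flank clipped to [%d, %d)", c.chrom, c.start, c.end, lo, hi
            )
        out.append(genome.fetch(c.chrom, lo, hi, c.strand))
    return out


_BASE_CODE = np.full(256, 4, dtype=np.int64)  # N and anything else -> 4
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Base-4 codes of all k-windows without N; N windows are dropped."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win != 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[valid] @ powers


def _motif_code(motif: str) -> int:
    code = 0
    for b in motif:
        code = code * 4 + int(_BASE_CODE[ord(b)])
    return code


def count_motif_occurrences(
    sequences: Sequence[str],
    motif_set: MotifSet,
) -> tuple[dict[str, int], int]:
    """Sliding-window motif counts (overlaps included) and opportunities.

    Opportunities = sum over sequences of max(0, len - k + 1); windows
    containing N count as opportunities but can never match.
    """
    k = motif_set.k
    opportunities = sum(max(0, len(s) - k + 1) for s in sequences)
    codes = np.sort(
        np.concatenate(
            [_window_codes(s, k) for s in sequences]
            or [np.empty(0, dtype=np.int64)]
        )
    )
    counts: dict[str, int] = {}
    for motif in motif_set.motifs:
        code = _motif_code(motif)
        lo = np.searchsorted(codes, code, side="left")
        hi = np.searchsorted(codes, code, side="right")
        counts[motif] = int(hi - lo)
    return counts, opportunities


def random_sequences(
    n: int, length: int, gc_content: float, rng: np.random.Generator
) -> list[str]:
    """i.i.d. nucleotide sequences at the given GC content."""
    gc = gc_content / 2.0
    at = (1.0 - gc_content) / 2.0
    draws = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=(n, length),
                       p=[at, gc, gc, at])
    return [bytes(row).decode("ascii") for row in draws]


def build_background(
    genes: Sequence[GeneModel],
    genome: GenomeSequences,
    n: int,
    length: int,
    rng_seed: int,
    mode: str = "introns",
    gc_content: float = 0.4,
) -> list[str]:
    """n background sequences of exactly ``length`` bases.

    ``introns`` (default) samples uniformly from gene intron positions of
    the supplied genome with uniform strand, preserving genomic
    composition; ``genes`` samples from whole gene spans; ``iid`` draws
    i.i.d. nucleotides at ``gc_content``.  Fully reproducible from
    ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    if n == 0:
        return []
    if mode == "iid":
        return random_sequences(n, length, gc_content, rng)
    if mode == "introns":
        pool = [
            (g.chrom, g.strand, start, end)
            for g in genes
            for start, end in g.introns
            if end - start >= length
        ]
    elif mode == "genes":
        pool = [
            (g.chrom, g.strand, g.span[0], g.span[1])
            for g in genes
            if g.span[1] - g.span[0] >= length
        ]
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    if not pool:
        raise ValueError(
            f"no {mode} interval can host a background sequence of length {length}"
        )
    weights = np.array([end - start - length + 1 for _, _, start, end in pool], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(pool), size=n, p=weights)
    offsets = rng.random(n)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    out = []
    for idx, frac, strand in zip(picks, offsets, strands):
        chrom, _, start, end = pool[idx]
        pos = start + int(frac * (end - start - length + 1))
        out.append(genome.fetch(chrom, pos, pos + length, strand))
    return out


def enrichment_test(
    fg_counts: dict[str, int],
    bg_counts: dict[str, int],
    fg_opportunities: int,
    bg_opportunities: int,
    set_name: str = "",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-motif chi-square enrichment of foreground vs background.

    For each motif the 2x2 table
    ``[[count_fg, opp_fg - count_fg], [count_bg, opp_bg - count_bg]]``
    is tested with Pearson chi-square (no continuity correction).  The
    log2 fold change of per-opportunity frequencies uses a 0.5
    pseudocount on zero cells only (never for the test).  BH FDR is
    applied across the motifs of the set; significance at fdr <= alpha.
    """
    if fg_opportunities <= 0 or bg_opportunities <= 0:
        raise ValueError("opportunities must be positive")
    motifs = list(fg_counts)
    if set(bg_counts) != set(motifs):
        raise ValueError("foreground and background count different motif sets")
    rows = []
    for motif in motifs:
        cf, cb = fg_counts[motif], bg_counts[motif]
        if cf > fg_opportunities or cb > bg_opportunities:
            raise ValueError(f"count exceeds opportunities for motif {motif}")
        if cf == 0 and cb == 0:
            chi2, p = 0.0, 1.0
        else:
            table = [
                [cf, fg_opportunities - cf],
                [cb, bg_opportunities - cb],
            ]
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        if cf == 0 and cb == 0:
            # no occurrences anywhere: no evidence of change
            freq_fg = freq_bg = 1.0
        else:
            freq_fg = (cf if cf > 0 else 0.5) / fg_opportunities
            freq_bg = (cb if cb > 0 else 0.5) / bg_opportunities
        rows.append(
            {
                "motif": motif,
                "set": set_name,
                "count_fg": cf,
                "count_bg": cb,
                "opportunities_fg": fg_opportunities,
                "opportunities_bg": bg_opportunities,
                "log2_fold_change": float(np.log2(freq_fg / freq_bg)),
                "chi2": float(chi2),
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] <= alpha
    return df


def run_enrichment(
    clusters: Iterable[MotifCluster],
    genes: Sequence[GeneModel],
    genome: GenomeSequences,
    params: AnalysisParameters | None = None,
    motif_sets: Sequence[MotifSet] | None = None,
    background_mode: str = "introns",
) -> pd.DataFrame:
    """Full enrichment stage: select clusters, build background, test."""
    params = params or AnalysisParameters()
    motif_sets = list(motif_sets) if motif_sets is not None else list(MOTIF_SETS.values())
    fg = select_enrichment_clusters(clusters, genome, params)
    if not fg:
        raise ValueError(
            f"no cluster has >= {params.enrichment_min_sites} sites; nothing to test"
        )
    median_len = int(np.median([len(s) for s in fg]))
    bg = build_background(
        genes, genome, params.n_background, median_len, params.rng_seed,
        mode=background_mode,
    )
    frames = []
    for mset in motif_sets:
        fg_counts, fg_opp = count_motif_occurrences(fg, mset)
        bg_counts, bg_opp = count_motif_occurrences(bg, mset)
        frames.append(
            enrichment_test(
                fg_counts, bg_counts, fg_opp, bg_opp,
                set_name=mset.name, alpha=params.significance_p,
            )
        )
    return pd.concat(frames, ignore_index=True)


def volcano_plot(df: pd.DataFrame, path) -> None:
    """Volcano plot: log2 fold change vs -log10 p, coloured by motif set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, sub in df.groupby("set"):
        ax.scatter(
            sub["log2_fold_change"],
            -np.log10(np.maximum(sub["p_value"], 1e-300)),
            s=14,
            label=name,
            alpha=0.8,
        )
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Log2(Fold Change)")
    ax.set_ylabel("-Log10(p-value)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
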