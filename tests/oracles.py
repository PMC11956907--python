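"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (literal definitions, quadratic
loops, textbook formulas) and shares no code with the package paths it
verifies.
"""

from __future__ import annotations

import numpy as np

K = 5  # GCATG footprint


def naive_call_clusters(
    positions: list[int],
    window: int = 500,
    min_sites: int = 4,
    ext: int = 500,
    k: int = K,
) -> list[tuple[int, ...]]:
    """Literal seed / extend / merge fixpoint on sorted site positions.

    Returns sorted tuples of member positions.
    """
    n = len(positions)
    clusters: list[set[int]] = []
    for i in range(n - min_sites + 1):
        if positions[i + min_sites - 1] + k - positions[i] <= window:
            clusters.append(set(range(i, i + min_sites)))
    changed = True
    while changed:
        changed = False
        for cl in clusters:
            start = min(positions[i] for i in cl)
            end = max(positions[i] + k for i in cl)
            for j in range(n):
                if j in cl:
                    continue
                p = positions[j]
                if p + k <= start:
                    gap = start - (p + k)
                elif p >= end:
                    gap = p - end
                else:
                    gap = 0
                if gap < ext:
                    cl.add(j)
                    changed = True
        merged: list[set[int]] = []
        for cl in sorted(clusters, key=lambda c: min(positions[i] for i in c)):
            if merged:
                prev = merged[-1]
                ps, pe = (
                    min(positions[i] for i in prev),
                    max(positions[i] + k for i in prev),
                )
                cs, ce = (
                    min(positions[i] for i in cl),
                    max(positions[i] + k for i in cl),
                )
                if (prev & cl) or (cs < pe and ps < ce):
                    if not cl <= prev:
                        changed = True
                    merged[-1] = prev | cl
                    continue
            merged.append(set(cl))
        clusters = merged
    return sorted({tuple(sorted(positions[i] for i in cl)) for cl in clusters})


def brute_count(seq: str, motif: str) -> int:
    """Count overlapping occurrences by checking every offset."""
    k = len(motif)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == motif)


def pearson_chi2(table) -> float:
    """Textbook Pearson chi-square statistic of a 2x2 table."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows @ cols / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def classify_base_naive(gene, pos: int, proximal_bp: int = 500) -> str:
    """Per-base genomic-context class by exhaustive checks."""
    for tx in gene.transcripts:
        if any(s <= pos < e for s, e in tx.utr5):
            return "utr5"
    for tx in gene.transcripts:
        if any(s <= pos < e for s, e in tx.utr3):
            return "utr3"
    if any(s <= pos < e for s, e in gene.merged_exons):
        return "exon"
    dist = min(
        min(abs(pos - s), abs(pos - (e - 1))) for s, e in gene.merged_exons
    )
    return "proximal_intron" if dist <= proximal_bp else "distal_intron"


def utr_label_naive(exons, cds, strand: str, pos: int) -> str:
    """Per-base label of an exonic base: cds / utr5 / utr3."""
    if any(s <= pos < e for s, e in cds):
        return "cds"
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    if pos < cds_lo:
        return "utr5" if strand == "+" else "utr3"
    assert pos >= cds_hi
    return "utr3" if strand == "+" else "utr5"
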