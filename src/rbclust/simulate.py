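"""Synthetic genomes, annotations, peaks and expression tables.

The generator emulates the geometry the analysis targets: genes with
long (tens-of-kb) introns, a configurable background rate of spurious
GCATG occurrences on the sense strand, planted motif clusters of known
size and spacing placed mid-intron (the canonical fixture reproduces a
TrkB-like gene: two 50 kb introns with 9- and 7-site clusters in their
middles), CLIP peaks placed on a configurable fraction of cluster genes,
and per-isoform log2 fold-change tables with stratum-specific effects.

Ground truth (planted coordinates, post-scan site lists, stratum
labels) is carried alongside every fixture so recovery can be scored
exactly.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel, infer_utr_exons
from .genome import GenomeSequences, reverse_complement
from .scanner import MOTIF, MOTIF_LEN, scan_motifs

_CHROM = "chrS"


@dataclass
class PlantedCluster:
    """Specification of one planted motif cluster."""

    gene_index: int
    intron_index: int = 0
    n_sites: int = 6
    span_bp: int = 300
    leading_t_fraction: float = 0.8
    position: float = 0.5  # fractional centre within the intron


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate the geometry the analysis was designed around:
    three-exon genes with ~50 kb introns, spurious sense-strand GCATG
    at one per 2 kb, clusters planted mid-intron in two thirds of the
    genes, a quarter of cluster genes carrying an on-cluster peak, and
    stratum |log2FC| effects of 1.8 / 1.55 / 1.4 (sd 0.5).
    """

    rng_seed: int = 0
    n_genes: int = 12
    exon_lengths: tuple[int, ...] = (150, 150, 150)
    intron_lengths: tuple[int, ...] = (50_000, 50_000)
    spacer_length: int = 2_000
    utr5_length: int = 50
    utr3_length: int = 60
    gc_content: float = 0.42
    background_motif_rate: float = 0.0005  # expected GCATG per sense-strand bp
    planted_clusters: list[PlantedCluster] | None = None
    cluster_gene_fraction: float = 2 / 3
    peak_on_cluster_fraction: float = 0.25
    peak_length: int = 150
    stratum_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "peaks_on_clusters": (1.8, 0.5),
            "peaks_off_clusters": (1.55, 0.5),
            "peaks_no_clusters": (1.4, 0.5),
        }
    )
    strand_mode: str = "alternate"  # "alternate", "+", or "-"

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one intron length per internal junction")
        if not (0.0 <= self.background_motif_rate <= 1.0):
            raise ValueError("background_motif_rate must lie in [0, 1]")
        if not (0.0 <= self.peak_on_cluster_fraction <= 1.0):
            raise ValueError("peak_on_cluster_fraction must lie in [0, 1]")


@dataclass
class PlantedClusterTruth:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    n_sites: int
    site_starts: list[int]


@dataclass
class GroundTruth:
    """Everything needed to score recovery exactly."""

    genes: list[str]
    clusters: list[PlantedClusterTruth]
    sites_by_gene: dict[str, list[int]]  # post-scan, includes accidental motifs
    strata: dict[str, str] = field(default_factory=dict)
    stratum_effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes,
            "clusters": [asdict(c) for c in self.clusters],
            "sites_by_gene": self.sites_by_gene,
            "strata": self.strata,
            "stratum_effects": self.stratum_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def canonical_config(seed: int = 0) -> SimulationConfig:
    """The canonical smoke-test fixture: one gene, two 50 kb introns,
    9- and 7-site clusters planted mid-intron, zero background motifs."""
    return SimulationConfig(
        rng_seed=seed,
        n_genes=1,
        exon_lengths=(200, 100, 170),
        intron_lengths=(50_000, 50_000),
        background_motif_rate=0.0,
        planted_clusters=[
            PlantedCluster(0, intron_index=0, n_sites=9, span_bp=300),
            PlantedCluster(0, intron_index=1, n_sites=7, span_bp=300),
        ],
        strand_mode="+",
    )


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> bytearray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return bytearray(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p))


def _scrub_motifs(seq: bytearray, rng: np.random.Generator) -> None:
    """Destroy every sense-strand GCATG by mutating its middle base."""
    motif = MOTIF.encode()
    pos = bytes(seq).find(motif)
    while pos != -1:
        seq[pos + 2] = ord(rng.choice(["C", "G"]))
        pos = bytes(seq).find(motif, max(0, pos - MOTIF_LEN + 1))


def _gene_layout(config: SimulationConfig) -> tuple[list[tuple[int, int]], list[tuple[int, int]], int]:
    """Sense-coordinate exons, introns and total length of one gene."""
    exons, introns = [], []
    cursor = 0
    for i, ex_len in enumerate(config.exon_lengths):
        exons.append((cursor, cursor + ex_len))
        cursor += ex_len
        if i < len(config.intron_lengths):
            introns.append((cursor, cursor + config.intron_lengths[i]))
            cursor += config.intron_lengths[i]
    return exons, introns, cursor


def _default_planting(config: SimulationConfig, rng: np.random.Generator) -> list[PlantedCluster]:
    n_cluster_genes = round(config.cluster_gene_fraction * config.n_genes)
    specs = []
    for gi in range(n_cluster_genes):
        specs.append(
            PlantedCluster(
                gene_index=gi,
                intron_index=int(rng.integers(len(config.intron_lengths))),
                n_sites=int(rng.integers(5, 10)),
                span_bp=300,
            )
        )
    return specs


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequences, list[GeneModel], GroundTruth]:
    """Build genome + annotation + ground truth from the configuration.

    Background sequence is i.i.d. at the configured GC; native GCATGs
    are scrubbed and re-planted at the configured per-bp rate so the
    spurious-site rate is controlled.  Planted cluster sites are evenly
    spaced substitutions; motifs accidentally created at substitution
    junctions are left in place and recorded by a post-scan.
    """
    rng = np.random.default_rng(config.rng_seed)
    planted = (
        config.planted_clusters
        if config.planted_clusters is not None
        else _default_planting(config, rng)
    )
    exons_s, introns_s, gene_len = _gene_layout(config)

    by_gene: dict[int, list[PlantedCluster]] = {}
    for spec in planted:
        if not (0 <= spec.gene_index < config.n_genes):
            raise ValueError(f"planted cluster gene_index {spec.gene_index} out of range")
        if spec.span_bp < spec.n_sites * (MOTIF_LEN + 2):
            raise ValueError("cluster span too small for the requested site count")
        by_gene.setdefault(spec.gene_index, []).append(spec)

    chrom_parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    truth_clusters: list[PlantedClusterTruth] = []

    for gi in range(config.n_genes):
        gene_id = f"gene{gi:04d}"
        if config.strand_mode == "alternate":
            strand = "+" if gi % 2 == 0 else "-"
        else:
            strand = config.strand_mode

        sense = _random_bases(gene_len, config.gc_content, rng)
        _scrub_motifs(sense, rng)

        # sense-coordinate intervals reserved by planted clusters (+ margin
        # so background sites cannot extend a planted cluster)
        reserved: list[tuple[int, int]] = []
        site_plans: list[tuple[int, bool]] = []  # (sense pos of G, leading T)
        cluster_plans: list[tuple[PlantedCluster, list[int]]] = []
        for spec in sorted(by_gene.get(gi, []), key=lambda s: (s.intron_index, s.position)):
            ist, ien = introns_s[spec.intron_index]
            centre = ist + spec.position * (ien - ist)
            first = int(round(centre - spec.span_bp / 2))
            offsets = np.linspace(0, spec.span_bp - MOTIF_LEN, spec.n_sites)
            positions = sorted({first + int(round(o)) for o in offsets})
            if len(positions) != spec.n_sites:
                raise ValueError("cluster sites collide; widen span_bp")
            lo, hi = positions[0] - 1, positions[-1] + MOTIF_LEN
            if not (ist < lo and hi < ien):
                raise ValueError("planted cluster does not fit inside its intron")
            for rs, re_ in reserved:
                if lo < re_ and rs < hi:
                    raise ValueError("planted clusters overlap each other")
            reserved.append((lo - 520, hi + 520))
            leading = rng.random(spec.n_sites) < spec.leading_t_fraction
            for p, lead in zip(positions, leading):
                site_plans.append((p, bool(lead)))
            cluster_plans.append((spec, positions))

        # background motif sites at the configured per-bp rate
        n_bg = rng.poisson(config.background_motif_rate * gene_len)
        placed: list[int] = []
        attempts = 0
        while len(placed) < n_bg and attempts < 50 * max(1, n_bg):
            attempts += 1
            p = int(rng.integers(1, gene_len - MOTIF_LEN - 1))
            if any(rs <= p < re_ for rs, re_ in reserved):
                continue
            if any(abs(p - q) < MOTIF_LEN + 2 for q in placed):
                continue
            placed.append(p)
        for p in sorted(placed):
            site_plans.append((p, bool(rng.random() < 0.5)))

        for p, lead in site_plans:
            sense[p : p + MOTIF_LEN] = MOTIF.encode()
            if lead:
                sense[p - 1] = ord("T")

        # substitutions can create extra GCATGs at junctions; destroy any
        # occurrence that was not planned so planted truth is exact
        planned_pos = {p for p, _ in site_plans}
        protected: set[int] = set()
        for p, lead in site_plans:
            protected.update(range(p, p + MOTIF_LEN))
            if lead:
                protected.add(p - 1)
        for _guard in range(100):
            raw = bytes(sense)
            extras = []
            q = raw.find(MOTIF.encode())
            while q != -1:
                if q not in planned_pos:
                    extras.append(q)
                q = raw.find(MOTIF.encode(), q + 1)
            if not extras:
                break
            for q in extras:
                for b in range(q, q + MOTIF_LEN):
                    if b not in protected:
                        expected = MOTIF[b - q]
                        current = chr(sense[b])
                        sense[b] = ord(
                            next(c for c in "ACGT" if c not in (expected, current))
                        )
                        break
                else:  # pragma: no cover - cannot happen with spacing >= 7
                    raise RuntimeError("cannot scrub accidental motif")
        else:  # pragma: no cover
            raise RuntimeError("motif scrubbing did not converge")

        # place on the chromosome; '-' genes store the reverse complement
        spacer = _random_bases(config.spacer_length, config.gc_content, rng)
        chrom_parts.append(spacer.decode("ascii"))
        cursor += config.spacer_length
        offset = cursor
        forward = sense.decode("ascii")
        if strand == "-":
            forward = reverse_complement(forward)
        chrom_parts.append(forward)
        cursor += gene_len

        def to_genomic_interval(iv: tuple[int, int]) -> tuple[int, int]:
            if strand == "+":
                return (offset + iv[0], offset + iv[1])
            return (offset + gene_len - iv[1], offset + gene_len - iv[0])

        def to_genomic_start(sense_pos: int) -> int:
            if strand == "+":
                return offset + sense_pos
            return offset + gene_len - sense_pos - MOTIF_LEN

        exons_g = sorted(to_genomic_interval(iv) for iv in exons_s)
        cds_sense = (config.utr5_length, gene_len - config.utr3_length)
        cds_g = []
        for iv in exons_s:
            lo = max(iv[0], cds_sense[0])
            hi = min(iv[1], cds_sense[1])
            if lo < hi:
                cds_g.append((lo, hi))
        cds_g = sorted(to_genomic_interval(iv) for iv in cds_g)
        tx = infer_utr_exons(
            TranscriptModel(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                chrom=_CHROM,
                strand=strand,
                exons=exons_g,
                cds=cds_g,
            )
        )
        genes.append(GeneModel(gene_id, _CHROM, strand, [tx]))

        for spec, positions in cluster_plans:
            starts = sorted(to_genomic_start(p) for p in positions)
            truth_clusters.append(
                PlantedClusterTruth(
                    gene_id=gene_id,
                    chrom=_CHROM,
                    strand=strand,
                    start=starts[0],
                    end=starts[-1] + MOTIF_LEN,
                    n_sites=spec.n_sites,
                    site_starts=starts,
                )
            )

    chrom_parts.append(
        _random_bases(config.spacer_length, config.gc_content, rng).decode("ascii")
    )
    genome = GenomeSequences({_CHROM: "".join(chrom_parts)})
    truth = GroundTruth(
        genes=[g.gene_id for g in genes],
        clusters=truth_clusters,
        sites_by_gene={
            g.gene_id: [s.genomic_start for s in scan_motifs(g, genome)] for g in genes
        },
        stratum_effects=dict(config.stratum_effects),
    )
    return genome, genes, truth


def simulate_peaks(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[dict]:
    """Emit peak rows (as dicts) and label gene strata in ``truth``.

    Exactly ``round(fraction * n_cluster_genes)`` cluster genes receive a
    peak overlapping their first planted cluster; the remaining cluster
    genes and all cluster-free genes receive an exonic peak.  Decoy
    peaks straddle the retention filter from below.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    by_gene = {g.gene_id: g for g in genes}
    clusters_by_gene: dict[str, list[PlantedClusterTruth]] = {}
    for c in truth.clusters:
        clusters_by_gene.setdefault(c.gene_id, []).append(c)
    cluster_genes = sorted(clusters_by_gene)
    n_on = round(config.peak_on_cluster_fraction * len(cluster_genes))
    rows: list[dict] = []

    def passing_stats():
        return 3.0 + 5.0 * rng.random(), 10.0 ** (-rng.uniform(3.5, 8.0))

    def add_peak(gene: GeneModel, start: int, end: int, name: str, log2fe, p):
        rows.append(
            {
                "chrom": gene.chrom,
                "start": start,
                "end": end,
                "name": name,
                "score": 0,
                "strand": gene.strand,
                "log2_fold_enrichment": round(float(log2fe), 4),
                "p_value": float(f"{p:.4g}"),
            }
        )

    for i, gid in enumerate(cluster_genes):
        gene = by_gene[gid]
        log2fe, p = passing_stats()
        if i < n_on:
            c = clusters_by_gene[gid][0]
            mid = (c.start + c.end) // 2
            add_peak(gene, mid - config.peak_length // 2,
                     mid - config.peak_length // 2 + config.peak_length,
                     f"{gid}_on", log2fe, p)
            truth.strata[gid] = "peaks_on_clusters"
        else:
            ex = gene.merged_exons[0]
            add_peak(gene, ex[0], min(ex[1], ex[0] + config.peak_length),
                     f"{gid}_off", log2fe, p)
            truth.strata[gid] = "peaks_off_clusters"

    for gid in truth.genes:
        if gid in clusters_by_gene:
            continue
        gene = by_gene[gid]
        log2fe, p = passing_stats()
        ex = gene.merged_exons[-1]
        add_peak(gene, ex[0], min(ex[1], ex[0] + config.peak_length),
                 f"{gid}_nc", log2fe, p)
        truth.strata[gid] = "peaks_no_clusters"

    # decoys failing the filter: sub-threshold enrichment or weak p
    for gid in truth.genes:
        gene = by_gene[gid]
        span = gene.span
        pos = int(rng.integers(span[0], max(span[0] + 1, span[1] - config.peak_length)))
        if rng.random() < 0.5:
            add_peak(gene, pos, pos + config.peak_length, f"{gid}_decoy",
                     0.5 + 2.4 * rng.random(), 10.0 ** (-rng.uniform(3.5, 8.0)))
        else:
            add_peak(gene, pos, pos + config.peak_length, f"{gid}_decoy",
                     3.0 + 5.0 * rng.random(), rng.uniform(0.01, 0.5))
    return rows


def write_peaks_bed(rows: Sequence[dict], path: str | Path) -> None:
    """BED6+2: columns 7-8 are log2 fold enrichment and p-value."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['name']}\t"
                f"{r['score']}\t{r['strand']}\t{r['log2_fold_enrichment']:.4f}\t"
                f"{r['p_value']:.4g}\n"
            )


def simulate_strata(
    n_per_stratum: int,
    rng_seed: int = 0,
    strata: Sequence[str] = ("peaks_on_clusters", "peaks_off_clusters", "peaks_no_clusters"),
) -> dict[str, str]:
    """Synthetic gene->stratum labels for expression-only studies."""
    labels: dict[str, str] = {}
    i = 0
    for s in strata:
        for _ in range(n_per_stratum):
            labels[f"gene{i:05d}"] = s
            i += 1
    return labels


def simulate_expression(
    genes: Sequence[str],
    strata: Mapping[str, str],
    config: SimulationConfig,
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """Per-isoform log2FC table with stratum-specific differential effects.

    Each stratum gene carries one differential isoform whose |log2FC| is
    drawn from the stratum's Normal(mean, sd) effect (clipped below at
    0.02) with random sign and a small adjusted p; remaining isoforms
    are null (log2FC ~ N(0, 0.2), p_adjusted >= 0.1).
    """
    rng = np.random.default_rng(
        config.rng_seed + 2 if rng_seed is None else rng_seed
    )
    rows = []
    for gid in genes:
        stratum = strata.get(gid)
        n_iso = int(rng.integers(2, 5))
        for j in range(n_iso):
            iso = f"{gid}.i{j + 1}"
            if stratum is not None and j == 0:
                mean, sd = config.stratum_effects[stratum]
                mag = max(0.02, rng.normal(mean, sd))
                sign = rng.choice([-1.0, 1.0])
                rows.append(
                    {
                        "gene_id": gid,
                        "isoform_id": iso,
                        "log2_fold_change": round(sign * mag, 6),
                        "p_adjusted": float(f"{10.0 ** (-rng.uniform(2, 6)):.4g}"),
                    }
                )
            else:
                rows.append(
                    {
                        "gene_id": gid,
                        "isoform_id": iso,
                        "log2_fold_change": round(rng.normal(0.0, 0.2), 6),
                        "p_adjusted": round(rng.uniform(0.1, 1.0), 6),
                    }
                )
    return pd.DataFrame(rows)


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
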