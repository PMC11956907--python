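"""Numeric parameters of the cluster analysis.

All thresholds used anywhere in the pipeline live here so that a run is
fully described by one :class:`AnalysisParameters` instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class AnalysisParameters:
    """Tunable constants of the (T)GCATG cluster analysis.

    Attributes
    ----------
    window_bp
        Maximum first-to-last span (motif footprint included) of a seed
        window, in bp.  A cluster seed is ``min_sites_seed`` motif sites
        confined within this many nucleotides.
    min_sites_seed
        Minimum number of GCATG sites required to seed a cluster.
    extension_bp
        A site closer than this (strict ``<``, gap between the site
        footprint and the cluster interval) is absorbed into the cluster.
    proximal_intron_bp
        Intronic bases within this distance of the nearest exon boundary
        are "proximal intron"; farther bases are "distal intron".
    enrichment_min_sites
        Only clusters with at least this many sites enter the repeat-motif
        enrichment analysis.
    enrichment_flank_bp
        Clusters are extended by this many bp on both sides before motif
        counting.
    n_background
        Number of random background sequences for the enrichment test.
    peak_min_log2fe, peak_max_p
        CLIP-peak retention filter: log2 fold enrichment >= peak_min_log2fe
        and p-value <= peak_max_p (both boundaries inclusive).
    significance_p
        Significance level for the isoform-association chi-square and
        t tests and for the enrichment FDR call.
    rng_seed
        Seed for every stochastic step (background sampling, simulation).
    """

    window_bp: int = 500
    min_sites_seed: int = 4
    extension_bp: int = 500
    proximal_intron_bp: int = 500
    enrichment_min_sites: int = 5
    enrichment_flank_bp: int = 50
    n_background: int = 10_000
    peak_min_log2fe: float = 3.0
    peak_max_p: float = 0.001
    significance_p: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "window_bp",
            "min_sites_seed",
            "extension_bp",
            "proximal_intron_bp",
            "enrichment_min_sites",
            "enrichment_flank_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        if not (0 < self.peak_max_p <= 1):
            raise ValueError("peak_max_p must lie in (0, 1]")
        if not (0 < self.significance_p <= 1):
            raise ValueError("significance_p must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParameters":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
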