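"""Stratified isoform fold-change association.

Genes with CLIP peaks are stratified by whether their peaks fall on
motif clusters; isoform log2 fold changes (from an upstream
differential-expression table, consumed as-is) are then compared across
strata two ways: the fraction of genes with at least one differential
isoform exceeding a percent-fold-change threshold (curve over a
threshold grid), and the per-gene isoform-modulation summary (max
|log2FC| over differential isoforms) via a two-sided Student t test.
Percent fold change maps to log2FC as percent = (2^|log2FC| - 1) * 100,
so |log2FC| = 1 is exactly a 100% change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import AnalysisParameters

logger = logging.getLogger(__name__)

STRATA = ("peaks_on_clusters", "peaks_off_clusters", "peaks_no_clusters")

DEFAULT_THRESHOLDS = tuple(range(5, 101, 5))

REQUIRED_COLUMNS = ("gene_id", "isoform_id", "log2_fold_change", "p_adjusted")


@dataclass
class StratumSummary:
    """Per-stratum percent-changed curve and mean isoform modulation."""

    stratum: str
    n_genes: int
    thresholds: tuple[int, ...]
    percent_with_change: dict[int, float]
    mean_abs_log2fc: float
    sem: float


def read_isoform_table(path: str | Path, diff_alpha: float = 0.05) -> pd.DataFrame:
    """Read a TSV of per-isoform log2FC and adjusted p-values.

    Adds ``is_differential`` = (p_adjusted <= diff_alpha).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"isoform table {path} lacks columns {missing}")
    if ((df["p_adjusted"] < 0) | (df["p_adjusted"] > 1)).any():
        raise ValueError("p_adjusted outside [0, 1]")
    df = df.copy()
    df["is_differential"] = df["p_adjusted"] <= diff_alpha
    return df


def percent_fold_change(log2fc: float | np.ndarray) -> float | np.ndarray:
    """Map |log2FC| to percent fold change: (2^|log2FC| - 1) * 100."""
    return (np.exp2(np.abs(log2fc)) - 1.0) * 100.0


def _gene_stats(
    records: pd.DataFrame,
    gene_ids: set[str],
    summary: str = "max",
) -> pd.Series:
    """Per-gene isoform-modulation statistic over differential isoforms.

    Genes without any differential isoform are absent from the result.
    """
    diff = records[records["is_differential"] & records["gene_id"].isin(gene_ids)]
    if diff.empty:
        return pd.Series(dtype=float)
    absfc = diff["log2_fold_change"].abs()
    grouped = absfc.groupby(diff["gene_id"])
    if summary == "max":
        return grouped.max()
    if summary == "mean":
        return grouped.mean()
    raise ValueError(f"unknown per-gene summary {summary!r}")


def percent_change_curve(
    records: pd.DataFrame,
    strata: Mapping[str, str],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    summary: str = "max",
) -> dict[str, StratumSummary]:
    """Percent-of-genes-changed curves per stratum.

    ``strata`` maps gene_id -> stratum label.  A gene counts as changed
    at threshold t% iff it has a differential isoform with
    (2^|log2FC| - 1)*100 >= t.  Genes missing from the expression table
    are logged and excluded.
    """
    if "is_differential" not in records.columns:
        raise ValueError("records need an is_differential column (read_isoform_table)")
    present = set(records["gene_id"])
    thresholds = tuple(int(t) for t in thresholds)
    out: dict[str, StratumSummary] = {}
    for stratum in sorted(set(strata.values())):
        gene_ids = {g for g, s in strata.items() if s == stratum}
        missing = gene_ids - present
        if missing:
            logger.warning(
                "stratum %s: %d genes missing from expression table, excluded",
                stratum,
                len(missing),
            )
        gene_ids &= present
        if not gene_ids:
            raise ValueError(f"stratum {stratum} has no genes in the expression table")
        diff = records[records["is_differential"] & records["gene_id"].isin(gene_ids)]
        max_pct = (
            percent_fold_change(diff["log2_fold_change"].to_numpy())
            .astype(float)
        )
        gene_max_pct = pd.Series(max_pct, index=diff["gene_id"]).groupby(level=0).max()
        n = len(gene_ids)
        curve = {
            t: 100.0 * float((gene_max_pct >= t).sum()) / n for t in thresholds
        }
        stat = _gene_stats(records, gene_ids, summary)
        mean = float(stat.mean()) if len(stat) else float("nan")
        sem = float(stat.std(ddof=1) / np.sqrt(len(stat))) if len(stat) > 1 else float("nan")
        out[stratum] = StratumSummary(
            stratum=stratum,
            n_genes=n,
            thresholds=thresholds,
            percent_with_change=curve,
            mean_abs_log2fc=mean,
            sem=sem,
        )
    return out


def compare_strata(
    records: pd.DataFrame,
    strata: Mapping[str, str],
    params: AnalysisParameters | None = None,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    summary: str = "max",
) -> dict:
    """Pairwise stratum comparison: chi-square curves + Student t test.

    For every stratum pair, a chi-square test on changed/unchanged gene
    counts at each threshold and a two-sided Student t test (equal
    variances) on the per-gene max |log2FC| over differential isoforms.
    Means +/- SEM are reported per stratum.  Requires >= 2 genes with a
    differential isoform per stratum.
    """
    params = params or AnalysisParameters()
    summaries = percent_change_curve(records, strata, thresholds, summary)
    labels = sorted(summaries)
    if len(labels) < 2:
        raise ValueError("compare_strata needs >= 2 non-empty strata")
    present = set(records["gene_id"])
    gene_stats = {
        s: _gene_stats(
            records, {g for g, lab in strata.items() if lab == s} & present, summary
        )
        for s in labels
    }
    for s, stat in gene_stats.items():
        if len(stat) < 2:
            raise ValueError(
                f"stratum {s} has {len(stat)} genes with a differential isoform; "
                "need >= 2 for the t test"
            )
    report: dict = {
        "significance_p": params.significance_p,
        "strata": {
            s: {
                "n_genes": summaries[s].n_genes,
                "mean_abs_log2fc": summaries[s].mean_abs_log2fc,
                "sem": summaries[s].sem,
                "percent_with_change": summaries[s].percent_with_change,
            }
            for s in labels
        },
        "pairwise": {},
    }
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            t_stat, t_p = stats.ttest_ind(
                gene_stats[a], gene_stats[b], equal_var=True
            )
            chi_per_threshold = {}
            na, nb = summaries[a].n_genes, summaries[b].n_genes
            for t in summaries[a].thresholds:
                ca = round(summaries[a].percent_with_change[t] * na / 100.0)
                cb = round(summaries[b].percent_with_change[t] * nb / 100.0)
                table = np.array([[ca, na - ca], [cb, nb - cb]])
                if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
                    chi_per_threshold[t] = {"chi2": 0.0, "p_value": 1.0}
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                    chi_per_threshold[t] = {"chi2": float(chi2), "p_value": float(p)}
            report["pairwise"][f"{a}|{b}"] = {
                "t_statistic": float(t_stat),
                "t_p_value": float(t_p),
                "t_significant": bool(t_p < params.significance_p),
                "chi_square": chi_per_threshold,
            }
    return report


def write_stratum_summaries(
    summaries: Mapping[str, StratumSummary], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("stratum\tn_genes\tthreshold_pct\tpercent_with_change\t"
                 "mean_abs_log2fc\tsem\n")
        for s in sorted(summaries):
            summ = summaries[s]
            for t in summ.thresholds:
                fh.write(
                    f"{s}\t{summ.n_genes}\t{t}\t"
                    f"{summ.percent_with_change[t]:.6g}\t"
                    f"{summ.mean_abs_log2fc:.6g}\t{summ.sem:.6g}\n"
                )


def curve_plot(summaries: Mapping[str, StratumSummary], path) -> None:
    """Percent-changed vs threshold curves per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in sorted(summaries):
        summ = summaries[s]
        ax.plot(
            summ.thresholds,
            [summ.percent_with_change[t] for t in summ.thresholds],
            marker="o",
            ms=3,
            label=s,
        )
    ax.set_xlabel("% fold change threshold")
    ax.set_ylabel("% genes with isoform change")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
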