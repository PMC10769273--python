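"""Annotation-quality metrics and group statistics.

Per-genome metrics: number of genes, median gene length (stop codon
included), coding density (percent of genome bases covered by the union
of gene intervals across both strands), genes per kb and, when a
per-gene function table is supplied, the fraction of genes with a
non-hypothetical product.  Cohorts are compared metric-by-metric with
Welch t-tests, jointly adjusted with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .orf_engine import Gene

# Display tier used for significance annotation in cohort reports.
DEFAULT_SIGNIFICANCE = 1e-10


@dataclass
class GenomeStats:
    genome_id: str
    genome_len: int
    n_genes: int
    median_gene_len: float
    coding_density: float
    genes_per_kb: float
    frac_annotated: float | None = None


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    metric: str
    p_raw: float
    p_adj: float
    significant: bool


def _intervals(genes: Iterable[Gene], genome_len: int) -> list[tuple[int, int]]:
    """Gene intervals clipped to the genome; wrap-around genes (from
    circular annotation) with end > genome_len are split at the origin."""
    out = []
    for g in genes:
        if not (0 <= g.start < g.end):
            raise ValueError(f"invalid gene interval [{g.start}, {g.end})")
        if g.end <= genome_len:
            out.append((g.start, g.end))
        else:
            out.append((g.start, genome_len))
            out.append((0, g.end - genome_len))
    return out


def coding_density(genes: Sequence[Gene], genome_len: int) -> float:
    """Percent of genome bases covered by at least one gene.

    The union of intervals is taken across both strands, so overlapping
    bases count once.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    by_contig: dict[str, list[Gene]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    covered = 0
    for contig_genes in by_contig.values():
        iv = sorted(_intervals(contig_genes, genome_len))
        cur_s = cur_e = None
        for s, e in iv:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
    return 100.0 * covered / genome_len


def frac_annotated(genes: Sequence[Gene], functions: Mapping[str, str]) -> float:
    """Percent of genes whose product is informative (not hypothetical)."""
    if not genes:
        return 0.0
    n = 0
    for g in genes:
        product = str(functions.get(g.gene_id, "") or "").strip()
        if product and product.lower() != "hypothetical protein":
            n += 1
    return 100.0 * n / len(genes)


def summarize_genome(
    genes: Sequence[Gene],
    genome_len: int,
    genome_id: str = "genome",
    functions: Mapping[str, str] | None = None,
) -> GenomeStats:
    """All per-genome metrics; an empty gene set yields zeros."""
    lengths = [g.end - g.start for g in genes]
    return GenomeStats(
        genome_id=genome_id,
        genome_len=genome_len,
        n_genes=len(genes),
        median_gene_len=float(np.median(lengths)) if lengths else 0.0,
        coding_density=coding_density(genes, genome_len),
        genes_per_kb=1000.0 * len(genes) / genome_len,
        frac_annotated=(
            frac_annotated(genes, functions) if functions is not None else None
        ),
    )


def median_of_medians(
    stats: Sequence[GenomeStats], field: str = "median_gene_len"
) -> float:
    """Cohort summary: median across genomes of a per-genome value."""
    if not stats:
        raise ValueError("empty cohort")
    return float(np.median([getattr(s, field) for s in stats]))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def welch_pvalue(a, b, paired: bool = False) -> float:
    """Two-sided t-test p-value; Welch by default, paired on request.

    Degenerate comparisons with zero variance in both groups and equal
    means return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        p = sps.ttest_rel(a, b).pvalue
    else:
        p = sps.ttest_ind(a, b, equal_var=False).pvalue
    if np.isnan(p):
        p = 1.0
    return float(p)


def compare_groups(
    comparisons: Sequence[tuple[str, str, str, Sequence[float], Sequence[float]]],
    paired: bool = False,
    significance: float = DEFAULT_SIGNIFICANCE,
) -> list[GroupComparison]:
    """Run every comparison and adjust jointly.

    ``comparisons`` is a list of (group_a, group_b, metric, values_a,
    values_b).  BH adjustment spans all comparisons in the call, so a
    report's p_adj values are mutually consistent.
    """
    raw = [welch_pvalue(va, vb, paired=paired) for _, _, _, va, vb in comparisons]
    adj = benjamini_hochberg(raw) if raw else np.empty(0)
    return [
        GroupComparison(
            group_a=ga, group_b=gb, metric=m,
            p_raw=p, p_adj=float(q), significant=bool(q <= significance),
        )
        for (ga, gb, m, _, _), p, q in zip(comparisons, raw, adj)
    ]


def stats_frame(stats: Sequence[GenomeStats]) -> pd.DataFrame:
    """Per-genome stats as a tidy table (for TSV reports)."""
    return pd.DataFrame([vars(s) for s in stats])


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])
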