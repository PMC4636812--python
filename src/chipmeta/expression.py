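"""Binding-versus-expression integration.

Genes are ranked by FPKM into five near-equal groups (group 1 = highest
expression), per-group occupancy is summarized as notched boxplot statistics,
and bound genes are compared with all genes by a two-sided Wilcoxon rank-sum
test on log2(FPKM + pseudocount).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ExpressionRecord

LOG2_PSEUDOCOUNT = 0.1
N_GROUPS = 5


@dataclass
class ExpressionGroups:
    labels: pd.Series  # gene_id -> group (1..5, 1 = highest FPKM)
    boundaries: list[float]  # lowest FPKM of each group, in group order
    sizes: list[int]

    def genes_in(self, group: int) -> list[str]:
        return list(self.labels.index[self.labels == group])


@dataclass
class BoxplotSummary:
    group: int
    n: int
    median: float
    q1: float
    q3: float
    notch: float  # half-width, 1.58 * IQR / sqrt(n)
    empty: bool = False


@dataclass
class BoundVsAllResult:
    n_all: int
    n_bound: int
    median_all_log2: float
    median_bound_log2: float
    statistic: float
    p_value: float


def _split_sizes(n: int, groups: int) -> list[int]:
    base, extra = divmod(n, groups)
    return [base + (1 if i < extra else 0) for i in range(groups)]


def rank_expression_quintiles(
    expression: list[ExpressionRecord], n_groups: int = N_GROUPS
) -> ExpressionGroups:
    """Sort genes by FPKM (descending, ties by gene id) and split into
    ``n_groups`` groups whose sizes differ by at most one gene."""
    if len(expression) < n_groups:
        raise ValueError(f"need >= {n_groups} genes, got {len(expression)}")
    ordered = sorted(expression, key=lambda r: (-r.fpkm, r.gene_id))
    sizes = _split_sizes(len(ordered), n_groups)
    labels = {}
    boundaries = []
    i = 0
    for group, size in enumerate(sizes, start=1):
        chunk = ordered[i : i + size]
        for rec in chunk:
            labels[rec.gene_id] = group
        boundaries.append(chunk[-1].fpkm)
        i += size
    return ExpressionGroups(pd.Series(labels, name="group"), boundaries, sizes)


def group_density_summary(
    per_gene_density: pd.Series,
    groups: ExpressionGroups,
    drop_zeros: bool = True,
) -> list[BoxplotSummary]:
    """Notched-boxplot statistics of occupancy per expression group.

    Zero densities are excluded before the quartiles when ``drop_zeros`` —
    genes with no peak carry no occupancy information.
    """
    out = []
    for group in range(1, len(groups.sizes) + 1):
        genes = groups.genes_in(group)
        vals = per_gene_density.reindex(genes).dropna().to_numpy(dtype=float)
        if drop_zeros:
            vals = vals[vals > 0]
        if len(vals) == 0:
            out.append(BoxplotSummary(group, 0, np.nan, np.nan, np.nan, np.nan, empty=True))
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        notch = 1.58 * (q3 - q1) / np.sqrt(len(vals))
        out.append(BoxplotSummary(group, len(vals), float(med), float(q1), float(q3), float(notch)))
    return out


def compare_bound_vs_all(
    expression: list[ExpressionRecord],
    bound_genes: set[str],
    pseudocount: float = LOG2_PSEUDOCOUNT,
) -> BoundVsAllResult:
    """log2(FPKM + pseudocount) of bound genes versus all genes, with a
    two-sided Wilcoxon rank-sum test."""
    if not bound_genes:
        raise ValueError("bound gene set is empty")
    all_ids = {r.gene_id for r in expression}
    missing = bound_genes - all_ids
    if missing:
        raise ValueError(f"{len(missing)} bound genes absent from the expression table")
    log2 = {r.gene_id: np.log2(r.fpkm + pseudocount) for r in expression}
    all_vals = np.array(list(log2.values()))
    bound_vals = np.array([log2[g] for g in sorted(bound_genes)])
    stat, p = stats.ranksums(bound_vals, all_vals)
    return BoundVsAllResult(
        n_all=len(all_vals),
        n_bound=len(bound_vals),
        median_all_log2=float(np.median(all_vals)),
        median_bound_log2=float(np.median(bound_vals)),
        statistic=float(stat),
        p_value=float(p),
    )


def summaries_to_frame(summaries: list[BoxplotSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
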