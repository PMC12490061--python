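"""Feature selection from the per-gene statistic table.

Selection combines two cutoffs: an FDR threshold on the adjusted p-value of
phi', and a quantile cutoff on phi' applied AMONG the significant genes
("top 10% of significant phi'" means the genes above the 0.9 quantile of the
significant genes' phi' values).  Dataset-level statistics drive recommended
defaults: shallow or small datasets keep the top 10%; deep, large datasets
where significance is rare (< 5% of genes) can afford the top 1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "DatasetStats",
    "SelectionPolicy",
    "dataset_statistics",
    "recommend_policy",
    "select_features",
]


@dataclass
class DatasetStats:
    n_cells: int
    median_umi_per_cell: float
    total_umi: int
    fraction_significant: float


@dataclass
class SelectionPolicy:
    """Joint significance/magnitude cutoffs.

    fdr_threshold >= 1 disables the significance filter entirely; quantile
    is interpreted as "keep genes above this quantile of significant phi'".
    """

    fdr_threshold: float = 0.05
    quantile: float = 0.90
    rationale: str = "manual"

    def __post_init__(self):
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if not 0 <= self.quantile < 1:
            raise ValueError("quantile must be in [0, 1)")


def dataset_statistics(counts: CountMatrix, table: pd.DataFrame) -> DatasetStats:
    """Summary statistics that inform the recommended selection policy."""
    depths = counts.cell_totals()
    fdr = table["fdr"].to_numpy(dtype=float)
    tested = np.isfinite(fdr)
    frac = float(np.mean(fdr[tested] < 0.05)) if tested.any() else 0.0
    return DatasetStats(
        n_cells=counts.n_cells,
        median_umi_per_cell=float(np.median(depths)),
        total_umi=int(counts.grand_total()),
        fraction_significant=frac,
    )


def recommend_policy(stats: DatasetStats) -> SelectionPolicy:
    """Deterministic policy from dataset statistics.

    Fewer than 150 cells or a median depth under 3,000 UMI/cell: keep the
    top 10% of significant phi' (shallow-small).  Deep and large with under
    5% of genes significant: top 1% (subtle differences).  Otherwise the
    top 10% (deep-large).
    """
    if stats.n_cells < 150 or stats.median_umi_per_cell < 3000:
        return SelectionPolicy(0.05, 0.90, "shallow-small")
    if stats.fraction_significant < 0.05:
        return SelectionPolicy(0.05, 0.99, "subtle")
    return SelectionPolicy(0.05, 0.90, "deep-large")


def select_features(table: pd.DataFrame, policy: SelectionPolicy) -> list:
    """Apply the policy and return selected gene ids, best phi' first.

    Significant genes are those with fdr < fdr_threshold (all tested genes
    when the threshold is 1).  Among them, genes at or above the policy
    quantile of their phi' values are kept; boundary ties are included.
    Sets the table's ``selected`` column in place.  An empty selection is
    returned with a warning, not an error.
    """
    phi = table["modified_fano"].to_numpy(dtype=float)
    tested = np.isfinite(phi)
    if policy.fdr_threshold < 1:
        fdr = table["fdr"].to_numpy(dtype=float)
        if not np.isfinite(fdr[tested]).any():
            raise ValueError("policy requires p-values but the table has none")
        significant = tested & (fdr < policy.fdr_threshold)
    else:
        significant = tested
    table["selected"] = False
    if not significant.any():
        warnings.warn("no gene passes the significance cutoff; empty selection")
        return []
    cutoff = np.quantile(phi[significant], policy.quantile)
    chosen = significant & (phi >= cutoff)
    table.loc[chosen, "selected"] = True
    ids = table.loc[chosen, "gene_id"]
    order = np.argsort(-phi[chosen], kind="stable")
    return list(ids.to_numpy()[order])
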