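"""End-to-end feature selection: counts -> per-gene statistic table.

Order of operations: filter lowly detected genes, derive depth-corrected
means from the margins, compute plain and modified corrected Fano factors
from the raw counts, fit the consensus biological CV when none is supplied,
attach moment-based upper-tail p-values with BH adjustment, and apply the
selection policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .core import (
    depth_corrected_means,
    filter_genes,
    modified_corrected_fano_from_counts,
    plain_fano,
)
from .cv import CvFitResult, fit_consensus_cv
from .nulldist import bh_adjust, phi_prime_null_cumulants, tail_pvalues
from .selection import (
    SelectionPolicy,
    dataset_statistics,
    recommend_policy,
    select_features,
)

__all__ = ["FeatureSelectionResult", "compute_feature_table", "run_feature_selection"]

# genes below this mean expression sit under the CV fitting window and their
# phi' is numerically delicate; they are reported but flagged
LOW_EXPRESSION_MEAN = 0.01


@dataclass
class FeatureSelectionResult:
    table: pd.DataFrame
    cv: float
    cv_fit: CvFitResult | None
    counts: CountMatrix = field(repr=False)
    policy: SelectionPolicy | None = None
    selected: list = field(default_factory=list)


def compute_feature_table(
    counts: CountMatrix,
    cv: float | None = None,
    compute_pvalues: bool = True,
    min_cells: int = 3,
) -> FeatureSelectionResult:
    """Per-gene means, Fano factors, phi' and (optionally) p-values.

    ``cv=None`` triggers the consensus fit.  Disabling p-values skips the
    null-moment machinery, which dominates runtime on large matrices.
    """
    counts = filter_genes(counts, min_cells)
    mu = depth_corrected_means(counts)
    fano, mean, var = plain_fano(counts, return_moments=True)
    cv_fit = None
    if cv is None:
        cv_fit = fit_consensus_cv(counts)
        cv = cv_fit.cv
    phi = modified_corrected_fano_from_counts(counts, cv, mu=mu)
    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "mean": mean,
            "variance": var,
            "fano": fano,
            "modified_fano": phi,
            "pvalue": np.nan,
            "fdr": np.nan,
            "selected": False,
            "low_expression": mean < LOW_EXPRESSION_MEAN,
        }
    )
    if compute_pvalues:
        cums = phi_prime_null_cumulants(mu, cv)
        table["pvalue"] = tail_pvalues(cums, phi)
        table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    return FeatureSelectionResult(table=table, cv=cv, cv_fit=cv_fit, counts=counts)


def run_feature_selection(
    counts: CountMatrix,
    cv: float | None = None,
    policy: SelectionPolicy | None = None,
    auto_policy: bool = False,
    min_cells: int = 3,
) -> FeatureSelectionResult:
    """Full pipeline through feature selection.

    ``auto_policy`` derives the cutoffs from dataset statistics; otherwise
    ``policy`` (default: fdr < 0.05, top 10% of significant phi') is used.
    """
    res = compute_feature_table(counts, cv=cv, min_cells=min_cells)
    if auto_policy:
        policy = recommend_policy(dataset_statistics(res.counts, res.table))
    elif policy is None:
        policy = SelectionPolicy()
    res.policy = policy
    res.selected = select_features(res.table, policy)
    return res
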