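"""Clustering evaluation against known target cells.

Given cluster labels and a boolean mask of "target" cells (a known rare
population or a simulated group), the purity score is the fraction of target
cells captured by the single cluster holding the most of them, with an
upper-tail hypergeometric p-value for how surprising that concentration is
under random assignment.  The normalized entropy of the targets'
distribution over clusters, and per-cluster marker enrichment scores,
complete the panel.  ``cluster_cells`` is a thin adapter over the standard
log-normalize / PCA / nearest-neighbor / Leiden pipeline; its internals
carry no methodological novelty and only the determinism contract (fixed
seed -> fixed labels) matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom

from .containers import CountMatrix

__all__ = [
    "ClusterLabels",
    "PurityResult",
    "log_normalize",
    "cluster_cells",
    "purity_score",
    "mean_group_purity",
    "purity_pvalue",
    "enrichment_score",
    "normalized_entropy",
    "multiseed_evaluation",
]


@dataclass
class ClusterLabels:
    labels: np.ndarray
    n_clusters: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=0) < 0 or (
            self.labels.size and self.labels.max() >= self.n_clusters
        ):
            raise ValueError("labels must lie in [0, n_clusters)")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


@dataclass
class PurityResult:
    purity: float
    best_cluster: int
    M: int  # dataset size
    n_targets: int
    N: int  # best cluster size
    k: int  # target cells in best cluster
    pvalue: float
    tied: bool = False


def log_normalize(counts: CountMatrix, target_sum: float = 1e4) -> sp.csr_matrix:
    """ln(count / cell_total * target_sum + 1), sparse cells x genes."""
    depths = counts.cell_totals()
    if np.any(depths <= 0):
        raise ValueError("every cell must have a positive total count")
    mat = counts.counts.tocsr().astype(float)
    scaled = sp.diags(target_sum / depths) @ mat
    scaled.data = np.log1p(scaled.data)
    return scaled


def cluster_cells(
    counts: CountMatrix,
    feature_ids,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 50,
    n_neighbors: int = 15,
) -> ClusterLabels:
    """Leiden community labels from the standard reduction pipeline.

    Log-normalizes over all genes, subsets to the feature genes, reduces to
    up to ``n_pcs`` principal components (fewer when rank-limited), builds a
    k-nearest-neighbor graph and runs Leiden at the given resolution and
    random seed.  Deterministic for fixed inputs and seed.
    """
    import scanpy as sc
    from anndata import AnnData

    feature_ids = np.asarray(feature_ids, dtype=object)
    present = np.isin(feature_ids, counts.gene_ids)
    if present.sum() < 2:
        raise ValueError("need at least 2 features present in the matrix")
    norm = log_normalize(counts)
    adata = AnnData(
        X=norm.astype(np.float32),
        obs=pd.DataFrame(index=counts.cell_ids.astype(str)),
        var=pd.DataFrame(index=counts.gene_ids.astype(str)),
    )
    adata = adata[:, np.isin(counts.gene_ids, feature_ids[present])].copy()
    n_comps = int(min(n_pcs, adata.n_obs - 1, adata.n_vars - 1))
    sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=0)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=0)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        key_added="leiden",
        flavor="leidenalg",
    )
    codes = adata.obs["leiden"].astype(int).to_numpy()
    return ClusterLabels(codes, int(codes.max()) + 1)


def purity_pvalue(M: int, n: int, N: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(K >= k).

    K is the number of target cells landing in a fixed cluster of size N
    when the n targets are placed at random among M cells without
    replacement.
    """
    if not (0 <= k <= min(n, N) and n <= M and N <= M):
        raise ValueError("inconsistent hypergeometric arguments")
    return float(hypergeom.sf(k - 1, M, n, N))


def purity_score(labels: ClusterLabels, targets: np.ndarray) -> PurityResult:
    """Fraction of target cells inside the cluster holding the most of them.

    Ties between clusters with equal target counts are broken toward the
    smaller cluster (highest concentration) and flagged in the result.
    """
    targets = np.asarray(targets, dtype=bool)
    if targets.size != labels.labels.size:
        raise ValueError("targets mask must match the number of cells")
    n_targets = int(targets.sum())
    if n_targets == 0:
        raise ValueError("at least one target cell is required")
    per_cluster = np.bincount(labels.labels[targets], minlength=labels.n_clusters)
    k = int(per_cluster.max())
    candidates = np.flatnonzero(per_cluster == k)
    sizes = labels.sizes()
    best = int(candidates[np.argmin(sizes[candidates])])
    return PurityResult(
        purity=k / n_targets,
        best_cluster=best,
        M=int(targets.size),
        n_targets=n_targets,
        N=int(sizes[best]),
        k=k,
        pvalue=purity_pvalue(int(targets.size), n_targets, int(sizes[best]), k),
        tied=candidates.size > 1,
    )


def mean_group_purity(labels: ClusterLabels, group_labels: np.ndarray) -> float:
    """Mean purity over each group treated in turn as the target set.

    The aggregation used when scoring simulated multi-group data, where no
    single group is the designated rare population.
    """
    group_labels = np.asarray(group_labels)
    groups = np.unique(group_labels)
    return float(
        np.mean([purity_score(labels, group_labels == g).purity for g in groups])
    )


def enrichment_score(
    normalized, labels: ClusterLabels, gene, gene_ids=None
) -> tuple[np.ndarray, float]:
    """Per-cluster mean expression of one gene over its dataset-wide mean.

    ``gene`` may be an integer column index or, when ``gene_ids`` is given,
    an identifier.  Returns (per-cluster scores, greatest score).
    """
    if gene_ids is not None and not isinstance(gene, (int, np.integer)):
        hits = np.flatnonzero(np.asarray(gene_ids, dtype=object) == gene)
        if hits.size == 0:
            raise KeyError(f"gene {gene!r} absent from the matrix")
        gene = int(hits[0])
    col = normalized[:, gene]
    col = np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()
    overall = col.mean()
    if overall == 0:
        raise ValueError(f"gene index {gene} has zero dataset-wide mean expression")
    scores = np.array(
        [col[labels.labels == c].mean() / overall for c in range(labels.n_clusters)]
    )
    return scores, float(scores.max())


def normalized_entropy(labels: ClusterLabels, targets: np.ndarray) -> float:
    """Shannon entropy of the targets' split over clusters, scaled to [0, 1].

    eta = -sum_i p_i ln p_i / ln(n_clusters), with p_i the fraction of target
    cells in cluster i and 0 ln 0 = 0.  Requires at least two clusters.
    """
    targets = np.asarray(targets, dtype=bool)
    if targets.sum() == 0:
        raise ValueError("at least one target cell is required")
    if labels.n_clusters < 2:
        raise ValueError("normalized entropy requires at least 2 clusters")
    p = np.bincount(labels.labels[targets], minlength=labels.n_clusters)
    p = p[p > 0] / targets.sum()
    return float(-(p * np.log(p)).sum() / np.log(labels.n_clusters))


def multiseed_evaluation(
    counts: CountMatrix,
    feature_ids,
    targets: np.ndarray,
    seeds=range(40),
    resolution: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Repeat clustering over seeds and tabulate purity/entropy per seed.

    Returns the per-seed table and a median/IQR summary, mirroring the
    robustness protocol of reporting clustering metrics across many Leiden
    starting seeds.
    """
    rows = []
    for seed in seeds:
        labels = cluster_cells(counts, feature_ids, resolution=resolution, seed=int(seed))
        res = purity_score(labels, targets)
        eta = (
            normalized_entropy(labels, targets) if labels.n_clusters >= 2 else np.nan
        )
        rows.append(
            {
                "seed": int(seed),
                "n_clusters": labels.n_clusters,
                "purity": res.purity,
                "purity_pvalue": res.pvalue,
                "normalized_entropy": eta,
            }
        )
    table = pd.DataFrame(rows)
    q = table["purity"].quantile([0.25, 0.5, 0.75])
    summary = {
        "purity_median": float(q.loc[0.5]),
        "purity_iqr": [float(q.loc[0.25]), float(q.loc[0.75])],
        "entropy_median": float(table["normalized_entropy"].median()),
        "n_seeds": len(table),
    }
    return table, summary
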