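"""Synthetic Poisson-lognormal scRNA-seq datasets with known ground truth.

Generator model, per gene j and cell i:

1. an underlying mean mu_j = 10^x with x uniform on (-1, 0.8) (log-uniform
   gene expression levels spanning ~0.1 to ~6.3 mean UMI per cell);
2. a biological rate y_ij drawn from a lognormal with ACTUAL mean mu_j
   (times an optional per-cell depth factor) and coefficient of variation c
   (underlying-normal parameters: s^2 = ln(1 + c^2),
   location = ln(actual mean) - s^2/2);
3. an observed count z_ij ~ Poisson(y_ij).

Two-group datasets split cells into equal groups; "truly variable" genes get
independent mean draws per group while all other genes share one mean, so
group differences of variable genes are themselves centered on zero.

Random streams are split per gene (and separately for shared vs.
group-specific means), so changing the number of truly variable genes leaves
the counts of unaffected genes bit-identical for the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix
from .core import filter_genes

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "sample_gene_means",
    "simulate_counts",
    "make_two_group_dataset",
    "make_rare_mixture",
    "lognormal_depth_factors",
]

DEFAULT_LOG10_MEAN_RANGE = (-1.0, 0.8)


@dataclass
class SimulationSpec:
    """Parameters of a two-group synthetic dataset.

    Defaults mirror the simulated benchmark conditions: 2,000 cells by
    15,000 genes in two equal groups, biological CV c = 0.7, gene means
    log-uniform over 10^(-1)..10^(0.8) and constant sequencing depth.
    """

    n_cells: int = 2000
    n_genes: int = 15000
    n_groups: int = 2
    n_variable_genes: int = 0
    cv: float = 0.7
    log10_mean_range: tuple[float, float] = DEFAULT_LOG10_MEAN_RANGE
    depth_factors: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.n_variable_genes <= self.n_genes):
            raise ValueError("n_variable_genes must be in [0, n_genes]")
        if self.n_groups < 1 or self.n_cells < self.n_groups:
            raise ValueError("need at least one cell per group")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.depth_factors is not None:
            df = np.asarray(self.depth_factors, dtype=float)
            if df.shape != (self.n_cells,) or np.any(df <= 0):
                raise ValueError("depth_factors must be positive, one per cell")
            self.depth_factors = df

    def group_sizes(self) -> np.ndarray:
        base, extra = divmod(self.n_cells, self.n_groups)
        return np.array([base + (k < extra) for k in range(self.n_groups)])


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    group_labels: np.ndarray
    variable_gene_mask: np.ndarray
    true_means: np.ndarray  # (n_groups, n_genes)
    spec: SimulationSpec = field(repr=False, default=None)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_gene_means(
    n_genes: int,
    log10_range: tuple[float, float] = DEFAULT_LOG10_MEAN_RANGE,
    seed=0,
) -> np.ndarray:
    """Gene means 10^U with U uniform on ``log10_range``."""
    lo, hi = log10_range
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("log10_range must be finite")
    rng = _rng(seed)
    return 10.0 ** rng.uniform(lo, hi, size=n_genes)


def _pln_column(
    rng: np.random.Generator, mean: float, cv: float, depth: np.ndarray
) -> np.ndarray:
    """Counts for one gene across cells; depth multiplies the actual mean."""
    actual = mean * depth
    if cv == 0.0:
        return rng.poisson(actual)
    s2 = np.log1p(cv * cv)
    y = np.exp(rng.normal(np.log(actual) - 0.5 * s2, np.sqrt(s2)))
    return rng.poisson(y)


def simulate_counts(
    means: np.ndarray,
    cv: float,
    n_cells: int,
    depth_factors: np.ndarray | None = None,
    seed=0,
    cell_prefix: str = "cell_",
) -> CountMatrix:
    """One homogeneous cell population from the Poisson-lognormal generator.

    ``cv = 0`` degenerates exactly to Poisson sampling.  Each gene consumes
    its own random substream derived from ``seed``.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("means must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    depth = np.ones(n_cells) if depth_factors is None else np.asarray(depth_factors, float)
    if depth.shape != (n_cells,):
        raise ValueError("depth_factors must have one entry per cell")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(means.size)
    out = np.empty((n_cells, means.size), dtype=np.int32)
    for j, ss in enumerate(streams):
        out[:, j] = _pln_column(np.random.default_rng(ss), means[j], cv, depth)
    cm = CountMatrix(
        sp.csr_matrix(out),
        cell_ids=[f"{cell_prefix}{i}" for i in range(n_cells)],
        gene_ids=[f"gene_{j}" for j in range(means.size)],
    )
    return cm


def make_two_group_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Simulate a dataset of ``n_groups`` equal cell groups with ground truth.

    The first ``n_variable_genes`` genes are truly variable: their
    group-specific means are independent draws from the log-uniform law.  All
    remaining genes share a single mean across groups.
    """
    root = np.random.SeedSequence(spec.seed)
    means_ss, var_ss, counts_ss = root.spawn(3)
    shared = sample_gene_means(spec.n_genes, spec.log10_mean_range, np.random.default_rng(means_ss))
    true_means = np.tile(shared, (spec.n_groups, 1))
    n_var = spec.n_variable_genes
    if n_var:
        var_rng = np.random.default_rng(var_ss)
        lo, hi = spec.log10_mean_range
        true_means[:, :n_var] = 10.0 ** var_rng.uniform(lo, hi, size=(spec.n_groups, n_var))
    mask = np.zeros(spec.n_genes, dtype=bool)
    mask[:n_var] = True

    sizes = spec.group_sizes()
    starts = np.concatenate([[0], np.cumsum(sizes)])
    labels = np.repeat(np.arange(spec.n_groups), sizes)
    depth = spec.depth_factors if spec.depth_factors is not None else np.ones(spec.n_cells)

    gene_streams = counts_ss.spawn(spec.n_genes)
    out = np.empty((spec.n_cells, spec.n_genes), dtype=np.int32)
    for j, ss in enumerate(gene_streams):
        rng = np.random.default_rng(ss)
        for k in range(spec.n_groups):
            rows = slice(starts[k], starts[k + 1])
            out[rows, j] = _pln_column(rng, true_means[k, j], spec.cv, depth[rows])
    counts = CountMatrix(
        sp.csr_matrix(out),
        cell_ids=[f"cell_{i}" for i in range(spec.n_cells)],
        gene_ids=[f"gene_{j}" for j in range(spec.n_genes)],
    )
    return SimulatedDataset(counts, labels, mask, true_means, spec)


def lognormal_depth_factors(n_cells: int, fold_range: float = 10.0, seed=0) -> np.ndarray:
    """Per-cell depth multipliers spanning ``fold_range`` (log-uniform), mean 1."""
    if fold_range < 1:
        raise ValueError("fold_range must be >= 1")
    rng = _rng(seed)
    half = 0.5 * np.log10(fold_range)
    f = 10.0 ** rng.uniform(-half, half, n_cells)
    return f / f.mean()


def make_rare_mixture(
    counts: CountMatrix,
    labels: np.ndarray,
    rare_group,
    rare_fraction: float = 0.05,
    seed=0,
    min_cells: int = 3,
) -> tuple[CountMatrix, np.ndarray]:
    """Mix a subsampled "rare" population into the remaining cells.

    The rare group is downsampled without replacement so its cells make up
    ``rare_fraction`` of the mixture (0.05 reproduces a 1:19 rare:common
    ratio).  Genes expressed in fewer than ``min_cells`` cells of the mixture
    are removed.  Returns the mixture and a boolean target mask marking the
    rare cells.
    """
    labels = np.asarray(labels)
    if not 0 < rare_fraction < 1:
        raise ValueError("rare_fraction must be in (0, 1)")
    rare_idx = np.flatnonzero(labels == rare_group)
    common_idx = np.flatnonzero(labels != rare_group)
    if rare_idx.size == 0 or common_idx.size == 0:
        raise ValueError("both the rare and the common group must be non-empty")
    n_rare = int(round(common_idx.size * rare_fraction / (1.0 - rare_fraction)))
    if n_rare < 1:
        raise ValueError("rare_fraction too small: would keep zero rare cells")
    if n_rare > rare_idx.size:
        max_f = rare_idx.size / (rare_idx.size + common_idx.size)
        raise ValueError(
            f"cannot reach rare_fraction={rare_fraction:g}: only {rare_idx.size} rare "
            f"cells available (maximum achievable fraction {max_f:.4f})"
        )
    if n_rare < rare_idx.size:
        rng = _rng(seed)
        rare_idx = np.sort(rng.choice(rare_idx, size=n_rare, replace=False))
    keep = np.concatenate([common_idx, rare_idx])
    mixture = counts.subset_cells(keep)
    targets = np.zeros(keep.size, dtype=bool)
    targets[common_idx.size:] = True
    mixture = filter_genes(mixture, min_cells)
    return mixture, targets
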