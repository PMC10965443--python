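"""Coarse-graining: collapse similar cells into super-cells before
co-expression estimation.

Droplet scRNA-seq counts are dominated by dropout zeros, which wreck
pairwise gene–gene correlation estimates.  Pooling each small neighborhood
of transcriptionally similar cells into one "super-cell" (a metacell)
trades resolution for depth: the pooled profiles are far less sparse, so
downstream Pearson correlations are estimated from informative counts.

The partition is built on a low-dimensional embedding: library-size
normalization, log1p, truncated PCA, a symmetrized k-nearest-neighbor
graph, then short-random-walk (walktrap) community agglomeration cut at
the dendrogram level whose group count is closest to ``n_cells / gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix

__all__ = [
    "SuperCellPartition",
    "CoarseMatrix",
    "SuperCellPartitioner",
    "compute_partition",
    "aggregate",
]


@dataclass
class SuperCellPartition:
    """Assignment of every cell to exactly one super-cell group."""

    assignment: np.ndarray  # group index per cell, aligned with cell_ids
    cell_ids: np.ndarray
    gamma: float
    n_groups: int
    embedding_dims: int
    seed: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.assignment) != len(self.cell_ids):
            raise ValueError("assignment length does not match cell count")
        distinct = np.unique(self.assignment)
        if self.n_groups != len(distinct):
            raise ValueError("n_groups does not match distinct group indices")
        if not 1 <= self.n_groups <= len(self.cell_ids):
            raise ValueError("n_groups out of range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "group": self.assignment})


@dataclass
class CoarseMatrix:
    """Genes x super-cells summed counts plus group sizes."""

    values: np.ndarray
    gene_ids: np.ndarray
    group_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.group_sizes = np.asarray(self.group_sizes, dtype=int)
        if self.values.shape != (len(self.gene_ids), len(self.group_sizes)):
            raise ValueError("coarse matrix shape mismatch")

    @property
    def n_groups(self) -> int:
        return self.values.shape[1]


def _normalize_log1p(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Counts-per-10k library-size normalization followed by log1p.

    Operates on a cells x genes dense array; all-zero cells pass through
    unchanged.
    """
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * target_sum)


class SuperCellPartitioner(ClusterMixin, BaseEstimator):
    """Group transcriptionally similar cells into super-cells.

    Parameters
    ----------
    gamma : float, default 10.0
        Target number of cells per super-cell; the partition aims for
        ``round(n_cells / gamma)`` groups.  ``gamma = 1`` returns the
        identity partition (no collapsing).
    n_components : int, default 25
        Dimensionality of the truncated PCA embedding (capped at the data
        rank).
    n_neighbors : int, default 5
        Neighbors per cell in the kNN graph; the graph is symmetrized as
        the union of directed neighbor relations.
    random_state : int, default 0
        Seed for the randomized SVD solver.  The remaining stages
        (neighbor search, walktrap merging) are deterministic.

    Attributes
    ----------
    labels_ : ndarray of shape (n_cells,)
        Group index per cell.
    n_groups_ : int
        Number of distinct groups.
    embedding_ : ndarray of shape (n_cells, k)
        The PCA embedding the kNN graph was built on.
    """

    def __init__(
        self,
        gamma: float = 10.0,
        n_components: int = 25,
        n_neighbors: int = 5,
        random_state: int = 0,
    ):
        self.gamma = gamma
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def fit(self, X, y=None):
        """Partition cells given a cells x genes count matrix."""
        if sp.issparse(X):
            X = np.asarray(X.todense())
        else:
            X = np.asarray(X, dtype=float)
        n_cells = X.shape[0]
        if n_cells < 2:
            raise ValueError("need at least 2 cells to partition")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.gamma > n_cells:
            raise ValueError(f"gamma={self.gamma} exceeds n_cells={n_cells}")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")

        if self.gamma == 1:
            self.labels_ = np.arange(n_cells)
            self.n_groups_ = n_cells
            self.embedding_ = None
            return self

        if n_cells < self.n_neighbors + 1:
            raise ValueError(
                f"{n_cells} cells is fewer than n_neighbors+1="
                f"{self.n_neighbors + 1}"
            )

        log_norm = _normalize_log1p(X)
        k = min(self.n_components, min(log_norm.shape) - 1)
        svd = TruncatedSVD(
            n_components=k, algorithm="randomized", random_state=self.random_state
        )
        embedding = svd.fit_transform(log_norm)

        nn = NearestNeighbors(n_neighbors=self.n_neighbors + 1).fit(embedding)
        adj = nn.kneighbors_graph(embedding, mode="connectivity")
        adj = adj.tolil()
        adj.setdiag(0)
        adj = adj.tocsr()
        adj = ((adj + adj.T) > 0).astype(np.int8)  # union symmetrization

        sources, targets = adj.nonzero()
        mask = sources < targets
        graph = ig.Graph(
            n=n_cells, edges=list(zip(sources[mask], targets[mask]))
        )
        dendrogram = graph.community_walktrap(steps=4)
        n_components_graph = len(graph.connected_components())
        target_groups = int(round(n_cells / self.gamma))
        # every count between #components and n_cells is reachable on the
        # merge path; clamp the target into that range
        n_groups = min(max(target_groups, n_components_graph), n_cells)
        clustering = dendrogram.as_clustering(n=n_groups)
        self.labels_ = np.asarray(clustering.membership, dtype=int)
        self.n_groups_ = len(set(clustering.membership))
        self.embedding_ = embedding
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def compute_partition(
    expr: ExpressionMatrix,
    gamma: float = 10.0,
    n_components: int = 25,
    n_neighbors: int = 5,
    seed: int = 0,
) -> SuperCellPartition:
    """Partition the cells of a genes x cells :class:`ExpressionMatrix`."""
    est = SuperCellPartitioner(
        gamma=gamma,
        n_components=n_components,
        n_neighbors=n_neighbors,
        random_state=seed,
    )
    labels = est.fit_predict(expr.values.T)
    dims = 0 if est.embedding_ is None else est.embedding_.shape[1]
    return SuperCellPartition(
        assignment=labels,
        cell_ids=expr.cell_ids,
        gamma=gamma,
        n_groups=est.n_groups_,
        embedding_dims=dims,
        seed=seed,
    )


def aggregate(expr: ExpressionMatrix, partition: SuperCellPartition) -> CoarseMatrix:
    """Sum member-cell counts per super-cell.

    Summation (not averaging) preserves the count nature of the data and
    total mass; downstream correlation is computed on per-super-cell
    normalized profiles so the varying group sizes do not leak in.
    """
    if len(partition.cell_ids) != expr.n_cells or not np.array_equal(
        partition.cell_ids, expr.cell_ids
    ):
        raise ValueError("partition cell ids do not match expression matrix")
    groups = np.unique(partition.assignment)
    n_groups = len(groups)
    remap = {g: i for i, g in enumerate(groups)}
    cols = np.array([remap[g] for g in partition.assignment])
    indicator = sp.csr_matrix(
        (np.ones(expr.n_cells), (np.arange(expr.n_cells), cols)),
        shape=(expr.n_cells, n_groups),
    )
    summed = np.asarray((expr.values @ indicator).todense())
    sizes = np.bincount(cols, minlength=n_groups)
    return CoarseMatrix(summed, expr.gene_ids, sizes)
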