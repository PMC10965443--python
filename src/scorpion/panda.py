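"""Message-passing refinement of a motif prior with PPI and co-expression
evidence.

Three networks are refined jointly: the regulatory network W (TF x gene,
seeded from motif scores), the cooperativity network P (TF x TF, seeded
from protein–protein interaction scores) and the co-regulation network C
(gene x gene, seeded from Pearson co-expression of coarse-grained
profiles).  All three are first normalized to z-score units.  Each
iteration computes, for every (TF i, gene j) pair, an availability
A_ij = T_Z(W_i., C_.j) — agreement between TF i's targeting profile and
gene j's co-expression profile — and a responsibility
R_ij = T_Z(P_i., W_.j) — agreement between TF i's cooperativity profile
and gene j's regulator profile — where T_Z is a continuous Tanimoto
similarity

    T_Z(x, y) = sum(x*y) / sqrt(sum(x^2) + sum(y^2) - |sum(x*y)|).

W moves a fraction ``alpha`` toward the average of A and R; P and C then
move the same fraction toward pairwise T_Z similarities of W's rows and
columns.  Iteration stops when the mean absolute change of W (a continuous
Hamming distance) drops below ``tol``.

The :class:`ScorpionGRN` estimator wraps the full pipeline — gene
filtering and prior alignment, super-cell coarse-graining, co-expression,
refinement — behind a scikit-learn ``fit`` interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .coarse import CoarseMatrix, _normalize_log1p, aggregate, compute_partition
from .io import ExpressionMatrix, Network, PriorEdgeList, align_universe

__all__ = [
    "tanimoto_z",
    "normalize_network",
    "build_coexpression",
    "NetworkTriple",
    "MessagePassingState",
    "message_passing_step",
    "hamming_distance",
    "refine",
    "build_network",
    "ScorpionGRN",
]

_SYM_TOL = 1e-10


def tanimoto_z(x: np.ndarray, y: np.ndarray) -> float:
    """Continuous Tanimoto similarity between two z-scored vectors.

    Returns ``sum(x*y) / sqrt(sum(x^2) + sum(y^2) - |sum(x*y)|)``; the
    denominator vanishes only when both vectors are identically zero, in
    which case 0 is returned (no information, no similarity).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y) or len(x) == 0:
        raise ValueError("tanimoto_z needs two equal-length 1-d vectors")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("tanimoto_z inputs must be finite")
    num = float(x @ y)
    den_sq = float(x @ x) + float(y @ y) - abs(num)
    if den_sq <= 0:
        return 0.0
    return num / np.sqrt(den_sq)


def _tanimoto_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """T_Z between every row of ``X`` and every column of ``Y``, vectorized."""
    num = X @ Y
    row_sq = np.einsum("ij,ij->i", X, X)[:, None]
    col_sq = np.einsum("ij,ij->j", Y, Y)[None, :]
    den_sq = row_sq + col_sq - np.abs(num)
    out = np.zeros_like(num)
    np.divide(num, np.sqrt(den_sq, where=den_sq > 0, out=np.ones_like(den_sq)),
              out=out, where=den_sq > 0)
    return out


def normalize_network(M: np.ndarray) -> np.ndarray:
    """Standardize a network to z-score units.

    Entry (i, j) becomes ``(zrow_ij + zcol_ij) / sqrt(2)``, where ``zrow``
    standardizes within row i and ``zcol`` within column j using the
    sample standard deviation.  A zero-variance row or column contributes
    0 for its term, so a globally constant matrix maps to all zeros.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("normalize_network input must be finite")
    row_mu = M.mean(axis=1, keepdims=True)
    row_sd = M.std(axis=1, ddof=1, keepdims=True) if M.shape[1] > 1 else np.zeros_like(row_mu)
    col_mu = M.mean(axis=0, keepdims=True)
    col_sd = M.std(axis=0, ddof=1, keepdims=True) if M.shape[0] > 1 else np.zeros_like(col_mu)
    zrow = np.divide(M - row_mu, row_sd, out=np.zeros_like(M), where=row_sd > 0)
    zcol = np.divide(M - col_mu, col_sd, out=np.zeros_like(M), where=col_sd > 0)
    return (zrow + zcol) / np.sqrt(2.0)


def build_coexpression(coarse: CoarseMatrix | np.ndarray) -> np.ndarray:
    """Raw gene x gene Pearson co-expression across super-cells.

    Profiles are library-size normalized per super-cell and log1p
    transformed before correlation.  Zero-variance genes get 0
    off-diagonal and 1 on the diagonal.  The result is in correlation
    units; :func:`refine` z-normalizes it before message passing.
    """
    values = coarse.values if isinstance(coarse, CoarseMatrix) else np.asarray(coarse, dtype=float)
    n_genes, n_groups = values.shape
    if n_groups < 3:
        raise ValueError(
            f"need >= 3 super-cells for a stable correlation, got {n_groups}"
        )
    profiles = _normalize_log1p(values.T).T  # normalize within each super-cell
    sd = profiles.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    zero_var = sd == 0
    if zero_var.any():
        corr[zero_var, :] = 0.0
        corr[:, zero_var] = 0.0
        np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class NetworkTriple:
    """The three jointly refined networks, all in z-score units."""

    W: np.ndarray  # TF x gene regulatory
    P: np.ndarray  # TF x TF cooperativity (symmetric)
    C: np.ndarray  # gene x gene co-regulation (symmetric)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n_tf, n_gene = self.W.shape
        if self.P.shape != (n_tf, n_tf):
            raise ValueError("P shape inconsistent with W rows")
        if self.C.shape != (n_gene, n_gene):
            raise ValueError("C shape inconsistent with W columns")
        for name, M in (("W", self.W), ("P", self.P), ("C", self.C)):
            if not np.all(np.isfinite(M)):
                raise ValueError(f"{name} contains non-finite entries")
        if np.abs(self.P - self.P.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("P is not symmetric")
        if np.abs(self.C - self.C.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("C is not symmetric")


@dataclass
class MessagePassingState:
    """Mutable state of the refinement loop."""

    triple: NetworkTriple
    alpha: float = 0.1
    tol: float = 0.001
    t: int = 0
    hamming_history: list[float] = field(default_factory=list)
    A: np.ndarray | None = None
    R: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def hamming_distance(W_prev: np.ndarray, W_next: np.ndarray) -> float:
    """Mean absolute entrywise difference between two weight matrices."""
    W_prev = np.asarray(W_prev, dtype=float)
    W_next = np.asarray(W_next, dtype=float)
    if W_prev.shape != W_next.shape:
        raise ValueError(f"shape mismatch {W_prev.shape} vs {W_next.shape}")
    return float(np.mean(np.abs(W_prev - W_next)))


def _inflate_diagonal(M: np.ndarray, alpha: float, t: int) -> None:
    """Set the diagonal of a pairwise-similarity matrix, in place.

    T_Z self-similarity grows with vector norm, so a raw diagonal would
    come to dominate the off-diagonal structure.  Instead the diagonal is
    set to (off-diagonal row SD) * n * exp(2*alpha*t): it grows
    exponentially with iteration, which makes each node's own message
    dominate the T_Z denominators, shrinks the effective updates, and
    gives the scheme its guaranteed convergence.
    """
    n = M.shape[0]
    off = M.copy()
    np.fill_diagonal(off, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan rows at n=1
        sd = np.nanstd(off, axis=1, ddof=1)
    sd = np.nan_to_num(sd, nan=0.0)
    np.fill_diagonal(M, sd * n * np.exp(2.0 * alpha * t))


def message_passing_step(state: MessagePassingState) -> MessagePassingState:
    """One refinement iteration: availability, responsibility, blended update.

    W moves a fraction alpha toward (A + R) / 2; P and C then move the
    same fraction toward pairwise T_Z similarities of the UPDATED W's rows
    and columns, with their diagonals re-set by the inflation schedule of
    :func:`_inflate_diagonal` before blending.
    """
    W, P, C = state.triple.W, state.triple.P, state.triple.C
    alpha = state.alpha

    A = _tanimoto_matrix(W, C)       # TF i's targets vs gene j's co-expression
    R = _tanimoto_matrix(P, W)       # TF i's partners vs gene j's regulators
    W_new = (1.0 - alpha) * W + alpha * (0.5 * A + 0.5 * R)

    P_hat = _tanimoto_matrix(W_new, W_new.T)   # TF-TF co-targeting similarity
    _inflate_diagonal(P_hat, alpha, state.t)
    C_hat = _tanimoto_matrix(W_new.T, W_new)   # gene-gene co-regulation similarity
    _inflate_diagonal(C_hat, alpha, state.t)
    P_new = (1.0 - alpha) * P + alpha * P_hat
    C_new = (1.0 - alpha) * C + alpha * C_hat

    history = state.hamming_history + [hamming_distance(W, W_new)]
    return MessagePassingState(
        triple=NetworkTriple(W_new, P_new, C_new),
        alpha=alpha,
        tol=state.tol,
        t=state.t + 1,
        hamming_history=history,
        A=A,
        R=R,
    )


def refine(
    W0: np.ndarray,
    P0: np.ndarray,
    C0: np.ndarray,
    alpha: float = 0.1,
    tol: float = 0.001,
    max_iter: int = 100,
) -> tuple[np.ndarray, dict]:
    """Normalize the three unrefined networks and iterate to convergence.

    Returns the refined W together with an info dict (iterations, final
    Hamming distance, full history, convergence flag).  Non-convergence at
    ``max_iter`` is reported, not fatal.
    """
    state = MessagePassingState(
        triple=NetworkTriple(
            normalize_network(W0), normalize_network(P0), normalize_network(C0)
        ),
        alpha=alpha,
        tol=tol,
    )
    converged = False
    for _ in range(max_iter):
        state = message_passing_step(state)
        if state.hamming_history[-1] < tol:
            converged = True
            break
    info = {
        "iterations": state.t,
        "hamming": state.hamming_history[-1] if state.hamming_history else 0.0,
        "hamming_history": list(state.hamming_history),
        "converged": converged,
        "alpha": alpha,
        "tol": tol,
        "max_iter": max_iter,
    }
    if not converged:
        warnings.warn(
            f"message passing did not reach tol={tol} within {max_iter} "
            f"iterations (last Hamming distance "
            f"{info['hamming']:.6g}); returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return state.triple.W, info


class ScorpionGRN(BaseEstimator):
    """Single-sample gene regulatory network inference.

    Runs the full pipeline on one expression sample: filter genes expressed
    in at least ``min_cell_fraction`` of cells and covered by the motif
    prior, coarse-grain cells into super-cells, estimate Pearson
    co-expression on the pooled profiles, then refine the motif prior by
    message passing against the PPI and co-expression evidence.

    Parameters
    ----------
    alpha : float, default 0.1
        Update fraction per iteration.
    tol : float, default 0.001
        Convergence threshold on the mean absolute change of W.
    max_iter : int, default 100
        Iteration cap; hitting it raises a warning, not an error.
    gamma : float, default 10.0
        Target cells per super-cell (1 disables coarse-graining).
    n_components, n_neighbors : int
        Embedding dimensionality and kNN graph degree for the partition.
    min_cell_fraction : float, default 0.05
        Expressed-gene filter: a gene is kept if nonzero in at least this
        fraction of cells.
    random_state : int, default 42
        Seed for the randomized embedding solver.

    Attributes
    ----------
    network_ : pandas.DataFrame
        Refined TF x gene weights in z-score units.
    tf_ids_, gene_ids_ : ndarray
        Aligned label universes.
    n_iter_ : int
        Iterations run.
    converged_ : bool
    hamming_history_ : list of float
    partition_ : SuperCellPartition
    """

    def __init__(
        self,
        alpha: float = 0.1,
        tol: float = 0.001,
        max_iter: int = 100,
        gamma: float = 10.0,
        n_components: int = 25,
        n_neighbors: int = 5,
        min_cell_fraction: float = 0.05,
        keep_uncovered_genes: bool = False,
        random_state: int = 42,
    ):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.gamma = gamma
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.min_cell_fraction = min_cell_fraction
        self.keep_uncovered_genes = keep_uncovered_genes
        self.random_state = random_state

    def fit(
        self,
        X: ExpressionMatrix,
        y=None,
        regulatory_prior: PriorEdgeList | None = None,
        ppi_prior: PriorEdgeList | None = None,
    ):
        """Fit on one sample.

        ``X`` is a genes x cells :class:`ExpressionMatrix`; the priors are
        passed as fit parameters because they are data, not
        hyperparameters.
        """
        if regulatory_prior is None:
            raise ValueError("regulatory_prior is required")
        if ppi_prior is None:
            ppi_prior = PriorEdgeList(
                pd.DataFrame(columns=["source", "target", "score"]),
                "cooperativity",
            )
        expr, w0, p0 = align_universe(
            X,
            regulatory_prior,
            ppi_prior,
            min_cell_fraction=self.min_cell_fraction,
            keep_uncovered_genes=self.keep_uncovered_genes,
        )
        partition = compute_partition(
            expr,
            gamma=self.gamma,
            n_components=self.n_components,
            n_neighbors=self.n_neighbors,
            seed=self.random_state,
        )
        coarse = aggregate(expr, partition)
        c0 = build_coexpression(coarse)
        weights, info = refine(
            w0.to_numpy(),
            p0.to_numpy(),
            c0,
            alpha=self.alpha,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.tf_ids_ = w0.index.to_numpy(dtype=object)
        self.gene_ids_ = w0.columns.to_numpy(dtype=object)
        self.network_ = pd.DataFrame(
            weights, index=self.tf_ids_, columns=self.gene_ids_
        )
        self.n_iter_ = info["iterations"]
        self.converged_ = info["converged"]
        self.hamming_history_ = info["hamming_history"]
        self.partition_ = partition
        self.refine_info_ = info
        return self

    def to_network(self, **extra_metadata) -> Network:
        """Export the fitted network with its provenance metadata."""
        if not hasattr(self, "network_"):
            raise ValueError("estimator is not fitted")
        metadata = {
            "alpha": self.alpha,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "gamma": self.gamma,
            "n_components": self.n_components,
            "n_neighbors": self.n_neighbors,
            "min_cell_fraction": self.min_cell_fraction,
            "seed": self.random_state,
            "iterations": self.n_iter_,
            "converged": self.converged_,
            "final_hamming": self.hamming_history_[-1]
            if self.hamming_history_
            else 0.0,
        }
        metadata.update(extra_metadata)
        return Network(
            self.network_.to_numpy(), self.tf_ids_, self.gene_ids_, metadata
        )


def build_network(
    expr: ExpressionMatrix,
    regulatory_prior: PriorEdgeList,
    ppi_prior: PriorEdgeList | None = None,
    alpha: float = 0.1,
    tol: float = 0.001,
    max_iter: int = 100,
    gamma: float = 10.0,
    n_components: int = 25,
    n_neighbors: int = 5,
    min_cell_fraction: float = 0.05,
    seed: int = 42,
) -> Network:
    """Functional wrapper over :class:`ScorpionGRN` returning a :class:`Network`."""
    est = ScorpionGRN(
        alpha=alpha,
        tol=tol,
        max_iter=max_iter,
        gamma=gamma,
        n_components=n_components,
        n_neighbors=n_neighbors,
        min_cell_fraction=min_cell_fraction,
        random_state=seed,
    )
    est.fit(expr, regulatory_prior=regulatory_prior, ppi_prior=ppi_prior)
    return est.to_network()
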