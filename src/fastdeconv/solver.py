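"""Regularized NMF solver for reference-free spot deconvolution.

The model factorizes the genes-by-spots expression matrix as
``X ~ W H^T`` with non-negative ``W`` (genes x cell types, the per-type
transcriptional signatures) and ``H`` (spots x cell types, the per-spot
abundances), minimizing

    ||X - W H^T||_F^2 + lambda1 Tr(H^T L H) + lambda2 ||H J - J_M||_F^2

subject to ``W, H >= 0``. The Laplacian term smooths abundances over the
spot neighbourhood graph (spatial coordinates fused with histology); the
second penalty pulls each spot's abundance row sum towards one, since the
rows are interpreted as cell-type proportions. ``J`` (R x M) and ``J_M``
(M x M) are all-ones matrices; the penalty is evaluated through the
identity ``||H J - J_M||_F^2 = M * sum_j (rowsum_j(H) - 1)^2`` and the
all-ones matrices are never materialized.

Optimization is by multiplicative updates derived from the KKT conditions,
splitting ``L = D - G`` so every numerator and denominator stays
non-negative; each update leaves the objective non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import SpatialGraph, laplacian_quadratic

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SolverConfig",
    "FactorModel",
    "objective",
    "update_W",
    "update_H",
    "fit",
    "proportions",
    "nndsvd_init",
]


@dataclass
class ExpressionMatrix:
    """Non-negative genes-by-spots expression matrix with identifiers."""

    X: np.ndarray
    gene_ids: np.ndarray
    spot_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids)
        self.spot_ids = np.asarray(self.spot_ids)
        n, m = self.X.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.spot_ids) != m:
            raise ValueError(f"{len(self.spot_ids)} spot ids for {m} columns")
        if not np.isfinite(self.X).all():
            raise ValueError("expression matrix contains non-finite entries")
        if (self.X < 0).any():
            i, j = np.argwhere(self.X < 0)[0]
            raise ValueError(
                f"negative entry at gene {self.gene_ids[i]!r}, "
                f"spot {self.spot_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_spots(self) -> int:
        return self.X.shape[1]

    def drop_empty(self) -> "ExpressionMatrix":
        """Drop all-zero rows and columns, logging how many were removed."""
        row_keep = self.X.sum(axis=1) > 0
        col_keep = self.X.sum(axis=0) > 0
        n_rows = int((~row_keep).sum())
        n_cols = int((~col_keep).sum())
        if n_rows or n_cols:
            logger.warning(
                "dropping %d all-zero gene row(s) and %d all-zero spot "
                "column(s)",
                n_rows,
                n_cols,
            )
            return ExpressionMatrix(
                self.X[np.ix_(row_keep, col_keep)],
                self.gene_ids[row_keep],
                self.spot_ids[col_keep],
            )
        return self

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.X[index], self.gene_ids[index], self.spot_ids)


@dataclass
class SolverConfig:
    """Hyperparameters of the regularized NMF fit.

    ``R`` is the factorization rank (number of cell types to deconvolve).
    ``lambda1`` weights the graph-Laplacian smoothness term and ``lambda2``
    the sum-to-one penalty on abundance rows; both default to 1, a value
    that balances reconstruction accuracy against the local similarity
    structure (small values such as 0.01 make the fit behave like standard
    NMF, values above ~10 make the result insensitive to the exact weight).
    """

    R: int
    lambda1: float = 1.0
    lambda2: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-5
    seed: int = 0
    init: str = "random"
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be a positive integer")
        for name in ("lambda1", "lambda2", "tol", "eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.init not in ("random", "svd"):
            raise ValueError(f"init must be 'random' or 'svd', got {self.init!r}")


@dataclass
class FactorModel:
    """Result of a fit: factors, objective trajectory, convergence state."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    config: SolverConfig | None = field(default=None, repr=False)


def _as_array(X) -> np.ndarray:
    return X.X if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)


def sum_to_one_penalty(H: np.ndarray) -> float:
    """``||H J - J_M||_F^2`` via the closed form ``M * sum_j (rowsum_j - 1)^2``."""
    m = H.shape[0]
    return float(m * np.sum((H.sum(axis=1) - 1.0) ** 2))


def objective(
    X,
    W: np.ndarray,
    H: np.ndarray,
    graph: SpatialGraph | None = None,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
) -> float:
    """Value of the regularized factorization objective."""
    X = _as_array(X)
    n, m = X.shape
    if W.shape[0] != n or H.shape[0] != m or W.shape[1] != H.shape[1]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, W {W.shape}, H {H.shape}"
        )
    value = float(np.linalg.norm(X - W @ H.T, "fro") ** 2)
    if lambda1 > 0:
        if graph is None:
            raise ValueError("lambda1 > 0 requires a graph")
        value += lambda1 * laplacian_quadratic(H, graph)
    if lambda2 > 0:
        value += lambda2 * sum_to_one_penalty(H)
    return value


def update_W(X, W: np.ndarray, H: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """One multiplicative step on the signatures: W <- W * (XH) / (W H^T H)."""
    X = _as_array(X)
    return W * (X @ H) / (W @ (H.T @ H) + eps)


def update_H(
    X,
    W: np.ndarray,
    H: np.ndarray,
    graph: SpatialGraph | None = None,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    eps: float = 1e-12,
) -> np.ndarray:
    """One multiplicative step on the abundances.

    The Laplacian is split as ``L = D - G`` so the attractive part ``G H``
    lands in the numerator and the degree part ``D H`` in the denominator;
    the sum-to-one penalty contributes ``lambda2 * M`` (its target) to the
    numerator and ``lambda2 * M * rowsum(H)`` to the denominator.
    """
    X = _as_array(X)
    m = H.shape[0]
    num = X.T @ W
    den = H @ (W.T @ W)
    if lambda1 > 0:
        if graph is None:
            raise ValueError("lambda1 > 0 requires a graph")
        num = num + lambda1 * (graph.G @ H)
        den = den + lambda1 * (graph.D @ H)
    if lambda2 > 0:
        num = num + lambda2 * m
        den = den + lambda2 * m * H.sum(axis=1, keepdims=True)
    return H * num / (den + eps)


def nndsvd_init(X: np.ndarray, R: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization.

    Splits each leading singular vector pair into its positive and negative
    parts and keeps the branch with the larger norm product; exact zeros are
    replaced by ``mean(X) / 100`` so multiplicative updates can move them.
    """
    n, m = X.shape
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((n, R))
    Ht = np.zeros((R, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    Ht[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for r in range(1, R):
        u, v = U[:, r], Vt[r]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        pos = np.linalg.norm(up) * np.linalg.norm(vp)
        neg = np.linalg.norm(un) * np.linalg.norm(vn)
        if pos >= neg:
            sigma = pos
            uu, vv = up, vp
        else:
            sigma = neg
            uu, vv = un, vn
        if sigma > 0:
            scale = np.sqrt(S[r] * sigma)
            W[:, r] = scale * uu / np.linalg.norm(uu)
            Ht[r] = scale * vv / np.linalg.norm(vv)
    floor = X.mean() / 100.0
    W[W == 0] = floor
    Ht[Ht == 0] = floor
    return W, Ht.T


def fit(X, graph: SpatialGraph | None, config: SolverConfig) -> FactorModel:
    """Alternate multiplicative updates on W and H until convergence.

    Stops when the relative objective change drops below ``config.tol`` or
    after ``config.max_iter`` iterations. The same seed, configuration and
    inputs reproduce the result bit for bit.
    """
    Xa = _as_array(X)
    n, m = Xa.shape
    if config.R > min(n, m):
        raise ValueError(
            f"R = {config.R} exceeds min(n_genes, n_spots) = {min(n, m)}"
        )
    if config.lambda1 > 0 and graph is None:
        raise ValueError("lambda1 > 0 requires a spot graph")
    if graph is not None and graph.n_spots != m:
        raise ValueError(
            f"graph has {graph.n_spots} spots but X has {m} columns"
        )

    rng = np.random.default_rng(config.seed)
    if config.init == "random":
        W = rng.uniform(size=(n, config.R))
        H = rng.uniform(size=(m, config.R))
    else:
        W, H = nndsvd_init(Xa, config.R)

    lam1, lam2, eps = config.lambda1, config.lambda2, config.eps
    trace = [objective(Xa, W, H, graph, lam1, lam2)]
    converged = False
    n_iter = 0
    for it in range(1, config.max_iter + 1):
        W = update_W(Xa, W, H, eps=eps)
        H = update_H(Xa, W, H, graph, lam1, lam2, eps=eps)
        obj = objective(Xa, W, H, graph, lam1, lam2)
        if not np.isfinite(obj):
            raise RuntimeError(f"objective became non-finite at iteration {it}")
        prev = trace[-1]
        trace.append(obj)
        n_iter = it
        if abs(prev - obj) <= config.tol * max(abs(prev), 1e-300):
            converged = True
            break
    return FactorModel(
        W=W,
        H=H,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        config=config,
    )


def proportions(model_or_H) -> np.ndarray:
    """Row-normalize abundances into exact per-spot proportions.

    The sum-to-one penalty only encourages unit row sums; reported
    proportions are each row of ``H`` divided by its sum. All-zero rows
    become the uniform vector ``1/R`` with a logged warning.
    """
    H = model_or_H.H if isinstance(model_or_H, FactorModel) else np.asarray(model_or_H)
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    sums = H.sum(axis=1)
    zero = sums == 0
    if zero.any():
        logger.warning(
            "%d all-zero abundance row(s) replaced by the uniform vector",
            int(zero.sum()),
        )
    out = np.empty_like(H)
    out[~zero] = H[~zero] / sums[~zero, None]
    out[zero] = 1.0 / H.shape[1]
    return out
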