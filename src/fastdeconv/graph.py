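"""Spot adjacency graph fusing spatial coordinates with histology intensity.

The neighbourhood graph drives the Laplacian regularization of the solver:
two spots are connected when they are mutually close in a fused squared
distance ``(x_i-x_j)^2 + (y_i-y_j)^2 + beta (z_i-z_j)^2``, where ``z`` is the
median grey-scale intensity of a small window around each spot on the
histology image and ``beta`` balances the two sources of information. Each
row of the similarity matrix is sparsified to its ``k`` nearest neighbours
(``k=5`` by default) and the graph Laplacian ``L = D - G`` is formed from the
symmetrized result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import SpotGeometry

__all__ = [
    "SpatialGraph",
    "spot_intensity",
    "compute_beta",
    "squared_distance_matrix",
    "similarity_and_sparsify",
    "laplacian_quadratic",
    "build_graph",
]


@dataclass
class SpatialGraph:
    """k-nearest-neighbour spot graph with its Laplacian.

    Attributes
    ----------
    G
        ``M x M`` sparse symmetric non-negative similarity matrix with a
        zero diagonal.
    D
        Diagonal degree matrix, ``D_jj = sum_l G_jl``.
    L
        Graph Laplacian ``L = D - G`` (positive semi-definite; row sums 0).
    k
        Neighbours kept per row before symmetrization.
    beta
        Histology scale used in the fused distance (0 when no usable
        intensity was available).
    """

    G: sp.csr_matrix
    D: sp.csr_matrix
    L: sp.csr_matrix
    k: int
    beta: float

    @property
    def n_spots(self) -> int:
        return self.G.shape[0]


def spot_intensity(
    image: np.ndarray,
    centers: np.ndarray,
    window: int = 5,
) -> np.ndarray:
    """Median grey-scale intensity in a pixel window around each spot.

    Parameters
    ----------
    image
        2-D grey-scale intensity grid. Integer images are rescaled to
        ``[0, 1]`` by the maximum representable value of their dtype;
        floating-point images are assumed to be on that scale already.
    centers
        ``(M, 2)`` integer pixel coordinates ``(row, col)`` of spot centres.
    window
        Odd window side length; the window is clipped at image borders.

    Returns
    -------
    ndarray
        Length-``M`` vector of median intensities in ``[0, 1]``.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.isfinite(np.asarray(image, dtype=float)).all():
        raise ValueError("image contains non-finite values")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    centers = np.asarray(centers)
    if centers.ndim != 2 or centers.shape[1] != 2:
        raise ValueError("centers must be an (M, 2) array of (row, col)")

    if np.issubdtype(image.dtype, np.integer):
        scale = float(np.iinfo(image.dtype).max)
    else:
        scale = 1.0

    nrow, ncol = image.shape
    half = window // 2
    z = np.empty(len(centers), dtype=float)
    for i, (r, c) in enumerate(centers):
        r, c = int(r), int(c)
        if not (0 <= r < nrow and 0 <= c < ncol):
            raise ValueError(
                f"spot {i}: center ({r}, {c}) lies outside the "
                f"{nrow}x{ncol} image"
            )
        patch = image[
            max(0, r - half) : min(nrow, r + half + 1),
            max(0, c - half) : min(ncol, c + half + 1),
        ]
        z[i] = np.median(np.asarray(patch, dtype=float))
    return z / scale


def lattice_intensity(
    geometry: SpotGeometry,
    z_raw: np.ndarray,
    window: int = 5,
) -> np.ndarray:
    """Median intensity over the window x window block of neighbouring spots.

    Alternative reading of the windowing step in which the median is taken
    over the spot lattice rather than image pixels: for each spot the
    ``window**2`` spots nearest in (x, y) are located and the median of their
    raw intensities is returned.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    z_raw = np.asarray(z_raw, dtype=float)
    if z_raw.shape != (geometry.n_spots,):
        raise ValueError("z_raw length must match the number of spots")
    d2 = squared_distance_matrix(geometry, beta=0.0)
    n_neigh = min(window * window, geometry.n_spots)
    order = np.argsort(d2, axis=1, kind="stable")[:, :n_neigh]
    return np.median(z_raw[order], axis=1)


def compute_beta(geometry: SpotGeometry) -> float:
    """Recommended histology scale for the fused squared distance.

    ``beta = (max dx^2 + max dy^2) / max dz^2`` computed from the coordinate
    and intensity ranges, so that the histology term and the spatial term
    enter the distance on a comparable scale. When ``z`` is absent or
    constant the histology term carries no information and ``beta = 0``.
    """
    if geometry.n_spots < 2:
        raise ValueError("need at least 2 spots to compute beta")
    if geometry.z is None:
        return 0.0
    dz2 = float(np.ptp(geometry.z)) ** 2
    if dz2 == 0.0:
        return 0.0
    dx2 = float(np.ptp(geometry.x)) ** 2
    dy2 = float(np.ptp(geometry.y)) ** 2
    return (dx2 + dy2) / dz2


def squared_distance_matrix(geometry: SpotGeometry, beta: float) -> np.ndarray:
    """Pairwise squared distances fusing coordinates and intensity.

    Entry ``(i, j)`` is ``(x_i-x_j)^2 + (y_i-y_j)^2 + beta (z_i-z_j)^2``.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x, y = geometry.x, geometry.y
    d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
    if beta > 0 and geometry.z is not None:
        z = geometry.z
        d2 = d2 + beta * (z[:, None] - z[None, :]) ** 2
    np.fill_diagonal(d2, 0.0)
    return d2


def similarity_and_sparsify(
    sq_dist: np.ndarray,
    k: int = 5,
    mode: str = "binary",
    mutual: bool = False,
    beta: float = 0.0,
) -> SpatialGraph:
    """Convert squared distances to a sparse symmetric similarity graph.

    Each row keeps its ``k`` nearest off-diagonal neighbours (distance ties
    broken by lower spot index). In ``binary`` mode kept edges get weight 1;
    in ``heat`` mode they get ``exp(-d^2 / sigma^2)`` with ``sigma^2`` the
    median of all kept squared distances. The row-sparsified matrix is
    symmetrized by the elementwise maximum (or minimum, i.e. mutual-kNN,
    when ``mutual`` is set), after which ``D`` and ``L = D - G`` are formed.
    """
    sq_dist = np.asarray(sq_dist, dtype=float)
    m = sq_dist.shape[0]
    if sq_dist.shape != (m, m):
        raise ValueError("sq_dist must be square")
    if not np.allclose(sq_dist, sq_dist.T):
        raise ValueError("sq_dist must be symmetric")
    if not (1 <= k <= m - 1):
        raise ValueError(f"k must satisfy 1 <= k <= M-1 = {m - 1}, got {k}")
    if mode not in ("binary", "heat"):
        raise ValueError(f"mode must be 'binary' or 'heat', got {mode!r}")

    # k smallest off-diagonal entries per row; stable sort fixes ties at the
    # lower index
    masked = sq_dist.copy()
    np.fill_diagonal(masked, np.inf)
    order = np.argsort(masked, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(m), k)
    cols = order.ravel()
    kept_d2 = masked[rows, cols]

    if mode == "binary":
        weights = np.ones_like(kept_d2)
    else:
        sigma2 = float(np.median(kept_d2))
        if sigma2 <= 0:
            weights = np.ones_like(kept_d2)
        else:
            weights = np.exp(-kept_d2 / sigma2)

    g_row = sp.csr_matrix((weights, (rows, cols)), shape=(m, m))
    G = g_row.minimum(g_row.T) if mutual else g_row.maximum(g_row.T)
    G.eliminate_zeros()
    deg = np.asarray(G.sum(axis=1)).ravel()
    D = sp.diags(deg, format="csr")
    L = (D - G).tocsr()
    return SpatialGraph(G=G.tocsr(), D=D, L=L, k=k, beta=float(beta))


def laplacian_quadratic(H: np.ndarray, graph: SpatialGraph) -> float:
    """Smoothness penalty ``Tr(H^T L H)`` of spot loadings on the graph.

    Equals ``1/2 sum_{j,l} G_jl ||h_j - h_l||^2`` for a symmetric graph, so
    it is non-negative and vanishes iff connected spots share identical rows.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != graph.n_spots:
        raise ValueError(
            f"H must be (M, R) with M = {graph.n_spots}, got {H.shape}"
        )
    return float(np.sum(H * (graph.L @ H)))


def build_graph(
    geometry: SpotGeometry,
    k: int = 5,
    mode: str = "binary",
    beta: float | None = None,
    mutual: bool = False,
) -> SpatialGraph:
    """Convenience: fused distances -> sparsified similarity -> Laplacian.

    ``beta=None`` uses the recommended range-ratio value from
    :func:`compute_beta`.
    """
    if beta is None:
        beta = compute_beta(geometry)
    d2 = squared_distance_matrix(geometry, beta)
    return similarity_and_sparsify(d2, k=k, mode=mode, mutual=mutual, beta=beta)
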