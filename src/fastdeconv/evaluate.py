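"""Scoring of deconvolution output against known ground truth.

Inferred factors are first annotated by correlating each estimated
signature column with the reference signatures and assigning the best-
correlated reference type (a data-driven rule; two factors may map to the
same type, in which case their proportion columns are summed before
scoring). Accuracy is then summarized by the mean Pearson correlation of
matched proportion columns across spots, the RMSE between row-normalized
proportion matrices, and optionally the adjusted Rand index of a K-means
clustering of the abundance rows against region labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "EvaluationReport",
    "annotate_factors",
    "mean_pearson",
    "rmse",
    "cluster_ari",
    "evaluate_model",
]


@dataclass
class EvaluationReport:
    factor_assignment: list[int]
    mean_pearson: float
    rmse: float
    per_type_pearson: list[float]
    ari: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def annotate_factors(W_est: np.ndarray, W_ref: np.ndarray) -> np.ndarray:
    """Assign each inferred factor the reference type it correlates best with.

    Returns an integer array of length R mapping factor -> reference column.
    Many-to-one assignments are allowed. Correlations involving a constant
    column are treated as -inf (with a warning); exact ties break towards
    the lower reference index.
    """
    W_est = np.asarray(W_est, dtype=float)
    W_ref = np.asarray(W_ref, dtype=float)
    if W_est.shape[0] != W_ref.shape[0]:
        raise ValueError(
            f"gene dimension mismatch: {W_est.shape[0]} vs {W_ref.shape[0]}"
        )
    R, K = W_est.shape[1], W_ref.shape[1]
    corr = np.full((R, K), -np.inf)
    for r in range(R):
        for k in range(K):
            if W_est[:, r].std() == 0 or W_ref[:, k].std() == 0:
                warnings.warn(
                    f"zero-variance column in correlation of factor {r} "
                    f"with reference {k}; treated as -inf",
                    stacklevel=2,
                )
            else:
                corr[r, k] = _pearson(W_est[:, r], W_ref[:, k])
    return corr.argmax(axis=1)


def _match_columns(
    H_est: np.ndarray, assignment: np.ndarray, n_types: int
) -> np.ndarray:
    """Sum estimated columns mapping to the same reference type; types that
    receive no factor get an all-zero column."""
    M = H_est.shape[0]
    matched = np.zeros((M, n_types))
    for r, k in enumerate(assignment):
        matched[:, k] += H_est[:, r]
    return matched


def mean_pearson(
    H_est: np.ndarray,
    H_true: np.ndarray,
    assignment: np.ndarray,
) -> float:
    """Unweighted mean over reference types of the Pearson correlation
    between matched estimated and true proportion columns across spots.

    A constant column yields an undefined correlation; it is recorded as 0
    with a warning and still enters the mean.
    """
    return float(np.mean(per_type_pearson(H_est, H_true, assignment)))


def per_type_pearson(
    H_est: np.ndarray,
    H_true: np.ndarray,
    assignment: np.ndarray,
) -> np.ndarray:
    H_est = np.asarray(H_est, dtype=float)
    H_true = np.asarray(H_true, dtype=float)
    if H_est.shape[0] != H_true.shape[0]:
        raise ValueError("H_est and H_true must have the same number of spots")
    K = H_true.shape[1]
    matched = _match_columns(H_est, np.asarray(assignment), K)
    out = np.empty(K)
    for k in range(K):
        if matched[:, k].std() == 0 or H_true[:, k].std() == 0:
            warnings.warn(
                f"constant proportion column for type {k}; correlation "
                "recorded as 0",
                stacklevel=2,
            )
            out[k] = 0.0
        else:
            out[k] = _pearson(matched[:, k], H_true[:, k])
    return out


def _row_normalize(H: np.ndarray) -> np.ndarray:
    sums = H.sum(axis=1, keepdims=True)
    safe = np.where(sums == 0, 1.0, sums)
    return H / safe


def rmse(
    H_est: np.ndarray,
    H_true: np.ndarray,
    assignment: np.ndarray,
    normalize: bool = True,
) -> float:
    """Root-mean-square difference between matched proportion matrices.

    Both matrices are row-normalized first (``normalize=False`` compares
    raw values); the mean runs over all (spot, type) matched entries.
    """
    H_est = np.asarray(H_est, dtype=float)
    H_true = np.asarray(H_true, dtype=float)
    if H_est.shape[0] != H_true.shape[0]:
        raise ValueError("H_est and H_true must have the same number of spots")
    if normalize:
        H_est = _row_normalize(H_est)
        H_true = _row_normalize(H_true)
    matched = _match_columns(H_est, np.asarray(assignment), H_true.shape[1])
    return float(np.sqrt(np.mean((matched - H_true) ** 2)))


def cluster_ari(
    H: np.ndarray,
    true_labels,
    k: int,
    seed: int = 0,
) -> float:
    """Adjusted Rand index of K-means on abundance rows vs. given labels.

    K-means runs with 10 restarts at a fixed seed; the ARI is invariant to
    how either partition names its groups.
    """
    H = np.asarray(H, dtype=float)
    true_labels = np.asarray(true_labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > H.shape[0]:
        raise ValueError(f"k = {k} exceeds the number of spots {H.shape[0]}")
    if len(true_labels) != H.shape[0]:
        raise ValueError("true_labels length must match the number of spots")
    pred = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(H)
    return float(adjusted_rand_score(true_labels, pred))


def evaluate_model(
    W_est: np.ndarray,
    H_est: np.ndarray,
    W_ref: np.ndarray,
    H_true: np.ndarray,
    cluster_labels=None,
    cluster_k: int | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Full report: annotation, mean Pearson, RMSE and optional ARI."""
    assignment = annotate_factors(W_est, W_ref)
    per_type = per_type_pearson(H_est, H_true, assignment)
    ari = None
    if cluster_labels is not None:
        k = cluster_k if cluster_k is not None else len(np.unique(cluster_labels))
        ari = cluster_ari(H_est, cluster_labels, k=k, seed=seed)
    return EvaluationReport(
        factor_assignment=[int(a) for a in assignment],
        mean_pearson=float(per_type.mean()),
        rmse=rmse(H_est, H_true, assignment),
        per_type_pearson=[float(v) for v in per_type],
        ari=ari,
    )
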