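"""Helpers for choosing the factorization rank (number of cell types).

The rank is the most consequential hyperparameter of the deconvolution; it
fixes how many transcriptional programs the factorization can express. This
module scans candidate ranks with multiple seeded restarts and summarizes
each rank by its best reconstruction error, explained variance, and a
restart-stability score, then proposes the elbow of the error curve. These
criteria are this package's own; other selection heuristics (consensus
clustering, cross-validation) are equally legitimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .graph import SpatialGraph
from .solver import SolverConfig, _as_array, fit

__all__ = ["RankScanResult", "scan_ranks", "suggest_rank"]


@dataclass
class RankScanResult:
    ranks: np.ndarray
    recon_error: np.ndarray  # best final ||X - W H^T||_F per rank
    explained_var: np.ndarray  # 1 - err^2 / ||X||_F^2
    stability: np.ndarray  # mean pairwise factor agreement across restarts


def _factor_agreement(W_a: np.ndarray, W_b: np.ndarray) -> float:
    """Mean |Pearson r| between optimally matched columns of two W's."""
    R = W_a.shape[1]
    corr = np.zeros((R, R))
    for i in range(R):
        for j in range(R):
            sa, sb = W_a[:, i].std(), W_b[:, j].std()
            if sa > 0 and sb > 0:
                corr[i, j] = abs(np.corrcoef(W_a[:, i], W_b[:, j])[0, 1])
    row, col = linear_sum_assignment(-corr)
    return float(corr[row, col].mean())


def scan_ranks(
    X,
    graph: SpatialGraph | None,
    ranks: list[int],
    restarts: int,
    config: SolverConfig,
) -> RankScanResult:
    """Fit ``restarts`` seeded models per candidate rank and summarize.

    Restart seeds are spawned deterministically from ``config.seed``, so the
    scan is reproducible. With a single restart the stability score is 1 by
    convention (a model trivially agrees with itself).
    """
    if len(ranks) == 0:
        raise ValueError("empty rank list")
    Xa = _as_array(X)
    limit = min(Xa.shape)
    if max(ranks) > limit:
        raise ValueError(f"rank {max(ranks)} exceeds min(N, M) = {limit}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    x_norm2 = float(np.linalg.norm(Xa, "fro") ** 2)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(ranks) * restarts
    ) % (2**31)
    errors, evars, stabs = [], [], []
    for idx, R in enumerate(ranks):
        models = []
        for rep in range(restarts):
            cfg = SolverConfig(
                R=R,
                lambda1=config.lambda1,
                lambda2=config.lambda2,
                max_iter=config.max_iter,
                tol=config.tol,
                seed=int(seeds[idx * restarts + rep]),
                init=config.init,
                eps=config.eps,
            )
            models.append(fit(Xa, graph, cfg))
        errs = [
            float(np.linalg.norm(Xa - m.W @ m.H.T, "fro")) for m in models
        ]
        best = min(errs)
        errors.append(best)
        evars.append(1.0 - best**2 / x_norm2)
        if restarts == 1:
            stabs.append(1.0)
        else:
            pair_scores = [
                _factor_agreement(models[a].W, models[b].W)
                for a in range(restarts)
                for b in range(a + 1, restarts)
            ]
            stabs.append(float(np.mean(pair_scores)))
    return RankScanResult(
        ranks=np.asarray(ranks),
        recon_error=np.asarray(errors),
        explained_var=np.asarray(evars),
        stability=np.asarray(stabs),
    )


def suggest_rank(result: RankScanResult) -> int:
    """Elbow of the reconstruction-error curve.

    Ranks and errors are rescaled to the unit square (making the choice
    invariant to affine rescaling of either axis), and the interior point
    with the maximum perpendicular distance to the chord joining the first
    and last points is returned; ties break towards the smaller rank.
    """
    ranks = np.asarray(result.ranks, dtype=float)
    errs = np.asarray(result.recon_error, dtype=float)
    if len(ranks) < 3:
        raise ValueError("need at least 3 candidate ranks to find an elbow")
    x = (ranks - ranks[0]) / (ranks[-1] - ranks[0])
    span = errs.max() - errs.min()
    y = (errs - errs.min()) / span if span > 0 else np.zeros_like(errs)
    # distance from (x, y) to the chord through the first and last points
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    interior = slice(1, len(ranks) - 1)
    best = int(np.argmax(dist[interior])) + 1
    return int(result.ranks[best])
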