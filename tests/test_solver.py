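import numpy as np
import pytest

from fastdeconv import (
    ExpressionMatrix,
    SolverConfig,
    fit,
    objective,
    proportions,
    update_H,
    update_W,
)
from fastdeconv.solver import nndsvd_init, sum_to_one_penalty

from _plain_nmf import plain_nmf_run
from conftest import random_graph


def explicit_objective(X, W, H, L, lam1, lam2):
    """Brute-force evaluation materializing the all-ones matrices."""
    m, r = H.shape
    J = np.ones((r, m))
    J_M = np.ones((m, m))
    val = np.linalg.norm(X - W @ H.T, "fro") ** 2
    val += lam1 * np.trace(H.T @ L @ H)
    val += lam2 * np.linalg.norm(H @ J - J_M, "fro") ** 2
    return val


class TestObjective:
    def test_zero_residual_unpenalized(self, planted_factorization):
        W, H, X = planted_factorization
        assert objective(X, W, H) == pytest.approx(0.0, abs=1e-18)

    def test_row_stochastic_H_kills_sum_to_one_term(self, rng):
        H = rng.dirichlet(np.ones(3), size=8)
        W = rng.uniform(size=(6, 3))
        X = W @ H.T
        assert objective(X, W, H, lambda2=100.0) == pytest.approx(0.0, abs=1e-18)

    def test_matches_explicit_all_ones_evaluation(self, rng):
        g = random_graph(5, seed=11, k=2)
        L = g.L.toarray()
        for _ in range(5):
            X = rng.uniform(size=(6, 5))
            W = rng.uniform(size=(6, 2))
            H = rng.uniform(size=(5, 2))
            got = objective(X, W, H, g, lambda1=0.7, lambda2=1.3)
            want = explicit_objective(X, W, H, L, 0.7, 1.3)
            assert got == pytest.approx(want, rel=1e-12)

    def test_closed_form_sum_to_one_identity(self, rng):
        for _ in range(20):
            m, r = rng.integers(2, 15), rng.integers(1, 5)
            H = rng.uniform(size=(m, r))
            explicit = np.linalg.norm(
                H @ np.ones((r, m)) - np.ones((m, m)), "fro"
            ) ** 2
            assert sum_to_one_penalty(H) == pytest.approx(explicit, rel=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            objective(rng.uniform(size=(4, 3)), rng.uniform(size=(4, 2)),
                      rng.uniform(size=(5, 2)))


class TestUpdates:
    def test_W_fixed_point_at_exact_factorization(self, planted_factorization):
        W, H, X = planted_factorization
        W1 = update_W(X, W, H)
        assert np.allclose(W1, W, atol=1e-9)

    def test_updates_preserve_non_negativity(self, rng):
        g = random_graph(6, seed=3, k=2)
        for _ in range(1000):
            X = rng.uniform(size=(8, 6))
            W = rng.uniform(size=(8, 2))
            H = rng.uniform(size=(6, 2))
            assert (update_W(X, W, H) >= 0).all()
            assert (update_H(X, W, H, g, 1.0, 1.0) >= 0).all()

    def test_W_update_never_increases_objective(self, rng):
        for _ in range(100):
            X = rng.uniform(size=(8, 6))
            W = rng.uniform(size=(8, 2))
            H = rng.uniform(size=(6, 2))
            before = objective(X, W, H)
            after = objective(X, update_W(X, W, H), H)
            assert after <= before * (1 + 1e-9)

    def test_H_update_never_increases_regularized_objective(self, rng):
        # 6-spot chain graph
        from fastdeconv import SpotGeometry, build_graph

        chain = build_graph(
            SpotGeometry(np.arange(6).astype(str), np.arange(6.0), np.zeros(6)),
            k=1,
        )
        for _ in range(100):
            X = rng.uniform(size=(8, 6))
            W = rng.uniform(size=(8, 2))
            H = rng.uniform(size=(6, 2))
            before = objective(X, W, H, chain, 1.0, 1.0)
            H1 = update_H(X, W, H, chain, 1.0, 1.0)
            after = objective(X, W, H1, chain, 1.0, 1.0)
            assert after <= before * (1 + 1e-9)

    def test_H_update_without_penalties_is_classic_rule(self, rng):
        X = rng.uniform(size=(8, 6))
        W = rng.uniform(size=(8, 2))
        H = rng.uniform(size=(6, 2))
        got = update_H(X, W, H)
        classic = H * (X.T @ W) / (H @ (W.T @ W) + 1e-12)
        assert np.allclose(got, classic, atol=1e-15)

    def test_sum_to_one_pull_with_dominant_penalty(self):
        # tiny residual/graph terms: a deficient row sum moves towards 1
        X = np.full((2, 3), 1e-6)
        W = np.full((2, 2), 1e-6)
        H = np.full((3, 2), 0.2)  # row sums 0.4
        H1 = update_H(X, W, H, lambda2=10.0)
        assert (np.abs(H1.sum(1) - 1) < np.abs(H.sum(1) - 1)).all()


class TestFit:
    def test_matches_plain_nmf_oracle_without_penalties(self):
        for seed in range(5):
            inst = np.random.default_rng(100 + seed)
            X = inst.uniform(size=(20, 15))
            r = np.random.default_rng(seed)
            W0 = r.uniform(size=(20, 3))
            H0 = r.uniform(size=(15, 3))
            oracle = plain_nmf_run(X, W0, H0, n_iter=25)
            for t in (1, 5, 25):
                cfg = SolverConfig(R=3, lambda1=0, lambda2=0, max_iter=t,
                                   tol=0.0, seed=seed)
                model = fit(X, None, cfg)
                W_t, H_t = oracle[t - 1]
                assert np.abs(model.W - W_t).max() < 1e-10
                assert np.abs(model.H - H_t).max() < 1e-10

    def test_recovers_planted_factorization(self, planted_factorization):
        _, _, X = planted_factorization
        cfg = SolverConfig(R=2, lambda1=0, lambda2=0, max_iter=2000,
                           tol=1e-9, seed=0)
        model = fit(X, None, cfg)
        rel = np.linalg.norm(X - model.W @ model.H.T) / np.linalg.norm(X)
        assert rel < 0.05

    def test_same_seed_reproduces_trace_bit_for_bit(self, rng, small_graph):
        X = rng.uniform(size=(10, small_graph.n_spots))
        cfg = SolverConfig(R=3, seed=9, max_iter=50)
        a = fit(X, small_graph, cfg)
        b = fit(X, small_graph, cfg)
        assert np.array_equal(a.objective_trace, b.objective_trace)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.H, b.H)

    def test_objective_trace_non_increasing_across_penalty_grid(self, rng):
        g = random_graph(10, seed=21, k=3)
        X = rng.uniform(size=(12, 10))
        for lam1 in (0, 0.01, 1, 10):
            for lam2 in (0, 0.01, 1, 10):
                cfg = SolverConfig(R=2, lambda1=lam1, lambda2=lam2,
                                   max_iter=100, seed=4)
                trace = fit(X, g, cfg).objective_trace
                drops = np.diff(trace)
                assert (drops <= 1e-9 * np.abs(trace[:-1])).all()

    def test_rank_larger_than_matrix_rejected(self, rng):
        with pytest.raises(ValueError, match="R"):
            fit(rng.uniform(size=(5, 4)), None, SolverConfig(R=5, lambda1=0))

    def test_graph_spot_mismatch_rejected(self, rng, small_graph):
        X = rng.uniform(size=(5, small_graph.n_spots + 1))
        with pytest.raises(ValueError, match="spots"):
            fit(X, small_graph, SolverConfig(R=2))

    def test_svd_init_fits_and_stays_non_negative(self, planted_factorization):
        _, _, X = planted_factorization
        cfg = SolverConfig(R=2, lambda1=0, lambda2=0, init="svd", max_iter=200)
        model = fit(X, None, cfg)
        assert (model.W >= 0).all() and (model.H >= 0).all()
        assert model.objective_trace[-1] <= model.objective_trace[0]

    def test_nndsvd_init_has_no_zeros(self, rng):
        W, H = nndsvd_init(rng.uniform(size=(12, 9)), 3)
        assert (W > 0).all() and (H > 0).all()

    def test_approximate_kkt_at_convergence(self, planted_factorization):
        _, _, X = planted_factorization
        g = random_graph(X.shape[1], seed=5, k=4)
        lam1, lam2 = 1.0, 1.0
        cfg = SolverConfig(R=2, lambda1=lam1, lambda2=lam2, max_iter=20000,
                           tol=1e-12, seed=1)
        model = fit(X, g, cfg)
        H, W = model.H, model.W
        grad = 2 * (
            H @ (W.T @ W)
            - X.T @ W
            + lam1 * (g.L @ H)
            + lam2 * H.shape[0] * (H.sum(1, keepdims=True) - 1)
        )
        assert np.minimum(H, np.abs(grad)).max() < 1e-3

    def test_lambda2_drives_row_sums_towards_one(self, rng):
        g = random_graph(15, seed=2, k=4)
        X = rng.uniform(size=(20, 15)) * 5
        devs = []
        for lam2 in (0, 0.1, 1, 10, 100):
            cfg = SolverConfig(R=3, lambda1=1.0, lambda2=lam2,
                               max_iter=3000, tol=1e-9, seed=11)
            model = fit(X, g, cfg)
            devs.append(np.abs(model.H.sum(1) - 1).mean())
        assert all(b <= a * (1 + 1e-9) for a, b in zip(devs, devs[1:]))


class TestProportions:
    def test_rows_normalized(self):
        out = proportions(np.array([[2.0, 2.0], [1.0, 3.0]]))
        assert np.allclose(out, [[0.5, 0.5], [0.25, 0.75]])

    def test_idempotent_on_stochastic_rows(self, rng):
        H = rng.dirichlet(np.ones(4), size=6)
        assert np.allclose(proportions(H), H)

    def test_zero_row_becomes_uniform_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="fastdeconv.solver"):
            out = proportions(np.array([[0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]]))
        assert np.allclose(out[0], 0.25)
        assert "all-zero" in caplog.text

    def test_rows_sum_to_one_exactly(self, rng):
        H = rng.uniform(size=(40, 5)) * rng.integers(0, 2, size=(40, 1))
        assert np.allclose(proportions(H).sum(1), 1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            proportions(np.array([[1.0, -0.1]]))
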