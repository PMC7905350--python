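import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfatigue import rols


def _gspace_regularized_oracle(Phi_sel, y, lam):
    """Independent path to the regularized solution: QR factorization,
    shrinkage of the orthogonal weights, triangular solve."""
    Q, R = np.linalg.qr(Phi_sel)
    d = np.diag(R)
    W = Q * d
    A = R / d[:, None]
    g = (W.T @ y) / (np.einsum("ij,ij->j", W, W) + lam)
    return np.linalg.solve(A, g)


def _single_term_cost_reduction(Phi, y, lam, beta):
    """Brute force: drop in the combined cost for each one-term model."""
    yty = y @ y
    out = np.empty(Phi.shape[1])
    for i in range(Phi.shape[1]):
        w = Phi[:, i]
        wtw = w @ w
        g = (w @ y) / (wtw + lam)
        e = y - w * g
        cost_with = e @ e + lam * g**2 - beta * np.log(wtw)
        out[i] = yty - cost_with  # reduction vs the empty model
    return out


class TestBuildCandidates:
    def test_duplicate_rows_all_ones(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        with pytest.warns(UserWarning, match="duplicate"):
            model = rols.build_candidates(X, np.array([0.0, 1.0]), rho=1.0)
        np.testing.assert_allclose(model.Phi, np.ones((2, 2)))

    def test_distance_sqrt_rho(self):
        rho = 2.5
        X = np.array([[0.0], [np.sqrt(rho)]])
        model = rols.build_candidates(X, np.zeros(2), rho=rho)
        assert model.Phi[0, 1] == pytest.approx(np.exp(-1.0))
        assert model.Phi[1, 0] == pytest.approx(np.exp(-1.0))

    def test_double_loop_oracle(self, rng):
        X = rng.standard_normal((5, 3))
        rho = 0.7
        model = rols.build_candidates(X, rng.standard_normal(5), rho=rho)
        expected = np.empty((5, 5))
        for k in range(5):
            for i in range(5):
                expected[k, i] = np.exp(-np.sum((X[k] - X[i]) ** 2) / rho)
        np.testing.assert_allclose(model.Phi, expected, atol=1e-14)

    def test_structure_invariants(self, rng):
        X = rng.standard_normal((7, 2))
        model = rols.build_candidates(X, rng.standard_normal(7), rho=1.3)
        np.testing.assert_allclose(np.diag(model.Phi), 1.0)
        np.testing.assert_allclose(model.Phi, model.Phi.T)
        assert (model.Phi > 0).all() and (model.Phi <= 1.0).all()

    def test_rejects_bad_inputs(self, rng):
        X = rng.standard_normal((4, 2))
        with pytest.raises(ValueError):
            rols.build_candidates(X, np.zeros(4), rho=0.0)
        with pytest.raises(ValueError):
            rols.build_candidates(X[:1], np.zeros(1), rho=1.0)


class TestForwardSelect:
    def test_exact_single_column_target(self, rng):
        X = rng.standard_normal((6, 2))
        model = rols.build_candidates(X, np.zeros(6), rho=1.0)
        j = 3
        model.y = model.Phi[:, j].copy()
        trace = rols.forward_select(model, lam=0.0, beta=0.0, max_terms=6)
        assert trace.selected[0] == j
        resid = model.y - trace.W[:, :1] @ trace.g[:1]
        assert float(resid @ resid) < 1e-20

    @pytest.mark.parametrize("lam,beta", [(0.0, 0.0), (0.1, 0.0), (0.05, 0.01)])
    def test_step1_matches_exhaustive_cost_oracle(self, lam, beta):
        rng = np.random.default_rng(7)
        X = rng.uniform(-2, 2, size=(4, 1))
        y = rng.standard_normal(4)
        model = rols.build_candidates(X, y, rho=1.0)
        reductions = _single_term_cost_reduction(model.Phi, y, lam, beta)
        trace = rols.forward_select(model, lam=lam, beta=beta)
        assert trace.selected[0] == int(np.argmax(reductions))

    def test_huge_beta_terminates_early(self):
        # deflated columns shrink below unit norm, so a large beta makes the
        # log term dominate negative after a few steps and selection stops
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, size=(8, 1))
        y = rng.standard_normal(8)
        model = rols.build_candidates(X, y, rho=1.0)
        trace_big = rols.forward_select(model, lam=0.0, beta=10.0)
        trace_zero = rols.forward_select(model, lam=0.0, beta=0.0)
        assert trace_big.n_selected <= trace_zero.n_selected
        assert trace_big.stop_reason == "no_positive_crerr"
        assert (trace_big.crerr > 0).all()

    def test_huge_beta_stops_empty_short_columns(self):
        # Gaussian candidate columns always have norm >= 1 (unit diagonal), so
        # a negative step-1 log term needs artificially short columns; verify
        # the direct evaluation of the selection score on such a toy model
        rng = np.random.default_rng(3)
        Phi = 0.1 * rng.standard_normal((4, 4))
        y = rng.standard_normal(4)
        model = rols.CandidateModel(
            Phi=Phi, centers=rng.standard_normal((4, 1)), rho=1.0, y=y
        )
        wtw = np.einsum("ij,ij->j", Phi, Phi)
        assert (np.log(wtw) < 0).all()
        g = (Phi.T @ y) / wtw
        beta = 2 * float(np.max(wtw * g**2 / -np.log(wtw)))
        assert all(
            w * gi**2 + beta * np.log(w) < 0 for w, gi in zip(wtw, g)
        )
        trace = rols.forward_select(model, lam=0.0, beta=beta)
        assert trace.n_selected == 0
        assert trace.stop_reason == "no_positive_crerr"

    def test_tie_breaks_to_lowest_index(self):
        # duplicate candidates: identical crerr, lowest index must win
        X = np.array([[0.0], [0.0], [3.0]])
        y = np.array([1.0, 1.0, 0.2])
        with pytest.warns(UserWarning):
            model = rols.build_candidates(X, y, rho=1.0)
        trace = rols.forward_select(model, lam=0.0, beta=0.0, max_terms=1)
        assert trace.selected[0] == 0

    def test_collinear_candidates_skipped(self):
        X = np.array([[0.0], [0.0], [1.0], [2.0]])
        y = np.array([1.0, 1.0, 0.0, -1.0])
        with pytest.warns(UserWarning):
            model = rols.build_candidates(X, y, rho=1.0)
        trace = rols.forward_select(model, lam=0.0, beta=0.0)
        # columns 0 and 1 are identical: at most one of them can be selected
        assert len({0, 1} & set(trace.selected)) <= 1
        assert trace.n_selected <= 3

    def test_determinism(self, rng):
        X = rng.standard_normal((9, 3))
        y = rng.standard_normal(9)
        model = rols.build_candidates(X, y, rho=2.0)
        t1 = rols.forward_select(model, lam=0.01, beta=1e-4)
        t2 = rols.forward_select(model, lam=0.01, beta=1e-4)
        assert t1.selected == t2.selected
        np.testing.assert_array_equal(t1.g, t2.g)


class TestRecoverWeights:
    def test_identity_system(self):
        trace = rols.SelectionTrace(
            selected=[0, 1],
            W=np.eye(2),
            A=np.eye(2),
            g=np.array([3.0, -1.0]),
            crerr=np.array([0.5, 0.1]),
            lam=0.0,
            beta=0.0,
            stop_reason="all_selected",
        )
        np.testing.assert_allclose(rols.recover_weights(trace), [3.0, -1.0])

    def test_two_by_two_example(self):
        trace = rols.SelectionTrace(
            selected=[0, 1],
            W=np.eye(2),
            A=np.array([[1.0, 0.5], [0.0, 1.0]]),
            g=np.array([1.0, 2.0]),
            crerr=np.array([0.5, 0.1]),
            lam=0.0,
            beta=0.0,
            stop_reason="all_selected",
        )
        theta = rols.recover_weights(trace)
        oracle = np.linalg.inv(trace.A) @ trace.g
        np.testing.assert_allclose(theta, [0.0, 2.0], atol=1e-14)
        np.testing.assert_allclose(theta, oracle, atol=1e-14)

    def test_defining_property(self, rng):
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        model = rols.build_candidates(X, y, rho=1.5)
        trace = rols.forward_select(model, lam=0.02, beta=1e-5)
        theta = rols.recover_weights(trace)
        assert np.linalg.norm(trace.A @ theta - trace.g) < 1e-10

    def test_empty_trace_rejected(self):
        trace = rols.SelectionTrace(
            selected=[], W=np.zeros((3, 0)), A=np.zeros((0, 0)),
            g=np.zeros(0), crerr=np.zeros(0), lam=0.0, beta=0.0,
            stop_reason="no_positive_crerr",
        )
        with pytest.raises(ValueError):
            rols.recover_weights(trace)


class TestFit:
    def test_interpolation_limit(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        net, trace = rols.fit(X, y, lam=0.0, rho=1.0, beta=0.0, max_terms=10)
        from eegfatigue.predict import predict

        mse = float(np.mean((predict(net, X) - y) ** 2))
        assert mse < 1e-8

    @pytest.mark.parametrize("lam", [0.0, 1e-3, 0.05, 0.5])
    def test_weights_match_gspace_regularized_oracle(self, lam, rng):
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        net, trace = rols.fit(X, y, lam=lam, rho=2.0, beta=1e-5)
        model = rols.build_candidates(X, y, rho=2.0)
        theta_oracle = _gspace_regularized_oracle(model.Phi[:, trace.selected], y, lam)
        np.testing.assert_allclose(net.theta, theta_oracle, atol=1e-8)

    def test_lam_zero_equals_plain_least_squares(self, rng):
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        net, trace = rols.fit(X, y, lam=0.0, rho=1.5, beta=1e-6)
        model = rols.build_candidates(X, y, rho=1.5)
        Phi_s = model.Phi[:, trace.selected]
        theta_ls, *_ = np.linalg.lstsq(Phi_s, y, rcond=None)
        np.testing.assert_allclose(net.theta, theta_ls, atol=1e-8)

    def test_g_norm_shrinks_with_lambda(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        _, trace0 = rols.fit(X, y, lam=0.0, rho=1.0, beta=0.0, max_terms=5)
        W = trace0.W
        wtw = np.einsum("ij,ij->j", W, W)
        prev = np.inf
        for lam in (0.0, 0.01, 0.1, 1.0, 10.0):
            g = (W.T @ y) / (wtw + lam)
            norm = float(np.linalg.norm(g))
            assert norm <= prev + 1e-12
            prev = norm

    def test_theta_norm_shrinks_on_fixed_subset(self):
        # ridge-path behaviour on one frozen selected subset
        rng = np.random.default_rng(42)
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        _, trace0 = rols.fit(X, y, lam=0.0, rho=1.0, beta=0.0, max_terms=4)
        model = rols.build_candidates(X, y, rho=1.0)
        Phi_s = model.Phi[:, trace0.selected]
        prev = np.inf
        for lam in (0.0, 0.01, 0.1, 1.0, 10.0):
            theta = _gspace_regularized_oracle(Phi_s, y, lam)
            norm = float(np.linalg.norm(theta))
            assert norm <= prev + 1e-12
            prev = norm

    def test_empty_selection_raises_with_advice(self):
        # an all-zero target gives zero error reduction for every candidate
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, size=(4, 1))
        y = np.zeros(4)
        with pytest.raises(rols.EmptySelectionError, match="beta"):
            rols.fit(X, y, lam=0.0, rho=1.0, beta=0.0)


class TestTraceInvariants:
    @given(seed=st.integers(min_value=0, max_value=200))
    @settings(max_examples=25, deadline=None)
    def test_orthogonality_and_consistency(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 13))
        X = rng.standard_normal((N, 2))
        y = rng.standard_normal(N)
        lam = float(rng.uniform(0, 0.5))
        beta = float(10 ** rng.uniform(-7, -2))
        model = rols.build_candidates(X, y, rho=float(rng.uniform(0.5, 5)))
        trace = rols.forward_select(model, lam=lam, beta=beta)
        if trace.n_selected < 2:
            return
        W, A = trace.W, trace.A
        G = W.T @ W
        norms = np.sqrt(np.diag(G))
        off = np.abs(G - np.diag(np.diag(G))) / np.outer(norms, norms)
        assert off.max() < 1e-8
        np.testing.assert_allclose(W @ A, model.Phi[:, trace.selected], atol=1e-8)
        assert np.all(np.diag(A) == 1.0)

    def test_cost_nonincreasing_beta_zero(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        lam = 0.03
        model = rols.build_candidates(X, y, rho=1.0)
        trace = rols.forward_select(model, lam=lam, beta=0.0)
        assert (trace.crerr >= 0).all()
        # recompute the regularized cost directly after each prefix of steps
        prev_cost = float(y @ y)
        for k in range(1, trace.n_selected + 1):
            W = trace.W[:, :k]
            g = trace.g[:k]
            e = y - W @ g
            cost = float(e @ e + lam * g @ g)
            assert cost <= prev_cost + 1e-10
            prev_cost = cost

    @given(seed=st.integers(min_value=0, max_value=100))
    @settings(max_examples=20, deadline=None)
    def test_final_weights_equal_bruteforce_on_subset(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 13))
        X = rng.standard_normal((N, 2))
        y = rng.standard_normal(N)
        lam = float(rng.uniform(0, 0.3))
        try:
            net, trace = rols.fit(X, y, lam=lam, rho=1.5, beta=1e-6)
        except rols.EmptySelectionError:
            return
        model = rols.build_candidates(X, y, rho=1.5)
        oracle = _gspace_regularized_oracle(model.Phi[:, trace.selected], y, lam)
        np.testing.assert_allclose(net.theta, oracle, atol=1e-8)
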