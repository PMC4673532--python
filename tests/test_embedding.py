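import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm, solve_continuous_lyapunov

from dnmark.embedding import (LinearModel, MomentEmbedder, MomentIndexMap,
                              MomentSeries, SlidingWindowSpec,
                              gaussian_closure_field_1d, linear_moment_field,
                              moment_bifurcation_scan, moment_dimension,
                              noise_reduction_ratio, propagate_moments,
                              sliding_window_moments)
from dnmark.simulate import SDEModel, ensemble, ensemble_moments


class TestMomentDimension:
    @pytest.mark.parametrize("n, expected", [(1, 2), (11, 77), (18, 189)])
    def test_reference_counts(self, n, expected):
        assert moment_dimension(n) == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=1, max_value=500))
    def test_two_formulas_agree(self, n):
        assert moment_dimension(n) == n + n * (n + 1) // 2

    def test_rejects_bad_n(self):
        with pytest.raises(ValueError):
            moment_dimension(0)


class TestIndexMap:
    def test_bijective_and_sized(self):
        imap = MomentIndexMap(5)
        assert imap.size == moment_dimension(5)
        assert len(set(imap.pairs)) == imap.n_second
        assert len(set(imap.names())) == imap.size
        # packing order is row-major upper triangle
        assert imap.pairs[:5] == [(0, 0), (0, 1), (0, 2), (0, 3), (0, 4)]
        assert imap.pairs[5] == (1, 1)

    def test_pack_unpack_roundtrip(self, rng):
        imap = MomentIndexMap(4)
        A = rng.standard_normal((4, 4))
        V = A + A.T
        np.testing.assert_array_equal(imap.unpack(imap.pack(V)), V)


class TestSlidingWindowMoments:
    def test_matches_bruteforce_loops(self, rng):
        X = rng.standard_normal((50, 5))
        for step in (1, 3):
            spec = SlidingWindowSpec(length=7, step=step)
            ms = sliding_window_moments(X, spec)
            starts = range(0, 50 - 7 + 1, step)
            for w, s in enumerate(starts):
                win = X[s: s + 7]
                np.testing.assert_allclose(ms.first_moments[w], win.mean(axis=0),
                                           atol=1e-12)
                C = np.cov(win, rowvar=False, ddof=1)
                np.testing.assert_allclose(
                    ms.second_central_moments[w], ms.index_map.pack(C), atol=1e-12
                )

    def test_constant_series_degenerate(self):
        X = np.full((30, 2), 3.5)
        ms = sliding_window_moments(X, SlidingWindowSpec(10, 1))
        np.testing.assert_array_equal(ms.first_moments, 3.5)
        np.testing.assert_array_equal(ms.second_central_moments, 0.0)
        ms.validate()

    def test_three_point_window(self):
        ms = sliding_window_moments(np.array([1.0, 2.0, 3.0]),
                                    SlidingWindowSpec(3, 1))
        assert ms.first_moments[0, 0] == 2.0
        assert ms.second_central_moments[0, 0] == 1.0

    def test_linear_dependence(self, rng):
        x1 = rng.standard_normal(40)
        X = np.column_stack([x1, 2.0 * x1])
        ms = sliding_window_moments(X, SlidingWindowSpec(10, 1))
        v11 = ms.second_central_moments[:, ms.index_map.column_of(0, 0)]
        v12 = ms.second_central_moments[:, ms.index_map.column_of(0, 1)]
        v22 = ms.second_central_moments[:, ms.index_map.column_of(1, 1)]
        np.testing.assert_allclose(v12, 2.0 * v11, rtol=1e-12)
        np.testing.assert_allclose(v12 / np.sqrt(v11 * v22), 1.0, rtol=1e-12)

    def test_replicates_pool_within_window(self, rng):
        X = rng.standard_normal((20, 4, 3))  # T=20, S=4 replicates, n=3
        spec = SlidingWindowSpec(5, 1)
        ms = sliding_window_moments(X, spec)
        pooled = X[0:5].reshape(20, 3)
        np.testing.assert_allclose(ms.first_moments[0], pooled.mean(axis=0),
                                   atol=1e-12)
        np.testing.assert_allclose(
            ms.second_central_moments[0],
            ms.index_map.pack(np.cov(pooled, rowvar=False, ddof=1)),
            atol=1e-12,
        )

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_window_moments(np.zeros((5, 1)), SlidingWindowSpec(10, 1))

    def test_label_positions(self):
        X = np.arange(20.0)[:, None]
        for pos, expected in (("left", 0.0), ("center", 5.0), ("right", 9.0)):
            ms = sliding_window_moments(X, SlidingWindowSpec(10, 1, pos))
            assert ms.window_labels[0] == expected

    def test_embedder_sklearn_api(self, rng):
        X = rng.standard_normal((40, 3))
        emb = MomentEmbedder(window=10).fit(X)
        assert emb.n_moments_ == moment_dimension(3)
        Z = emb.transform(X)
        assert Z.shape == (31, 9)
        assert list(emb.get_feature_names_out())[:3] == ["u_1", "u_2", "u_3"]
        assert emb.get_params()["window"] == 10


class TestNoiseReductionRatio:
    def test_iid_ratio_near_inverse_sqrt_length(self, rng):
        X = rng.standard_normal((5000, 1))
        r = noise_reduction_ratio(X, SlidingWindowSpec(10, 10))
        assert abs(r[0] - 1 / np.sqrt(10)) < 0.25 / np.sqrt(10)

    def test_constant_series_flagged(self):
        r = noise_reduction_ratio(np.full((300, 1), 2.0), SlidingWindowSpec(10, 10))
        assert np.isnan(r[0])


class TestLinearMomentField:
    def test_ou_stationary_variance(self):
        fld = linear_moment_field(LinearModel(A=[[-1.0]], b=[0.0], D=[[0.25]]))
        # sigma^2/(2 theta) = 0.125 zeroes the field
        np.testing.assert_allclose(fld(np.array([0.0, 0.125])), 0.0, atol=1e-15)

    def test_pure_drift(self):
        fld = linear_moment_field(LinearModel(A=np.zeros((2, 2)), b=[1.0, -2.0],
                                              D=np.zeros((2, 2))))
        dz = fld(np.array([0.0, 0.0, 1.0, 0.5, 2.0]))
        np.testing.assert_array_equal(dz[:2], [1.0, -2.0])
        np.testing.assert_array_equal(dz[2:], 0.0)

    def test_decoupled_lyapunov(self):
        fld = linear_moment_field(LinearModel(A=np.diag([-1.0, -2.0]),
                                              b=[0.0, 0.0], D=np.eye(2)))
        z_star = np.array([0.0, 0.0, 0.5, 0.0, 0.25])
        np.testing.assert_allclose(fld(z_star), 0.0, atol=1e-15)

    def test_random_stationary_covariance_solves_lyapunov(self, rng):
        # oracle: scipy's continuous Lyapunov solver
        M = rng.standard_normal((3, 3))
        A = M - (np.linalg.eigvals(M).real.max() + 1.0) * np.eye(3)
        C = rng.standard_normal((3, 3))
        D = C @ C.T
        V_star = solve_continuous_lyapunov(A, -D)
        imap = MomentIndexMap(3)
        u_star = np.linalg.solve(A, -rng.standard_normal(3) * 0.0)
        z = np.concatenate([u_star, imap.pack(V_star)])
        fld = linear_moment_field(LinearModel(A=A, b=np.zeros(3), D=D))
        np.testing.assert_allclose(fld(z), 0.0, atol=1e-9)


class TestGaussianClosure:
    def test_linear_drift_reduces_to_linear_field_exactly(self):
        a, c, sigma = -0.7, 0.3, 0.4
        closure = gaussian_closure_field_1d(
            lambda x: a * x + c, sigma,
            fprime=lambda x: a, fsecond=lambda x: 0.0,
        )
        linear = linear_moment_field(
            LinearModel(A=[[a]], b=[c], D=[[sigma ** 2]])
        )
        for z in ([0.0, 0.0], [1.5, 0.2], [-2.0, 1.0]):
            np.testing.assert_array_equal(closure(np.array(z)),
                                          linear(np.array(z)))

    def test_fold_closure_matches_symbolic_derivation(self):
        # oracle: symbolic differentiation of f = p + 3x - x^3
        u_s, v_s, p_s, s_s = sympy.symbols("u v p sigma")
        f = p_s + 3 * u_s - u_s ** 3
        du = f + sympy.Rational(1, 2) * sympy.diff(f, u_s, 2) * v_s
        dv = 2 * sympy.diff(f, u_s) * v_s + s_s ** 2
        du_fn = sympy.lambdify((u_s, v_s, p_s, s_s), du)
        dv_fn = sympy.lambdify((u_s, v_s, p_s, s_s), dv)
        p, sigma = -1.3, 0.8
        fld = gaussian_closure_field_1d(
            lambda x: p + 3 * x - x ** 3, sigma,
            fprime=lambda x: 3 - 3 * x ** 2, fsecond=lambda x: -6 * x,
        )
        for u, v in [(-2.0, 0.1), (0.5, 0.3), (1.7, 0.0)]:
            np.testing.assert_allclose(
                fld(np.array([u, v])),
                [du_fn(u, v, p, sigma), dv_fn(u, v, p, sigma)],
                rtol=1e-12,
            )

    def test_numeric_derivatives_close_to_analytic(self):
        fld_num = gaussian_closure_field_1d(lambda x: 2 * x - x ** 3, 0.5)
        fld_ana = gaussian_closure_field_1d(
            lambda x: 2 * x - x ** 3, 0.5,
            fprime=lambda x: 2 - 3 * x ** 2, fsecond=lambda x: -6 * x,
        )
        z = np.array([0.7, 0.2])
        np.testing.assert_allclose(fld_num(z), fld_ana(z), rtol=1e-5, atol=1e-5)

    def test_noise_free_limit_keeps_zero_variance(self):
        fld = gaussian_closure_field_1d(
            lambda x: 1.0 + 3 * x - x ** 3, 0.0,
            fprime=lambda x: 3 - 3 * x ** 2, fsecond=lambda x: -6 * x,
        )
        Z = propagate_moments(fld, np.array([-2.0, 0.0]), np.linspace(0, 5, 51))
        np.testing.assert_array_equal(Z[:, 1], 0.0)


class TestPropagateMoments:
    def test_ou_closed_form(self):
        sigma = 0.5
        fld = linear_moment_field(LinearModel(A=[[-1.0]], b=[0.0],
                                              D=[[sigma ** 2]]))
        times = np.linspace(0.0, 5.0, 101)
        Z = propagate_moments(fld, np.array([1.0, 0.0]), times)
        np.testing.assert_allclose(Z[:, 0], np.exp(-times), atol=1e-7)
        np.testing.assert_allclose(
            Z[:, 1], sigma ** 2 / 2 * (1 - np.exp(-2 * times)), atol=1e-7
        )

    def test_linear_2d_matches_matrix_exponential(self, rng):
        # oracle: the packed moment field of a linear SDE is affine,
        # z' = M z + c, solvable by the exponential of an augmented matrix
        M0 = rng.standard_normal((2, 2))
        A = M0 - (np.linalg.eigvals(M0).real.max() + 0.8) * np.eye(2)
        C = rng.standard_normal((2, 2)) * 0.5
        model = LinearModel(A=A, b=rng.standard_normal(2), D=C @ C.T)
        fld = linear_moment_field(model)
        N = fld.size
        c = fld(np.zeros(N))
        M = np.column_stack([fld(e) - c for e in np.eye(N)])
        aug = np.zeros((N + 1, N + 1))
        aug[:N, :N] = M
        aug[:N, N] = c
        z0 = np.array([1.0, -1.0, 0.3, 0.1, 0.2])
        t_final = 2.0
        exact = (expm(aug * t_final) @ np.append(z0, 1.0))[:N]
        Z = propagate_moments(fld, z0, np.linspace(0.0, t_final, 21))
        np.testing.assert_allclose(Z[-1], exact, atol=1e-6)

    def test_monte_carlo_ensemble_agreement(self, rng):
        # cross-check against sampled moments of the same SDE
        A = np.array([[-1.0, 0.3], [0.0, -0.5]])
        b = np.array([0.2, -0.1])
        D = np.diag([0.09, 0.04])
        model = SDEModel(drift=lambda x, p: A @ x + b, noise_cov=D, n_vars=2)
        x0 = np.array([1.0, -0.5])
        times = np.linspace(0.0, 1.5, 151)
        trajs = ensemble(model, x0, times, n_reps=800, seed=17)
        _, U, V = ensemble_moments(trajs)
        imap = MomentIndexMap(2)
        fld = linear_moment_field(LinearModel(A=A, b=b, D=D))
        Z = propagate_moments(fld, np.concatenate([x0, np.zeros(3)]), times)
        X_end = np.stack([t.states[-1] for t in trajs])
        se_u = X_end.std(axis=0, ddof=1) / np.sqrt(800)
        assert np.all(np.abs(U[-1] - Z[-1, :2]) < 3 * se_u)
        # covariance entries: SE from the spread of centered products
        prods = np.einsum("ri,rj->rij", X_end - U[-1], X_end - U[-1])
        se_v = prods.std(axis=0, ddof=1) / np.sqrt(800)
        V_pred = imap.unpack(Z[-1, 2:])
        assert np.all(np.abs(V[-1] - V_pred) < 3 * se_v + 1e-12)


class TestBifurcationScan:
    @staticmethod
    def closure_factory(sigma):
        def factory(p):
            return gaussian_closure_field_1d(
                lambda x: p + 3 * x - x ** 3, sigma,
                fprime=lambda x: 3 - 3 * x ** 2, fsecond=lambda x: -6 * x,
            )
        return factory

    @staticmethod
    def closed_form_fold(sigma):
        # on the lower branch the closed moment system reduces to
        # p(u) = u^3 - 3u + u sigma^2 / (2(u^2-1)); the fold is its maximum
        from scipy.optimize import minimize_scalar

        if sigma == 0:
            return 2.0
        obj = lambda u: -(u ** 3 - 3 * u + u * sigma ** 2 / (2 * (u ** 2 - 1)))
        res = minimize_scalar(obj, bounds=(-2.5, -1.0001), method="bounded")
        return -res.fun

    @pytest.mark.parametrize("sigma", [0.0, 0.5])
    def test_fold_location_matches_closed_form(self, sigma):
        grid = np.arange(-6.0, 3.0, 0.01)
        scan = moment_bifurcation_scan(self.closure_factory(sigma), grid,
                                       z0=np.array([-2.1455, 0.0]))
        assert scan.has_fold
        assert abs(scan.p_fold - self.closed_form_fold(sigma)) < 0.02
        assert scan.stable.all()

    def test_linear_system_has_no_fold(self):
        def factory(p):
            return linear_moment_field(LinearModel(A=[[-1.0]], b=[p], D=[[0.25]]))

        scan = moment_bifurcation_scan(factory, np.linspace(-3, 3, 61),
                                       z0=np.array([-3.0, 0.125]))
        assert not scan.has_fold
        assert scan.p_branch.size == 61

    def test_first_point_failure_raises(self):
        def factory(p):
            return gaussian_closure_field_1d(
                lambda x: p + 3 * x - x ** 3, 0.1,
                fprime=lambda x: 3 - 3 * x ** 2, fsecond=lambda x: -6 * x,
            )
        with pytest.raises(RuntimeError, match="first"):
            moment_bifurcation_scan(factory, np.linspace(5.9, 6.0, 3),
                                    z0=np.array([-200.0, 1e6]))


class TestMomentSeriesValidation:
    def test_negative_variance_caught(self):
        with pytest.raises(ValueError, match="negative variance"):
            MomentSeries(
                window_labels=[0.0],
                first_moments=[[0.0]],
                second_central_moments=[[-1.0]],
                n_vars=1,
            ).validate()

    def test_invalid_minor_caught(self):
        # |v_12| > sqrt(v_11 v_22) cannot come from a covariance
        with pytest.raises(ValueError, match="minor"):
            MomentSeries(
                window_labels=[0.0],
                first_moments=[[0.0, 0.0]],
                second_central_moments=[[1.0, 5.0, 1.0]],
                n_vars=2,
            ).validate()
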