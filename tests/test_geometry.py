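import numpy as np
import pytest

import infogeom as ig


def _uninormal_metric_args():
    model = ig.get_model("normal", free=("mu", "sigma"))
    noise = ig.NoiseModel(sigma_known=False)
    return model, [0.0], [10], noise


class TestFisherMetric:
    def test_univariate_normal_reproduces_observation_information(self):
        model, times, counts, noise = _uninormal_metric_args()
        G = ig.fisher_metric(model, times, counts, noise, [0.7, 0.5])
        assert np.allclose(G, (10 / 0.25) * np.diag([1.0, 2.0]))

    def test_linear_model_assembly(self):
        model = ig.get_model("linear", free=("a", "C0"))
        T = np.array([0.1, 0.25, 0.5])
        sigma, n = 0.2301, 10
        G = ig.fisher_metric(model, T, n, ig.NoiseModel(sigma=sigma), [0.9, 0.7])
        expected = (n / sigma**2) * np.array(
            [[np.sum(T**2), np.sum(T)], [np.sum(T), T.size]]
        )
        assert np.allclose(G, expected)

    def test_singular_at_steady_state_initialization(self):
        # r is unidentifiable when the process starts at carrying capacity
        model = ig.get_model("logistic", free=("r", "K"), fixed={"C0": 79.74})
        with pytest.raises(ig.SingularFisherError, match="r"):
            ig.fisher_metric(
                model, [2.74, 6.84, 10.95], 10, ig.NoiseModel(sigma=2.301), [0.9, 79.74]
            )

    def test_design_dependence_not_data_dependence(self):
        # the metric depends on times/counts/sigma only
        model, times, counts, noise = _uninormal_metric_args()
        G1 = ig.fisher_metric(model, times, counts, noise, [0.2, 0.9])
        G2 = ig.fisher_metric(model, times, counts, noise, [5.0, 0.9])
        assert np.allclose(G1, G2)  # mean translation does not change it

    def test_inverse_consistency(self):
        field = ig.MetricField.normal(10)
        th = np.array([0.7, 0.5])
        assert np.allclose(field.g_inv(th) @ field.g(th), np.eye(2), atol=1e-12)


class TestChristoffel:
    def test_constant_metric_gives_zero_symbols(self):
        field = ig.MetricField.euclidean(2, scale=4.0)
        assert np.allclose(ig.christoffel(field, [0.3, 1.2]), 0.0, atol=1e-12)

    def test_closed_form_normal_manifold_symbols(self):
        field = ig.MetricField.normal(7)
        mu, sigma = 0.7, 0.5
        Gam = ig.christoffel(field, [mu, sigma])
        expected = np.zeros((2, 2, 2))
        expected[0, 0, 1] = expected[0, 1, 0] = -1.0 / sigma
        expected[1, 0, 0] = 1.0 / (2.0 * sigma)
        expected[1, 1, 1] = -1.0 / sigma
        assert np.abs(Gam - expected).max() < 1e-6

    def test_symmetric_in_lower_indices(self):
        model = ig.get_model("logistic", free=("r", "C0"))
        field = ig.fisher_metric_field(model, [2.74, 6.84, 10.95], 10, ig.NoiseModel(sigma=2.301))
        Gam = ig.christoffel(field, [0.9, 0.4])
        assert np.allclose(Gam, np.swapaxes(Gam, 1, 2))

    def test_index_raise_lower_round_trip(self):
        field = ig.MetricField.normal(3)
        th = np.array([0.2, 0.8])
        Gam2 = ig.christoffel(field, th)  # second kind
        g, ginv = field.g(th), field.g_inv(th)
        Gam1 = np.einsum("km,mij->kij", g, Gam2)  # lower the index
        back = np.einsum("km,mij->kij", ginv, Gam1)
        assert np.abs(back - Gam2).max() < 1e-8


class TestGeodesicIVP:
    def test_flat_space_geodesics_are_straight_lines(self):
        field = ig.MetricField.euclidean(2)
        path = ig.geodesic_ivp(field, [0.0, 0.0], [3.0, 4.0], 2.0)
        expected = np.outer(path.s, [0.6, 0.8])
        assert np.abs(path.positions - expected).max() < 1e-8
        assert path.length == pytest.approx(2.0)

    def test_endpoint_distance_matches_closed_form(self, normal_metric_n10):
        path = ig.geodesic_ivp(normal_metric_n10, [0.5, 0.5], [1.0, 0.3], 1.5)
        d = ig.fisher_rao_normal_distance([0.5, 0.5], path.end, n_obs=10)
        assert d == pytest.approx(1.5, abs=1e-4)

    def test_flow_reversibility(self, normal_metric_n10):
        fwd = ig.geodesic_ivp(normal_metric_n10, [0.7, 0.5], [1.0, 0.4], 1.2)
        back = ig.geodesic_ivp(normal_metric_n10, fwd.end, -fwd.velocities[-1], 1.2)
        assert np.abs(back.end - [0.7, 0.5]).max() < 1e-6

    def test_metric_speed_conserved(self, normal_metric_n10):
        path = ig.geodesic_ivp(normal_metric_n10, [0.7, 0.5], [0.2, -1.0], 2.0)
        speeds = path.speeds(normal_metric_n10)
        assert np.ptp(speeds) / speeds.mean() < 1e-4

    def test_truncates_at_admissible_boundary(self):
        field = ig.MetricField.euclidean(2)
        field.bounds = [(-1.0, 1.0), (-1.0, 1.0)]
        path = ig.geodesic_ivp(field, [0.0, 0.0], [1.0, 0.0], 5.0)
        assert path.truncated
        assert path.end[0] == pytest.approx(1.0, abs=1e-5)

    def test_zero_direction_rejected(self, normal_metric_n10):
        with pytest.raises(ValueError, match="nonzero"):
            ig.geodesic_ivp(normal_metric_n10, [0.7, 0.5], [0.0, 0.0], 1.0)


class TestGeodesicSpray:
    def test_default_count_is_twenty(self):
        field = ig.MetricField.euclidean(2)
        spray = ig.geodesic_spray(field, [0.0, 0.0])
        assert len(spray) == 20

    def test_flat_case_endpoints_reach_confidence_distance(self):
        # for the MVN-means metric the endpoints sit exactly on the
        # likelihood boundary circle of radius sigma sqrt(Delta / N)
        model = ig.get_model("mvnormal", free=("mu1", "mu2"))
        field = ig.fisher_metric_field(model, [0.0], [10], ig.NoiseModel(sigma=0.3))
        center = np.array([0.71, 1.15])
        spray = ig.geodesic_spray(field, center, alpha=0.95)
        radius = 0.3 * np.sqrt(ig.chi2_threshold(0.95, 2) / 10)
        ends = np.array([p.end for p in spray])
        assert np.abs(np.linalg.norm(ends - center, axis=1) - radius).max() < 1e-3

    def test_sigma_endpoints_biased_low_on_normal_manifold(self, uninormal_data):
        # geodesic endpoints sit at smaller sigma than the likelihood
        # boundary along the sigma axis
        from scipy.optimize import brentq

        model, data, noise = uninormal_data
        mle = ig.find_mle(model, data, noise, n_restarts=5)
        field = ig.fisher_metric_field(model, [0.0], [10], noise)
        spray = ig.geodesic_spray(field, mle.values, count=20)
        ends = np.array([p.end for p in spray])
        thr = -0.5 * ig.chi2_threshold(0.95, 2)

        def lhat_minus_thr(s):
            return (
                ig.log_likelihood(model, [mle.values[0], s], data, noise)
                - mle.log_likelihood
                - thr
            )

        sig_up = brentq(lhat_minus_thr, mle.values[1], 5 * mle.values[1])
        sig_dn = brentq(lhat_minus_thr, 1e-3, mle.values[1])
        assert ends[:, 1].max() < sig_up
        assert ends[:, 1].min() < sig_dn


class TestGeodesicBVP:
    def test_degenerate_endpoints(self, normal_metric_n10):
        path = ig.geodesic_bvp(normal_metric_n10, [0.7, 0.5], [0.7, 0.5])
        assert path.length == 0.0

    def test_flat_metric_straight_line_distance(self):
        G = np.array([[4.0, 1.0], [1.0, 3.0]])
        field = ig.MetricField.from_function(lambda _t: G, 2)
        a, b = np.array([0.1, 0.2]), np.array([1.0, -0.5])
        path = ig.geodesic_bvp(field, a, b)
        assert path.length == pytest.approx(np.sqrt((a - b) @ G @ (a - b)), rel=1e-8)

    def test_univariate_normal_squared_length(self, normal_metric_n10):
        path = ig.geodesic_bvp(normal_metric_n10, [0.5050, 0.4846], [0.6, 0.3])
        assert path.length**2 == pytest.approx(5.1954, abs=2e-3)

    def test_oracle_equivalence_random_pairs(self, normal_metric_n10):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = np.array([rng.uniform(-1, 1), rng.uniform(0.3, 1.5)])
            b = np.array([rng.uniform(-1, 1), rng.uniform(0.3, 1.5)])
            d_bvp = ig.geodesic_bvp(normal_metric_n10, a, b).length
            d_cf = ig.fisher_rao_normal_distance(a, b, n_obs=10)
            assert abs(d_bvp - d_cf) / d_cf < 1e-3


class TestFisherRaoNormalDistance:
    def test_identity(self):
        assert ig.fisher_rao_normal_distance((0.3, 0.9), (0.3, 0.9)) == 0.0

    def test_small_separation_equal_sigma_limit(self):
        sigma = 0.5
        dmu = sigma / 100
        d = ig.fisher_rao_normal_distance((0.0, sigma), (dmu, sigma), n_obs=25)
        assert d == pytest.approx(np.sqrt(25) * dmu / sigma, rel=1e-3)

    def test_plug_in_squared_value(self):
        d2 = ig.fisher_rao_normal_distance((0.5050, 0.4846), (0.6, 1.0), n_obs=10) ** 2
        assert d2 == pytest.approx(10.666, abs=1e-3)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ig.fisher_rao_normal_distance((0.0, -0.1), (0.0, 1.0))


class TestCurveLength:
    def test_euclidean_straight_segment(self):
        field = ig.MetricField.euclidean(2)
        pts = np.array([[0.0, 0.0], [0.6, 0.8]])
        assert ig.curve_length(field, pts) == pytest.approx(1.0)

    def test_consistent_with_geodesic_length(self, normal_metric_n10):
        path = ig.geodesic_ivp(normal_metric_n10, [0.7, 0.5], [1.0, 0.5], 1.0, n_samples=801)
        assert ig.curve_length(normal_metric_n10, path.positions) == pytest.approx(
            path.length, abs=1e-6
        )

    def test_second_order_convergence(self):
        # quadrature error drops ~4x when the sample count doubles;
        # analytic case: quarter unit circle under the Euclidean metric
        field = ig.MetricField.euclidean(2)
        exact = np.pi / 2.0
        err = []
        for k in (32, 64, 128):
            phi = np.linspace(0.0, np.pi / 2.0, k + 1)
            pts = np.column_stack([np.cos(phi), np.sin(phi)])
            err.append(abs(ig.curve_length(field, pts) - exact))
        assert err[0] / err[1] == pytest.approx(4.0, rel=0.15)
        assert err[1] / err[2] == pytest.approx(4.0, rel=0.15)


class TestCurvature:
    @pytest.mark.parametrize("n_obs,point", [(1, (0.7, 0.5)), (1, (1.2, 0.9)), (10, (0.7, 0.5))])
    def test_normal_manifold_constant_negative_curvature(self, n_obs, point):
        field = ig.MetricField.normal(n_obs)
        sc = ig.scalar_curvature(field, np.array(point))
        assert abs(sc + 1.0 / n_obs) < 1e-3

    def test_flat_for_mvn_means_and_linear_model(self):
        mvn = ig.get_model("mvnormal", free=("mu1", "mu2"))
        f1 = ig.fisher_metric_field(mvn, [0.0], [10], ig.NoiseModel(sigma=0.3))
        lin = ig.get_model("linear", free=("a", "C0"))
        f2 = ig.fisher_metric_field(lin, [0.1, 0.25, 0.5], 10, ig.NoiseModel(sigma=0.2301))
        assert abs(ig.scalar_curvature(f1, [0.8, 1.2])) < 1e-6
        assert abs(ig.scalar_curvature(f2, [0.9, 0.7])) < 1e-6

    def test_ricci_symmetric_riemann_antisymmetric(self, normal_metric_n10):
        R = ig.riemann_tensor(normal_metric_n10, [0.7, 0.5])
        ric = ig.ricci(R)
        assert np.allclose(ric, ric.T, atol=1e-6)
        assert np.abs(R + np.swapaxes(R, 2, 3)).max() < 1e-5  # last-two antisymmetry

    def test_reparametrization_invariance_logistic(self):
        # Sc in (r, C0) equals Sc in (log r, C0) at corresponding points
        model = ig.get_model("logistic", free=("r", "C0"))
        base = ig.fisher_metric_field(model, [2.74, 6.84, 10.95], 10, ig.NoiseModel(sigma=2.301))

        def g_log(u):
            r = np.exp(u[0])
            J = np.diag([r, 1.0])
            return J @ base.g(np.array([r, u[1]])) @ J

        logf = ig.MetricField.from_function(g_log, 2, bounds=[(-np.inf, np.inf), (1e-6, np.inf)])
        r, c0 = 0.9, 0.2
        s1 = ig.scalar_curvature(base, np.array([r, c0]))
        s2 = ig.scalar_curvature(logf, np.array([np.log(r), c0]))
        assert abs(s1 - s2) / abs(s1) < 1e-3

    def test_curvature_map_marks_failures(self):
        model = ig.get_model("logistic", free=("r", "K"), fixed={"C0": 10.0})
        field = ig.fisher_metric_field(model, [2.74, 6.84, 10.95], 10, ig.NoiseModel(sigma=2.301))
        # includes the singular line K ~ C0
        cmap = ig.curvature_map(field, ((0.5, 1.2), (9.9, 20.0)), resolution=4)
        assert cmap.values.shape == (4, 4)
        assert np.isnan(cmap.values).sum() == cmap.n_failed

    def test_sir_beta_gamma_positive_curvature(self):
        model = ig.get_model("sir", free=("beta", "gamma"))
        field = ig.fisher_metric_field(model, [4.0, 7.0, 10.0], 10, ig.NoiseModel(sigma=0.05))
        for pt in [(1.6633, 0.44036), (1.9, 0.5)]:
            assert ig.scalar_curvature(field, np.array(pt)) > 0


class TestAsymptoticIdentity:
    def test_mvn_means_lr_equals_squared_distance_exactly(self):
        # quadratic log-likelihood: 2(l(mle) - l(theta)) == d(mle, theta)^2
        from infogeom.hypothesis_tests import lr_statistic_mvn_means

        model = ig.get_model("mvnormal", free=("mu1", "mu2"))
        field = ig.fisher_metric_field(model, [0.0], [10], ig.NoiseModel(sigma=0.3))
        mle, theta = np.array([0.71, 1.15]), np.array([0.8, 1.0])
        lam = lr_statistic_mvn_means(mle, theta, 0.3, 10)
        d = ig.geodesic_bvp(field, mle, theta).length
        assert lam == pytest.approx(d**2, abs=1e-6)

    @pytest.mark.parametrize("n_obs", [10, 100, 1000])
    def test_univariate_gap_shrinks_with_n(self, n_obs):
        from infogeom.hypothesis_tests import lr_statistic_normal

        mh, sh = 0.7 + 0.5 / np.sqrt(n_obs), 0.5 * (1 - 0.5 / np.sqrt(n_obs))
        lam_lr = lr_statistic_normal((mh, sh), (0.7, 0.5), n_obs)
        lam_gd = ig.fisher_rao_normal_distance((mh, sh), (0.7, 0.5), n_obs) ** 2
        rel_gap = abs(lam_lr - lam_gd) / lam_lr
        # ~0.156 at N=10, ~0.046 at N=100, ~0.014 at N=1000
        assert rel_gap < 2.0 / np.sqrt(n_obs)
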