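"""Regression assembly, elastic net, lambda path, simulation scoring."""

import numpy as np
import pytest
from scipy.linalg import expm

from hmfnet import synthetic
from hmfnet.containers import Profile, ProfileSet
from hmfnet.identify import (
    build_m_sets,
    build_regression_system,
    elastic_net_solve,
    grid_search_identify,
    lambda_max,
    lambda_path,
    simulate_and_score,
    simulate_linear,
)


def _profiles_from_truth(K, E0, times, labels=None, scale=False):
    """Exact trajectories packed into a scaled ProfileSet (strain 'd')."""
    times = np.asarray(times, dtype=float)
    traj = np.stack([expm(K * (t - times[0])) @ E0 for t in times], axis=1)
    n = K.shape[0]
    labels = labels or [("o1", f"g{i:02d}") for i in range(n)]
    ps = ProfileSet()
    for i, (o, g) in enumerate(labels):
        v = traj[i]
        s = (v - v.min()) / (v.max() - v.min()) if scale else v
        ps.add(Profile("d", o, g, times, v, scaled=s))
    return ps


class TestBuildMSets:
    def test_full_study_geometry_minimal_and_maximal_sets(self):
        m_sets = build_m_sets(110)
        assert len(m_sets) == 10
        assert len(m_sets[0]) == 111  # M_min = 55
        assert len(m_sets[-1]) == 221  # M = 110

    def test_small_network_formula(self):
        m_sets = build_m_sets(4, n_grid=1)
        assert m_sets[0] == [-2, -1, 0, 1, 2]

    def test_m_max_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            build_m_sets(10, M_max=3)


class TestBuildRegressionSystem:
    def test_dimension_bookkeeping_two_nodes(self):
        rng = np.random.default_rng(0)
        ps = ProfileSet()
        t = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
        for g in ("g1", "g2"):
            v = rng.uniform(size=5)
            ps.add(Profile("d", "o", g, t, v, scaled=v))
        system = build_regression_system(ps, "d", [-2, -1, 0, 1, 2])
        assert system.X_block.shape == (5, 2)
        assert system.full_X().shape == (10, 4)
        assert system.full_y().shape == (10,)
        # off-block entries are structural zeros
        assert np.all(system.full_X()[:5, 2:] == 0.0)

    def test_underdetermined_block_rejected(self):
        rng = np.random.default_rng(1)
        ps = ProfileSet()
        t = np.array([0.0, 6.0, 12.0])
        for g in ("g1", "g2", "g3"):
            v = rng.uniform(size=3)
            ps.add(Profile("d", "o", g, t, v, scaled=v))
        with pytest.raises(ValueError, match="underdetermined"):
            build_regression_system(ps, "d", [0, 1])

    def test_sinusoid_column_matches_analytic_hartley_integral(self):
        # For E = sin(w0 t), H(w) = int sin(w0 t) cas(w t) dt has the
        # closed form T/2 at w = +/- w0 and the integral is evaluated here
        # numerically for the piecewise-linear interpolant instead.
        t = np.linspace(0.0, 12.0, 481)
        w0 = 2.0 * np.pi / 12.0
        v = np.sin(w0 * t)
        ps = ProfileSet([Profile("d", "o", "g", t, v, scaled=v)])
        system = build_regression_system(ps, "d", [-1, 0, 1])
        # Hbar(m=0) = H((1+0-0) w0) - H((1+0-1) w0 -> eps) = T/2 - ~0
        assert system.X_block[1, 0] == pytest.approx(6.0, abs=1e-2)


class TestElasticNet:
    @pytest.fixture()
    def system(self):
        K = np.array([[-0.4, 0.2], [0.0, -0.3]])
        E0 = np.array([1.5, -0.8])
        return build_regression_system(
            _profiles_from_truth(K, E0, np.linspace(0.0, 12.0, 60)), "d", [-2, -1, 0, 1, 2]
        )

    def test_lambda_max_gives_empty_network(self, system):
        lam, _ = lambda_max(system, alpha=0.5)
        K = elastic_net_solve(system, lam, 0.5)
        assert np.all(K == 0.0)

    def test_lambda_max_matches_bisection_oracle(self, system):
        lam, _ = lambda_max(system, alpha=1.0)
        lo, hi = 1e-8, lam * 4.0
        for _ in range(60):  # bisection on "smallest lambda giving K = 0"
            mid = 0.5 * (lo + hi)
            if np.all(elastic_net_solve(system, mid, 1.0) == 0.0):
                hi = mid
            else:
                lo = mid
        assert lam == pytest.approx(hi, rel=5e-3)

    def test_unpenalized_recovers_exact_coefficients(self, system):
        # lam=0 with a consistent, well-conditioned system: exact solve
        beta, *_ = np.linalg.lstsq(system.X_block, system.Y, rcond=None)
        K = elastic_net_solve(system, 0.0, 0.5)
        assert np.allclose(K, beta.T, atol=1e-10)

    def test_univariate_lasso_soft_threshold_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        y = 0.7 * x + rng.normal(0, 0.1, 8)
        ps = ProfileSet([Profile("d", "o", "g", np.arange(8.0), y, scaled=y)])
        system = build_regression_system(ps, "d", list(range(-3, 4)))
        system.X_block = x.reshape(-1, 1)[:7]
        system.Y = y.reshape(-1, 1)[:7]
        lam = 0.3
        K = elastic_net_solve(system, lam, 1.0)
        xy = float(system.X_block[:, 0] @ system.Y[:, 0])
        xx = float(system.X_block[:, 0] @ system.X_block[:, 0])
        expected = np.sign(xy) * max(abs(xy) - lam / 2.0, 0.0) / xx
        assert K[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_block_separability(self, system):
        # solving the materialized global system equals per-block solves
        lam = 1e-3
        K = elastic_net_solve(system, lam, 0.0)
        Xf, yf = system.full_X(), system.full_y()
        beta_global = np.linalg.solve(Xf.T @ Xf + lam * np.eye(Xf.shape[1]), Xf.T @ yf)
        assert np.allclose(K.ravel(), beta_global, atol=1e-8)

    def test_invalid_parameters_rejected(self, system):
        with pytest.raises(ValueError):
            elastic_net_solve(system, -1.0, 0.5)
        with pytest.raises(ValueError):
            elastic_net_solve(system, 1.0, 1.5)

    def test_lambda_path_log_spacing_over_four_decades(self, system):
        path = lambda_path(system, alpha=0.4, n_lambda=10)
        ratios = np.diff(np.log10(path))
        assert np.allclose(ratios, ratios[0])
        assert np.log10(path[-1] / path[0]) == pytest.approx(4.0)


class TestSimulationScore:
    def test_perfect_fit_scores_zero(self):
        K = np.array([[-0.5]])
        t = np.array([0.0, 2.0, 5.0])
        traj = np.exp(-0.5 * t)
        ps = ProfileSet([Profile("d", "o", "g", t, traj, scaled=traj)])
        j, _ = simulate_and_score(K, ps, "d")
        assert j == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_two_node_case(self):
        # Node 1 holds at 1 (matching its data), node 2 ramps 0 -> 1 while
        # its data stay 0: contribution 1 / (Var(0,1) + eps) ~ 2.0.
        K = np.array([[0.0, 0.0], [1.0, 0.0]])
        t = np.array([0.0, 1.0])
        ps = ProfileSet(
            [
                Profile("d", "o", "g1", t, np.array([1.0, 1.0]), scaled=np.array([1.0, 1.0])),
                Profile("d", "o", "g2", t, np.array([0.0, 0.0]), scaled=np.array([0.0, 0.0])),
            ]
        )
        j, _ = simulate_and_score(K, ps, "d")
        assert j == pytest.approx(2.0, rel=1e-6)

    def test_all_zero_model_astronomically_penalized(self):
        rng = np.random.default_rng(3)
        t = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
        ps = ProfileSet()
        for g in ("g1", "g2"):
            v = rng.uniform(0.1, 1.0, size=5)
            ps.add(Profile("d", "o", g, t, v, scaled=v))
        j, _ = simulate_and_score(np.zeros((2, 2)), ps, "d")
        # constant simulation has Var = 0: only eps=1e-10 in the denominator
        assert j > 1e6

    def test_divergent_simulation_flagged_infinite(self):
        K = np.array([[5.0]])
        t = np.array([0.0, 5.0, 12.0])
        v = np.array([1.0, 0.5, 0.2])
        ps = ProfileSet([Profile("d", "o", "g", t, v, scaled=v)])
        j, _ = simulate_and_score(K, ps, "d")
        assert np.isinf(j)

    def test_simulate_linear_matches_expm_oracle(self):
        rng = np.random.default_rng(4)
        K = rng.normal(0, 0.3, (4, 4))
        K -= np.eye(4)
        E0 = rng.normal(size=4)
        t = np.array([0.0, 1.5, 4.0, 9.0])
        traj = simulate_linear(K, E0, t)
        for i, ti in enumerate(t):
            assert np.allclose(traj[:, i], expm(K * ti) @ E0, atol=1e-10)


class TestGridSearch:
    def test_grid_size_matches_full_design(self):
        # 10 m-sets x 6 alphas x 10 lambdas = 600 candidate fits
        m_sets = build_m_sets(110)
        assert len(m_sets) * 6 * 10 == 600

    def test_best_fit_beats_null_on_six_node_network(self):
        truth = synthetic.generate_network(2, 3, density=0.15, seed=8)
        ps = _profiles_from_truth(
            truth.K_true, np.abs(truth.E0) + 0.3, [4.0, 6.0, 8.0, 12.0, 16.0],
            labels=truth.node_labels, scale=True,
        )
        model, table, fits = grid_search_identify(
            ps, "d", alpha_grid=(0.2, 1.0), n_lambda=5, n_m_sets=2
        )
        j_null, _ = simulate_and_score(np.zeros_like(model.K), ps, "d")
        assert model.meta["J_sim"] < j_null
        assert len(table) == len(fits)

    def test_self_consistency_dense_noise_free_recovery(self):
        # Densely sampled exact trajectories: small-lambda fits recover the
        # support with 100% sign agreement (the method's self-consistency).
        truth = synthetic.generate_network(2, 3, density=0.2, seed=3)
        ps = _profiles_from_truth(
            truth.K_true, truth.E0, np.linspace(4.0, 16.0, 200),
            labels=truth.node_labels,
        )
        system = build_regression_system(ps, "d", build_m_sets(6, n_grid=1)[0])
        lam = 1e-6 * lambda_max(system, 1.0)[0]
        K = elastic_net_solve(system, lam, 1.0)
        sup = truth.K_true != 0
        assert np.all(np.sign(K[sup]) == np.sign(truth.K_true[sup]))

    def test_subset_restriction_shrinks_system(self):
        truth = synthetic.generate_network(2, 3, density=0.1, seed=6)
        ps = _profiles_from_truth(
            truth.K_true, truth.E0, [4.0, 6.0, 8.0, 12.0, 16.0],
            labels=truth.node_labels, scale=True,
        )
        model, _, _ = grid_search_identify(
            ps, "d", alpha_grid=(0.5,), n_lambda=3, n_m_sets=1,
            organs=["adrenal"], genes=["gene01", "gene02"],
        )
        assert model.K.shape == (2, 2)
        assert model.node_labels == [("adrenal", "gene01"), ("adrenal", "gene02")]

    def test_empty_grid_rejected(self):
        ps = ProfileSet([Profile("d", "o", "g", [0.0, 1.0], [0.0, 1.0], scaled=[0.0, 1.0])])
        with pytest.raises(ValueError):
            grid_search_identify(ps, "d", alpha_grid=())
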