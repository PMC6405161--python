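import numpy as np
import pytest

from ictalnet import (
    Connectome,
    ExcitabilityMap,
    ModelParams,
    build_jacobian,
    eigen_analysis,
    max_lyapunov,
    network_fixed_point,
    predict_pz,
    single_node_oscillation_threshold,
    uncoupled_fixed_point,
)
from ictalnet.errors import ConvergenceError
from ictalnet.epileptor import FixedPoint

from conftest import random_connectome


def single_node_spectrum(x_bar, params=ModelParams()):
    """Closed-form 2x2 spectrum of an isolated node at its fixed point."""
    a = -3.0 * x_bar**2 - 4.0 * x_bar
    block = np.array([[a, -1.0], [4.0 / params.tau, -1.0 / params.tau]])
    return np.linalg.eigvals(block)


def numerical_jacobian(c, ex, params, y, h=1e-6):
    """Central finite differences of the vector field at state y."""
    n = c.n
    K, s = c.weights, c.weights.sum(1)

    def f(y):
        x, z = y[:n], y[n:]
        dx = -(x**3) - 2 * x**2 + 1 - z + params.I_ext
        dz = (4 * (x - ex.x0) - z - (K @ x - s * x)) / params.tau
        return np.concatenate((dx, dz))

    J = np.empty((2 * n, 2 * n))
    for k in range(2 * n):
        e = np.zeros(2 * n)
        e[k] = h
        J[:, k] = (f(y + e) - f(y - e)) / (2 * h)
    return J


class TestJacobian:
    def test_single_node_closed_form(self):
        # x0 = -3.025 puts the fixed point exactly at x = -2
        params = ModelParams()
        c = Connectome(np.zeros((1, 1)))
        ex = ExcitabilityMap(np.array([-3.025]))
        fp = network_fixed_point(c, ex, params)
        J = build_jacobian(c, fp, params).entries
        expect = np.array(
            [[-4.0, -1.0], [4.0 / params.tau, -1.0 / params.tau]]
        )
        np.testing.assert_allclose(J, expect, atol=1e-9)

    def test_coupling_entry_scaling(self):
        params = ModelParams()
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        c = Connectome(w)
        ex = ExcitabilityMap.from_ez(3, [])
        fp = network_fixed_point(c, ex, params)
        J = build_jacobian(c, fp, params).entries
        # z-row off-diagonal is -K_ij / tau
        assert J[3, 1] == pytest.approx(-0.5 / params.tau)
        assert J[4, 0] == pytest.approx(-0.5 / params.tau)
        assert J[5, 0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_differences(self, seed, params):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        c = random_connectome(n, seed=seed)
        ez = [int(rng.integers(0, n))]
        ex = ExcitabilityMap.from_ez(n, ez)
        fp = network_fixed_point(c, ex, params)
        J = build_jacobian(c, fp, params).entries
        y = np.concatenate((fp.x_bar, fp.z_bar))
        J_fd = numerical_jacobian(c, ex, params, y)
        scale = np.abs(J).max()
        assert np.abs(J - J_fd).max() / scale < 1e-6

    def test_unconverged_fixed_point_rejected(self, params):
        c = Connectome(np.zeros((2, 2)))
        fp = FixedPoint(
            np.zeros(2), np.zeros(2), residual_norm=1.0, converged=False, iterations=0
        )
        with pytest.raises(ConvergenceError):
            build_jacobian(c, fp, params)


class TestEigenAnalysis:
    def test_decoupled_spectrum_is_union_of_blocks(self, params):
        x0 = np.array([-2.2, -1.6, -2.5, -2.15])
        c = Connectome(np.zeros((4, 4)))
        ex = ExcitabilityMap(x0)
        fp = network_fixed_point(c, ex, params)
        rep = eigen_analysis(build_jacobian(c, fp, params))
        expect = np.concatenate(
            [single_node_spectrum(xb, params) for xb in fp.x_bar]
        )
        got = np.sort_complex(rep.eigenvalues)
        np.testing.assert_allclose(np.sort_complex(expect), got, atol=1e-10)

    def test_all_healthy_has_no_positive_eigenvalues(self, params):
        c = Connectome(np.zeros((5, 5)))
        ex = ExcitabilityMap.from_ez(5, [])
        fp = network_fixed_point(c, ex, params)
        rep = eigen_analysis(build_jacobian(c, fp, params))
        assert rep.n_positive == 0

    def test_one_uncoupled_ez_gives_two_positive(self, params):
        c = Connectome(np.zeros((5, 5)))
        ex = ExcitabilityMap.from_ez(5, [3])
        fp = network_fixed_point(c, ex, params)
        rep = eigen_analysis(build_jacobian(c, fp, params))
        assert rep.n_positive == 2
        assert np.argmax(rep.node_scores) == 3

    def test_sorted_descending_real_part_and_unit_norm(self, params):
        c = random_connectome(6, seed=9)
        ex = ExcitabilityMap.from_ez(6, [0])
        fp = network_fixed_point(c, ex, params)
        rep = eigen_analysis(build_jacobian(c, fp, params))
        re = rep.eigenvalues.real
        assert np.all(np.diff(re) <= 1e-12)
        assert np.linalg.norm(rep.max_eigenvector) == pytest.approx(1.0)
        assert np.all(rep.node_scores >= 0)


class TestPredictPZ:
    def test_decoupled_ez_predicts_nothing(self, params):
        c = Connectome(np.zeros((4, 4)))
        ex = ExcitabilityMap.from_ez(4, [1])
        fp = network_fixed_point(c, ex, params)
        rep = eigen_analysis(build_jacobian(c, fp, params))
        assert predict_pz(rep, ex.ez) == []

    def test_planted_scenario_recovered_and_ranked(self, params):
        from ictalnet import generate_planted

        sc = generate_planted(30, 3, seed=17)
        ex = ExcitabilityMap.from_ez(30, sc.ez)
        fp = network_fixed_point(sc.connectome, ex, params)
        rep = eigen_analysis(build_jacobian(sc.connectome, fp, params))
        pz = predict_pz(rep, ex.ez)
        assert set(pz) == sc.planted_pz
        # ranked by descending planted weight
        assert pz == [j for _, j in sc.planted_edges]

    def test_relative_mode(self, params):
        c = random_connectome(5, seed=4)
        ex = ExcitabilityMap.from_ez(5, [0])
        fp = network_fixed_point(c, ex, params)
        rep = eigen_analysis(build_jacobian(c, fp, params))
        top = predict_pz(rep, ex.ez, eps_loc=0.999, mode="relative")
        assert len(top) >= 1  # the max non-EZ score always qualifies


class TestBifurcationThreshold:
    def test_matches_closed_form(self, params):
        closed = -4.0 / 3.0 + ((-4.0 / 3.0) ** 3 + 2 * (4.0 / 3.0) ** 2 - (1 + params.I_ext)) / 4.0
        numeric = single_node_oscillation_threshold(params)
        assert abs(numeric - closed) < 1e-3  # finite-tau correction is O(1/tau)


class TestLyapunov:
    def test_stable_system_exponent_equals_leading_eigenvalue(self, params):
        c = random_connectome(4, seed=2, density=0.8)
        ex = ExcitabilityMap.from_ez(4, [])
        fp = network_fixed_point(c, ex, params)
        rep = eigen_analysis(build_jacobian(c, fp, params))
        lam = float(rep.eigenvalues[0].real)
        assert lam < 0
        exponent, profile = max_lyapunov(c, ex, params, horizon=3.0 * params.tau)
        assert exponent == pytest.approx(lam, rel=0.05)
        assert profile.shape == (4,)

    def test_renormalization_interval_insensitive(self, params):
        c = random_connectome(3, seed=6, density=1.0)
        ex = ExcitabilityMap.from_ez(3, [])
        e1, _ = max_lyapunov(c, ex, params, horizon=2.0 * params.tau, renorm_interval=50.0)
        e2, _ = max_lyapunov(c, ex, params, horizon=2.0 * params.tau, renorm_interval=25.0)
        assert abs(e1 - e2) / abs(e1) < 0.01

    def test_planted_localization_matches_eigenvector_ranking(self, params, planted12, planted12_ex):
        c, ex = planted12.connectome, planted12_ex
        fp = network_fixed_point(c, ex, params)
        rep = eigen_analysis(build_jacobian(c, fp, params))
        _, profile = max_lyapunov(c, ex, params, horizon=1.0 * params.tau,
                                  discard_fraction=0.5)
        k = len(planted12.planted_pz) + 1  # EZ plus planted nodes
        top_eig = set(np.argsort(-rep.node_scores)[:k])
        top_lyap = set(np.argsort(-profile)[:k])
        assert top_eig == top_lyap
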