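import numpy as np
import pytest

from ictalnet import (
    Connectome,
    ExcitabilityMap,
    ModelParams,
    detect_seizure_events,
    healthy_reference_state,
    network_fixed_point,
    pz_from_signal_energy,
    recruited_set,
    simulate,
    uncoupled_fixed_point,
)
from ictalnet.epileptor import SeizureEvent, SeizureRaster, Trajectory
from ictalnet.errors import ValidationError

from conftest import random_connectome


class TestUncoupledFixedPoint:
    def test_exact_value_at_special_excitability(self):
        # x0 = -3.025 makes x = -2 an exact root; z = 4(x - x0) = 4.1
        x, z = uncoupled_fixed_point(-3.025)
        assert x[0] == pytest.approx(-2.0, abs=1e-12)
        assert z[0] == pytest.approx(4.1, abs=1e-12)

    def test_agrees_with_polynomial_root_oracle(self):
        # independent oracle: numpy companion-matrix roots of the cubic
        for x0 in (-2.2, -1.6, -2.5, -1.0):
            roots = np.roots([1.0, 2.0, 4.0, -(1.0 + 3.1 + 4.0 * x0)])
            real = roots[np.abs(roots.imag) < 1e-9].real
            assert real.size == 1  # monotone cubic: unique real root
            x, _ = uncoupled_fixed_point(x0)
            assert x[0] == pytest.approx(real[0], abs=1e-10)

    def test_z_consistent_with_x_nullcline(self):
        params = ModelParams()
        x, z = uncoupled_fixed_point(np.array([-2.2, -1.6, -3.0]), params)
        np.testing.assert_allclose(
            z, -(x**3) - 2 * x**2 + 1 + params.I_ext, atol=1e-12
        )


class TestNetworkFixedPoint:
    def test_decoupled_limit_matches_per_node_roots(self):
        c = Connectome(np.zeros((4, 4)))
        ex = ExcitabilityMap(np.array([-2.2, -1.6, -2.5, -2.1]))
        fp = network_fixed_point(c, ex)
        x_ref, z_ref = uncoupled_fixed_point(ex.x0)
        assert fp.converged
        np.testing.assert_allclose(fp.x_bar, x_ref, atol=1e-10)
        np.testing.assert_allclose(fp.z_bar, z_ref, atol=1e-10)

    def test_residual_small_on_random_network(self):
        c = random_connectome(10, seed=3)
        ex = ExcitabilityMap.from_ez(10, [2])
        fp = network_fixed_point(c, ex)
        assert fp.converged
        # plug back into the algebraic system
        K, s, x = c.weights, c.weights.sum(1), fp.x_bar
        g = 4 * (x - ex.x0) - fp.z_bar - (K @ x - s * x)
        assert np.abs(g).max() < 1e-10

    def test_all_healthy_planted_scenario_below_fold(self, planted12):
        c = planted12.connectome
        ex = ExcitabilityMap.from_ez(c.n, [])
        fp = network_fixed_point(c, ex)
        assert fp.converged
        assert np.all(fp.x_bar < -4.0 / 3.0)


class TestSimulate:
    def test_equilibrium_is_invariant(self):
        c = random_connectome(6, seed=1)
        ex = ExcitabilityMap.from_ez(6, [])  # all healthy
        x, z = healthy_reference_state(c, ex)
        traj = simulate(c, ex, init=(x, z), horizon=2000.0, dt_out=10.0)
        assert np.abs(traj.x - x).max() < 1e-6
        assert np.abs(traj.z - z).max() < 1e-6

    def test_single_uncoupled_ez_oscillates(self):
        c = Connectome(np.zeros((1, 1)))
        ex = ExcitabilityMap(np.array([-1.6]))
        traj = simulate(c, ex, horizon=3 * 2857.0, dt_out=2.0)
        raster = detect_seizure_events(traj)
        assert len(raster.events) >= 2  # recurrent relaxation oscillations
        # inter-seizure interval is on the slow timescale O(tau)
        gaps = np.diff([e.onset for e in raster.events])
        assert np.all(gaps > 0.1 * 2857) and np.all(gaps < 3 * 2857)

    def test_no_events_elsewhere_when_decoupled(self):
        c = Connectome(np.zeros((3, 3)))
        ex = ExcitabilityMap(np.array([-1.6, -2.2, -2.2]))
        traj = simulate(c, ex, horizon=3 * 2857.0, dt_out=2.0)
        raster = detect_seizure_events(traj)
        rec = recruited_set(raster, {0})
        assert rec.nodes == frozenset()
        assert any(e.node == 0 for e in raster.events)

    def test_deterministic(self, planted12, planted12_ex):
        t1 = simulate(planted12.connectome, planted12_ex, horizon=500.0)
        t2 = simulate(planted12.connectome, planted12_ex, horizon=500.0)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.z, t2.z)

    def test_rk4_cross_check_agrees_with_lsoda(self):
        c = Connectome(np.zeros((1, 1)))
        ex = ExcitabilityMap(np.array([-2.2]))
        x0, z0 = np.array([-1.3]), np.array([2.8])
        a = simulate(c, ex, init=(x0, z0), horizon=300.0, dt_out=50.0)
        b = simulate(c, ex, init=(x0, z0), horizon=300.0, dt_out=50.0, method="rk4")
        np.testing.assert_allclose(a.x, b.x, atol=1e-5)

    def test_invalid_horizon_rejected(self, planted12, planted12_ex):
        with pytest.raises(ValidationError):
            simulate(planted12.connectome, planted12_ex, horizon=-1.0)


class TestEventDetection:
    @staticmethod
    def _traj(t, x):
        x = np.asarray(x, dtype=float)[:, None]
        return Trajectory(np.asarray(t, dtype=float), x, np.zeros_like(x))

    def test_constant_below_threshold_gives_no_events(self):
        traj = self._traj(np.arange(100.0), np.full(100, -2.0))
        raster = detect_seizure_events(traj)
        assert raster.events == ()

    def test_square_wave_gives_two_events_with_known_onsets(self):
        t = np.arange(0.0, 100.0)
        x = np.full(100, -2.0)
        x[10:30] = 0.5
        x[60:80] = 0.5
        raster = detect_seizure_events(self._traj(t, x))
        assert len(raster.events) == 2
        on1, on2 = raster.events[0].onset, raster.events[1].onset
        assert 9.0 <= on1 <= 10.0 and 59.0 <= on2 <= 60.0

    def test_short_blips_discarded(self):
        t = np.arange(0.0, 50.0)
        x = np.full(50, -2.0)
        x[10:12] = 0.5  # 2 time units < min_duration=5
        raster = detect_seizure_events(self._traj(t, x))
        assert raster.events == ()

    def test_threshold_ordering_enforced(self):
        traj = self._traj(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValidationError):
            detect_seizure_events(traj, theta_on=-1.0, theta_off=0.0)

    def test_recruited_ordering_by_onset(self):
        raster = SeizureRaster(
            (
                SeizureEvent(2, 10.0, 50.0),
                SeizureEvent(0, 12.0, 60.0),
                SeizureEvent(1, 15.0, 55.0),
            ),
            horizon=100.0,
        )
        rec = recruited_set(raster, ez={2})
        assert rec.nodes == frozenset({0, 1})
        assert rec.onset_order == (0, 1)


class TestSignalEnergyPZ:
    @staticmethod
    def _signals(amplitudes, fs=512.0, seconds=2.0):
        t = np.arange(0, seconds, 1.0 / fs)
        return np.array([a * np.sin(2 * np.pi * 10.0 * t) for a in amplitudes])

    def test_thirty_percent_rule(self):
        # energies scale with amplitude^2: {1.0, 0.4, 0.2} relative
        sig = self._signals([1.0, np.sqrt(0.4), np.sqrt(0.2)])
        pz = pz_from_signal_energy(sig, fs=512.0, ez_channels={0})
        assert pz == frozenset({1})

    def test_boundary_energy_included(self):
        sig = self._signals([1.0, np.sqrt(0.3)])
        pz = pz_from_signal_energy(sig, fs=512.0, ez_channels={0})
        assert pz == frozenset({1})  # "at least 30%" is inclusive

    def test_all_channels_in_ez_gives_empty(self):
        sig = self._signals([1.0, 0.9])
        assert pz_from_signal_energy(sig, fs=512.0, ez_channels={0, 1}) == frozenset()

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValidationError):
            pz_from_signal_energy(np.zeros((2, 100)), fs=80.0, ez_channels=set())

    def test_out_of_band_signal_filtered_away(self):
        fs = 512.0
        t = np.arange(0, 2.0, 1.0 / fs)
        in_band = np.sin(2 * np.pi * 10.0 * t)
        dc_drift = 0.9 * np.ones_like(t)  # below the 1 Hz band edge
        pz = pz_from_signal_energy(
            np.array([in_band, dc_drift]), fs=fs, ez_channels=set()
        )
        assert pz == frozenset({0})
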