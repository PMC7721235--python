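"""Forward model: transfer function, drift, integration, hemodynamics, metastability."""

import numpy as np
import pytest

from braindyn.connectome import BOLDSeries, StructuralConnectome, default_labels
from braindyn.errors import InvalidArgumentError
from braindyn.model import (
    HemodynamicConstants,
    NeuralKinetics,
    RMFMParameters,
    SimulationConfig,
    balloon_windkessel,
    drift_jacobian,
    find_stable_fixed_point,
    hemodynamic_steady_state,
    integrate_neural,
    kuramoto_metastability,
    linearized_gating_correlation,
    neural_drift,
    simulate_fc,
    transfer_function,
)

KIN = NeuralKinetics.default()


class TestTransferFunction:
    def test_removable_singularity_equals_inverse_curvature(self):
        assert transfer_function(KIN.b / KIN.a) == pytest.approx(1.0 / KIN.d,
                                                                 rel=1e-9)

    def test_linear_asymptote_for_large_input(self):
        x = 10.0
        u = KIN.a * x - KIN.b
        assert transfer_function(x) / u == pytest.approx(1.0, rel=1e-12)

    def test_value_at_zero_matches_closed_form(self):
        expected = (-KIN.b) / (1.0 - np.exp(KIN.d * KIN.b))
        assert transfer_function(0.0) == pytest.approx(expected, rel=1e-12)

    def test_positive_and_continuous_across_the_singularity(self):
        xs = KIN.b / KIN.a + np.linspace(-1e-6, 1e-6, 101)
        vals = transfer_function(xs)
        assert np.all(vals > 0)
        assert np.max(np.abs(np.diff(vals))) < 1e-4


class TestNeuralDrift:
    def test_zero_state_leaves_only_gain_term(self, small_sc):
        n = small_sc.n_regions
        p = RMFMParameters(w=np.full(n, 0.5), I=np.zeros(n), G=0.3, sigma=0.0)
        drift = neural_drift(np.zeros(n), small_sc, p)
        expected = KIN.gamma_kinetic * transfer_function(0.0)
        np.testing.assert_allclose(drift, expected, rtol=1e-12)

    def test_saturated_state_decays_at_leak_rate(self, small_sc):
        n = small_sc.n_regions
        p = RMFMParameters(w=np.full(n, 0.5), I=np.full(n, 0.3), G=0.3, sigma=0.0)
        drift = neural_drift(np.ones(n), small_sc, p)
        np.testing.assert_allclose(drift, -1.0 / KIN.tau_s, rtol=1e-12)

    def test_identical_regions_get_identical_drift(self):
        sc = StructuralConnectome(np.array([[0.0, 1.0], [1.0, 0.0]]),
                                  default_labels(2), normalized=True)
        p = RMFMParameters(w=[0.5, 0.5], I=[0.3, 0.3], G=0.4, sigma=0.0)
        drift = neural_drift(np.array([0.1, 0.1]), sc, p)
        assert drift[0] == pytest.approx(drift[1], rel=1e-14)

    def test_decoupled_drift_ignores_other_regions(self, small_sc, small_params):
        from dataclasses import replace
        n = small_sc.n_regions
        rng = np.random.default_rng(0)
        S = rng.uniform(0.02, 0.2, n)
        p0 = RMFMParameters(w=small_params.w, I=small_params.I, G=0.0, sigma=0.0)
        d1 = neural_drift(S, small_sc, p0)
        S2 = S.copy()
        S2[1:] = rng.uniform(0.02, 0.2, n - 1)
        d2 = neural_drift(S2, small_sc, p0)
        assert d1[0] == pytest.approx(d2[0], rel=1e-14)


class TestIntegration:
    def test_deterministic_symmetric_network_reaches_common_fixed_point(self):
        n = 4
        W = np.ones((n, n)) - np.eye(n)
        sc = StructuralConnectome(W / W.max(), default_labels(n), normalized=True)
        p = RMFMParameters(w=np.full(n, 0.5), I=np.full(n, 0.3), G=0.2, sigma=0.0)
        cfg = SimulationConfig(dt=0.01, duration=60, burn_in=0, tr_out=1.0, seed=0)
        traj = integrate_neural(sc, p, config=cfg)
        final = traj.S[:, -1]
        assert np.ptp(final) < 1e-10
        assert np.abs(neural_drift(final, sc, p)).max() < 1e-6

    def test_noiseless_endpoint_matches_root_finder(self, small_sc, small_params):
        from dataclasses import replace
        p = RMFMParameters(w=small_params.w, I=small_params.I,
                           G=small_params.G, sigma=0.0)
        cfg = SimulationConfig(dt=0.01, duration=80, burn_in=0, tr_out=1.0, seed=0)
        traj = integrate_neural(small_sc, p, config=cfg)
        fixed = find_stable_fixed_point(small_sc, p)
        np.testing.assert_allclose(traj.S[:, -1], fixed, atol=1e-6)
        assert np.abs(neural_drift(traj.S[:, -1], small_sc, p)).max() < 1e-6

    def test_same_seed_reproduces_trajectory(self, small_sc, small_params, quick_sim):
        t1 = integrate_neural(small_sc, small_params, config=quick_sim)
        t2 = integrate_neural(small_sc, small_params, config=quick_sim)
        np.testing.assert_array_equal(t1.S, t2.S)

    def test_states_stay_in_unit_interval_with_few_clamps(
            self, small_sc, small_params, quick_sim):
        traj = integrate_neural(small_sc, small_params, config=quick_sim)
        assert traj.S.min() >= 0.0 and traj.S.max() <= 1.0
        assert traj.clamp_fraction < 1e-3


class TestBalloonWindkessel:
    def test_zero_drive_is_a_fixed_point_with_zero_bold(self):
        z = np.zeros((3, 500))
        bold = balloon_windkessel(z, dt=0.01)
        assert np.abs(bold.samples).max() < 1e-12

    def test_constant_drive_settles_at_algebraic_steady_state(self):
        drive = 0.05
        z = np.full((1, 60000), drive)
        bold = balloon_windkessel(z, dt=0.01)
        y_ss = hemodynamic_steady_state(drive)[4]
        assert bold.samples[0, -1] == pytest.approx(y_ss, rel=1e-4)

    def test_regions_are_independent_and_permutable(self):
        rng = np.random.default_rng(6)
        z = rng.random((4, 300)) * 0.05
        perm = np.array([2, 0, 3, 1])
        a = balloon_windkessel(z, dt=0.01).samples
        b = balloon_windkessel(z[perm], dt=0.01).samples
        np.testing.assert_array_equal(b, a[perm])

    def test_output_decimation_to_tr(self):
        z = np.zeros((2, 1000))
        bold = balloon_windkessel(z, dt=0.01, tr_out=0.5)
        assert bold.samples.shape[1] == 20
        assert bold.tr == pytest.approx(0.5)


class TestSimulateFC:
    def test_fc_is_valid_correlation_matrix(self, small_sc, small_params, quick_sim):
        fc = simulate_fc(small_sc, small_params, config=quick_sim)
        assert np.array_equal(fc.values, fc.values.T)
        assert np.array_equal(np.diag(fc.values), np.ones(small_sc.n_regions))
        assert np.abs(fc.values).max() <= 1.0

    def test_permuting_sc_and_noise_permutes_fc(self, small_sc, small_params,
                                                quick_sim):
        n = small_sc.n_regions
        rng = np.random.default_rng(8)
        perm = rng.permutation(n)
        noise = rng.standard_normal((quick_sim.n_steps, n)) * 1e-3
        fc = simulate_fc(small_sc, small_params, config=quick_sim,
                         noise=noise.copy()).values
        sc_p = StructuralConnectome(small_sc.weights[np.ix_(perm, perm)],
                                    [small_sc.region_labels[i] for i in perm],
                                    normalized=True)
        par_p = RMFMParameters(w=small_params.w[perm], I=small_params.I[perm],
                               G=small_params.G, sigma=small_params.sigma)
        fc_p = simulate_fc(sc_p, par_p, config=quick_sim,
                           noise=noise[:, perm].copy()).values
        np.testing.assert_allclose(fc_p, fc[np.ix_(perm, perm)], atol=1e-10)

    def test_seeded_determinism(self, small_sc, small_params, quick_sim):
        a = simulate_fc(small_sc, small_params, config=quick_sim).values
        b = simulate_fc(small_sc, small_params, config=quick_sim).values
        np.testing.assert_array_equal(a, b)

    def test_halving_dt_preserves_similarity_to_reference(self, small_sc,
                                                          small_params):
        from braindyn.estimation import similarity
        ref = simulate_fc(small_sc, small_params,
                          config=SimulationConfig(dt=0.01, duration=600,
                                                  burn_in=60, tr_out=1.0, seed=99))
        sims = []
        for dt in (0.02, 0.01):
            fc = simulate_fc(small_sc, small_params,
                             config=SimulationConfig(dt=dt, duration=300,
                                                     burn_in=30, tr_out=1.0,
                                                     seed=5))
            sims.append(similarity(fc, ref))
        assert abs(sims[0] - sims[1]) < 0.05

    def test_noiseless_trajectories_converge_as_dt_halves(self, small_sc,
                                                          small_params):
        p = RMFMParameters(w=small_params.w, I=small_params.I,
                           G=small_params.G, sigma=0.0)
        ends = []
        for dt in (0.02, 0.01):
            cfg = SimulationConfig(dt=dt, duration=40, burn_in=0, tr_out=2.0,
                                   seed=0)
            ends.append(integrate_neural(small_sc, p, config=cfg).S[:, -1])
        assert np.abs(ends[0] - ends[1]).max() < 1e-4


class TestLinearization:
    def test_jacobian_matches_finite_differences(self, small_sc, small_params):
        S = find_stable_fixed_point(small_sc, small_params)
        A = drift_jacobian(S, small_sc, small_params)
        eps = 1e-7
        for j in [0, 5, 11]:
            Sp = S.copy()
            Sp[j] += eps
            col = (neural_drift(Sp, small_sc, small_params)
                   - neural_drift(S, small_sc, small_params)) / eps
            np.testing.assert_allclose(A[:, j], col, rtol=1e-4, atol=1e-6)

    def test_linearized_correlation_is_valid_and_sigma_invariant(
            self, small_sc, small_params):
        C1, _ = linearized_gating_correlation(small_sc, small_params)
        p2 = RMFMParameters(w=small_params.w, I=small_params.I,
                            G=small_params.G, sigma=0.02)
        C2, _ = linearized_gating_correlation(small_sc, p2)
        np.testing.assert_allclose(np.diag(C1), 1.0, atol=1e-10)
        np.testing.assert_allclose(C1, C2, atol=1e-10)


class TestMetastability:
    def test_perfect_synchrony_has_zero_metastability(self):
        t = np.arange(0, 300, 2.0)
        x = np.sin(2 * np.pi * 0.03 * t)
        bold = BOLDSeries(np.tile(x, (5, 1)), tr=2.0)
        assert kuramoto_metastability(bold) == pytest.approx(0.0, abs=1e-8)

    def test_uniformly_spread_phases_cancel(self):
        t = np.arange(0, 600, 2.0)
        n = 8
        rows = [np.sin(2 * np.pi * 0.03 * t + 2 * np.pi * k / n) for k in range(n)]
        bold = BOLDSeries(np.array(rows), tr=2.0)
        assert kuramoto_metastability(bold) < 0.02

    def test_independent_noise_metastability_decreases_with_n(self):
        rng = np.random.default_rng(9)
        t_len = 400
        sds = []
        for n in (4, 64):
            vals = [kuramoto_metastability(
                BOLDSeries(rng.standard_normal((n, t_len)), tr=2.0))
                for _ in range(20)]
            sds.append(np.mean(vals))
        assert sds[1] < sds[0]

    def test_band_outside_nyquist_rejected(self):
        bold = BOLDSeries(np.random.default_rng(0).standard_normal((3, 100)), tr=2.0)
        with pytest.raises(InvalidArgumentError):
            kuramoto_metastability(bold, band=(0.01, 0.3))
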