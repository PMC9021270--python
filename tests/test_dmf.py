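"""Neural-mass core: transfer function, currents, integration, FIC tuning."""

import numpy as np
import pytest

import gabadmf as g
from gabadmf.dmf import DMFState, rates_from_currents


def single_region():
    return g.validate_connectome(np.zeros((1, 1)), ["R000"])


def ten_node(seed=3):
    spec = g.FixtureSpec(n_regions=10, seed=seed)
    return g.scale_for_simulation(g.synth_connectome(spec))


class TestTransferRate:
    def test_continuous_through_threshold(self):
        p = g.DMFParameters()
        eps = 1e-10
        lo = g.transfer_rate(p.I_thr_E - eps, p.g_E, p.I_thr_E, p.d_E)
        hi = g.transfer_rate(p.I_thr_E + eps, p.g_E, p.I_thr_E, p.d_E)
        at = g.transfer_rate(p.I_thr_E, p.g_E, p.I_thr_E, p.d_E)
        assert lo == pytest.approx(at, abs=1e-6)
        assert hi == pytest.approx(at, abs=1e-6)

    def test_monotone_and_nonnegative(self):
        p = g.DMFParameters()
        I = np.linspace(0.0, 1.0, 500)
        r = g.transfer_rate(I, p.g_E, p.I_thr_E, p.d_E)
        assert np.all(r >= 0)
        assert np.all(np.diff(r) > 0)

    def test_inhibitory_modulator_scales_gain(self):
        p = g.DMFParameters()
        r1 = g.transfer_rate(0.35, p.g_I, p.I_thr_I, p.d_I, 1.0)
        r2 = g.transfer_rate(0.35, p.g_I, p.I_thr_I, p.d_I, 1.5)
        # above threshold a larger modulator yields a larger rate
        assert r2 > r1

    def test_non_finite_input_rejected(self):
        p = g.DMFParameters()
        with pytest.raises(g.ValidationError):
            g.transfer_rate(np.nan, p.g_E, p.I_thr_E, p.d_E)


class TestGainVector:
    def test_zero_scaling_recovers_unit_gain(self, sphere_map):
        gv = g.gain_vector(sphere_map, 0.0)
        assert np.allclose(gv.values, 1.0)

    def test_elementwise_formula(self, sphere_map):
        gv = g.gain_vector(sphere_map, 0.52)
        assert np.allclose(gv.values, 1.0 + 0.52 * sphere_map.normalised)

    def test_monotone_in_scaling(self, sphere_map):
        lo = g.gain_vector(sphere_map, 0.2).values
        hi = g.gain_vector(sphere_map, 0.4).values
        pos = sphere_map.normalised > 0
        assert np.all(hi[pos] > lo[pos])


class TestCurrents:
    def test_rest_state_currents(self, scaled_sphere):
        n = scaled_sphere.n_regions
        p = g.DMFParameters(J_FIC=np.ones(n))
        state = DMFState(S_E=np.zeros(n), S_I=np.zeros(n))
        I_E, I_I = g.currents(state, p, scaled_sphere)
        assert np.allclose(I_E, 0.382)
        assert np.allclose(I_I, 0.2674)

    def test_zero_coupling_decouples(self, scaled_sphere):
        n = scaled_sphere.n_regions
        p = g.DMFParameters(G=0.0, J_FIC=np.zeros(n))
        rng = np.random.default_rng(0)
        S_E = rng.uniform(0, 1, n)
        state = DMFState(S_E=S_E, S_I=np.zeros(n))
        I_E, _ = g.currents(state, p, scaled_sphere)
        S_E2 = S_E.copy()
        S_E2[5] = 0.99  # perturbing region 5 must not touch other currents
        I_E2, _ = g.currents(DMFState(S_E=S_E2, S_I=np.zeros(n)), p, scaled_sphere)
        mask = np.arange(n) != 5
        assert np.allclose(I_E[mask], I_E2[mask])

    def test_fic_acts_locally_and_linearly(self, scaled_sphere):
        n = scaled_sphere.n_regions
        J = np.ones(n)
        S_I = np.full(n, 0.3)
        state = DMFState(S_E=np.zeros(n), S_I=S_I)
        p1 = g.DMFParameters(J_FIC=J)
        J2 = J.copy()
        J2[4] *= 2
        p2 = g.DMFParameters(J_FIC=J2)
        I1, _ = g.currents(state, p1, scaled_sphere)
        I2, _ = g.currents(state, p2, scaled_sphere)
        assert I2[4] - I1[4] == pytest.approx(-J[4] * S_I[4])
        mask = np.arange(n) != 4
        assert np.allclose(I1[mask], I2[mask])


class TestStep:
    def test_matches_compiled_kernel(self, scaled_sphere):
        """The reference NumPy step and the compiled integrator agree."""
        n = scaled_sphere.n_regions
        p = g.DMFParameters(G=1.2, sigma=0.0, J_FIC=np.full(n, 1.0))
        gain = g.gain_vector(None, 0.0, n_regions=n)
        state = DMFState(S_E=np.full(n, 0.1), S_I=np.full(n, 0.05))
        for _ in range(200):
            state = g.step(state, p, scaled_sphere, gain, dt_ms=0.25,
                           noise_draws=np.zeros((2, n)))
        trace = g.simulate(p, scaled_sphere, gain, duration_s=0.1, dt_ms=0.25,
                           burn_in_s=0.05, record_dt_ms=0.25, seed=0,
                           initial_state=DMFState(S_E=np.full(n, 0.1),
                                                  S_I=np.full(n, 0.05)))
        # 0.05 s at 0.25 ms = 200 steps of burn-in; first recorded rate is
        # the rate at the state reached by 200 reference steps
        I_E, I_I = g.currents(state, p, scaled_sphere)
        r_E, _ = rates_from_currents(I_E, I_I, p, gain)
        assert np.allclose(trace.rates[:, 0], r_E, rtol=1e-10)

    def test_linear_decay_limit(self):
        """With rates forced to zero, S_E decays with time constant tau_NMDA."""
        c = single_region()
        # current far below threshold => r_E ~ 0
        p = g.DMFParameters(I0=0.0, W_E=1.0, sigma=0.0, J_FIC=np.zeros(1))
        gain = g.gain_vector(None, 0.0, n_regions=1)
        state = DMFState(S_E=np.array([1.0]), S_I=np.array([0.0]))
        dt = 0.1
        for _ in range(1000):  # 100 ms = one tau
            state = g.step(state, p, c, gain, dt_ms=dt, noise_draws=np.zeros((2, 1)))
        assert state.S_E[0] == pytest.approx(np.exp(-1.0), rel=0.02)

    def test_gating_stays_bounded(self, scaled_sphere):
        n = scaled_sphere.n_regions
        p = g.DMFParameters(G=1.5, sigma=0.05, J_FIC=np.zeros(n))
        trace = g.simulate(p, scaled_sphere, duration_s=2.0, dt_ms=0.25,
                           burn_in_s=0.0, record_dt_ms=0.25, seed=3)
        assert np.all(trace.rates >= 0)
        assert np.all(np.isfinite(trace.rates))

    def test_bad_noise_shape_rejected(self, scaled_sphere):
        n = scaled_sphere.n_regions
        p = g.DMFParameters(J_FIC=np.zeros(n))
        state = DMFState(S_E=np.zeros(n), S_I=np.zeros(n))
        gain = g.gain_vector(None, 0.0, n_regions=n)
        with pytest.raises(g.ValidationError):
            g.step(state, p, scaled_sphere, gain, 0.1, np.zeros((2, n + 1)))


class TestSimulate:
    def test_seeded_determinism_and_seed_sensitivity(self, scaled_sphere):
        p = g.DMFParameters(G=1.0, J_FIC=np.ones(scaled_sphere.n_regions))
        a = g.simulate(p, scaled_sphere, duration_s=1.0, dt_ms=0.25,
                       burn_in_s=0.5, seed=11)
        b = g.simulate(p, scaled_sphere, duration_s=1.0, dt_ms=0.25,
                       burn_in_s=0.5, seed=11)
        c = g.simulate(p, scaled_sphere, duration_s=1.0, dt_ms=0.25,
                       burn_in_s=0.5, seed=12)
        assert np.array_equal(a.rates, b.rates)
        assert not np.array_equal(a.rates, c.rates)

    def test_duration_must_exceed_burn_in(self, scaled_sphere):
        p = g.DMFParameters(J_FIC=np.ones(scaled_sphere.n_regions))
        with pytest.raises(g.ValidationError):
            g.simulate(p, scaled_sphere, duration_s=5.0, burn_in_s=10.0)

    def test_dt_halving_converges(self):
        """Noise-free endpoint changes by <1e-3 when dt is halved."""
        c = ten_node()
        gain = g.gain_vector(None, 0.0, n_regions=10)
        res = g.tune_fic(g.DMFParameters(G=0.8, sigma=0.0), c, gain,
                         dt_ms=0.5, round_duration_s=4.0, seed=0)
        ends = []
        for dt in (0.5, 0.25):
            tr = g.simulate(res.params, c, gain, duration_s=10.0, dt_ms=dt,
                            burn_in_s=9.99, record_dt_ms=dt, seed=0)
            ends.append(tr.rates[:, -1])
        assert np.abs(ends[0] - ends[1]).max() < 1e-3

    def test_trace_io_roundtrip(self, tmp_path, scaled_sphere):
        from gabadmf.dmf import read_trace, write_trace
        p = g.DMFParameters(J_FIC=np.ones(scaled_sphere.n_regions))
        tr = g.simulate(p, scaled_sphere, duration_s=0.6, dt_ms=0.25,
                        burn_in_s=0.1, seed=0, record_dt_ms=1.0)
        path = tmp_path / "trace.tsv"
        write_trace(tr, path, seed=0)
        back = read_trace(path)
        assert back.dt_ms == tr.dt_ms
        assert np.allclose(back.rates, tr.rates, rtol=1e-6)


class TestTuneFIC:
    def test_single_region_settles_near_target(self):
        c = single_region()
        p = g.DMFParameters(G=0.0, sigma=0.0)
        res = g.tune_fic(p, c, round_duration_s=4.0, dt_ms=0.25, seed=0)
        tr = g.simulate(res.params, c, duration_s=10.0, dt_ms=0.25,
                        burn_in_s=5.0, seed=0)
        assert tr.rates.mean() == pytest.approx(3.0, abs=0.5)

    def test_identical_gains_give_identical_fic_at_zero_coupling(self):
        c = ten_node()
        res = g.tune_fic(g.DMFParameters(G=0.0), c, round_duration_s=4.0,
                         dt_ms=0.25, seed=2)
        assert np.allclose(res.params.J_FIC, res.params.J_FIC[0])

    def test_gain_modulation_shifts_converged_fic(self, sphere_map):
        """At the balanced state the inhibitory population sits below its
        F-I threshold, where a larger multiplicative gain lowers inhibitory
        output at fixed current; tuning therefore needs MORE feedback
        inhibition under a stronger gain map, and J_FIC shifts only where
        the map is non-zero."""
        c = ten_node()
        m = g.normalise_map(sphere_map.raw[:10], [f"R{i:03d}" for i in range(10)])
        j0 = g.tune_fic(g.DMFParameters(G=0.5), c, g.gain_vector(m, 0.0),
                        round_duration_s=4.0, dt_ms=0.25, seed=2).params.J_FIC
        j5 = g.tune_fic(g.DMFParameters(G=0.5), c, g.gain_vector(m, 0.5),
                        round_duration_s=4.0, dt_ms=0.25, seed=2).params.J_FIC
        pos = m.normalised > 0
        assert np.all(j5[pos] >= j0[pos] - 1e-9)
        assert np.any(j5[pos] > j0[pos] + 1e-6)

    def test_gain_raises_stationary_rate_before_retuning(self, sphere_map):
        """Applying the gain map without re-balancing shifts mean activity
        upward: the subthreshold inhibitory populations fire less when
        their formal gain grows, disinhibiting the excitatory populations."""
        c = ten_node()
        m = g.normalise_map(sphere_map.raw[:10], [f"R{i:03d}" for i in range(10)])
        res = g.tune_fic(g.DMFParameters(G=0.5), c, g.gain_vector(m, 0.0),
                         round_duration_s=4.0, dt_ms=0.25, seed=2)
        r0 = g.simulate(res.params, c, g.gain_vector(m, 0.0), duration_s=20.0,
                        dt_ms=0.25, burn_in_s=5.0, seed=5).rates.mean()
        r5 = g.simulate(res.params, c, g.gain_vector(m, 0.5), duration_s=20.0,
                        dt_ms=0.25, burn_in_s=5.0, seed=5).rates.mean()
        assert r5 > r0
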