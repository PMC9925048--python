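import numpy as np
import pytest
from scipy.signal import lfilter

from ornmotif import ornmap
from ornmotif.ornmap import (
    DelayedAux,
    MapNeuronState,
    MotifParams,
    NoiseParams,
    couple_inputs,
    default_params,
    input_current_trace,
    map_f,
    params_from_yaml,
    params_to_yaml,
    shape_input_delayed,
    shape_input_simple,
    simulate_batch,
    simulate_neuron,
    slow_update,
    step_noise,
)
from ornmotif.stimuli import H_STEP, StimulusTrace, square_pulse


class TestFastMap:
    def test_reset_branch(self):
        assert map_f(1.0, 0.0, 3.0) == -1.0
        assert map_f(1.7, 0.5, 0.01) == -1.0

    def test_spike_branch(self):
        assert map_f(0.0, 0.3, 5.0) == 1.0
        assert map_f(-0.5, 0.0, 0.01) == 1.0

    def test_linear_branch(self):
        assert map_f(-1.0, 0.1, 3.0) == pytest.approx(6.1)

    def test_vectorized_branches(self):
        x = np.array([-1.0, 0.0, 1.0])
        out = map_f(x, 0.0, 0.5)
        assert np.allclose(out, [1.0, 1.0, -1.0])


class TestNoise:
    def test_zero_amplitude_stays_zero(self):
        p = NoiseParams(d=0.0)
        xi = 0.0
        for w in np.random.default_rng(0).standard_normal(100):
            xi = step_noise(xi, p, w)
        assert xi == 0.0

    def test_stationary_std_equals_d(self):
        # AR(1) closed form: var = p^2/(1-q^2) = d^2
        p = NoiseParams()
        w = np.random.default_rng(1).standard_normal(1_000_000)
        xi = lfilter([0.0, -p.p], [1.0, -p.q], w)
        assert xi.std() == pytest.approx(p.d, rel=0.02)

    def test_correlation_time_is_tau_c(self):
        p = NoiseParams()
        w = np.random.default_rng(2).standard_normal(400_000)
        xi = lfilter([0.0, -p.p], [1.0, -p.q], w)
        lags = np.arange(1, 15)
        ac = np.array([np.corrcoef(xi[:-k], xi[k:])[0, 1] for k in lags])
        tau_steps = -1.0 / np.polyfit(lags, np.log(ac), 1)[0]
        assert tau_steps * 0.5 == pytest.approx(3.0, rel=0.1)  # ms

    def test_q_p_relation(self):
        p = NoiseParams(tau_c=3.0, d=0.01)
        assert p.q == pytest.approx(np.exp(-0.5 / 3.0))
        assert p.p == pytest.approx(0.01 * np.sqrt(1 - p.q ** 2))


class TestCoupling:
    def test_zero_inputs(self):
        p = MotifParams.for_motif("excitatory")
        assert couple_inputs(0.0, 0.0, p, NoiseParams()) == (0.0, 0.0)

    def test_sigma_n_formula(self):
        p = MotifParams.for_motif("excitatory", sigma_r=1.0)
        noise = NoiseParams(sigma_xi=1.0)
        _, sigma_n = couple_inputs(0.0, 1.0, p, noise)
        assert sigma_n == pytest.approx(1.0)

    def test_beta_n_linear_in_noise(self):
        p = MotifParams.for_motif("excitatory")
        noise = NoiseParams(beta_xi=0.1)
        beta_n, _ = couple_inputs(0.5, 0.0, p, noise)
        assert beta_n == pytest.approx(0.05)


class TestInputShaping:
    def test_zero_in_zero_out(self):
        p = MotifParams.for_motif("excitatory")
        assert shape_input_simple(0.0, 0.0, p) == 0.0

    @pytest.mark.parametrize("motif,expected", [("excitatory", 0.039),
                                                ("offset", -0.04),
                                                ("inhibitory", -0.02)])
    def test_fixed_point_is_as_times_s(self, motif, expected):
        p = MotifParams.for_motif(motif)
        I = 0.0
        for _ in range(20000):
            I = shape_input_simple(I, 1.0, p)
        assert I == pytest.approx(expected, rel=1e-6)

    def test_lowpass_time_constant(self):
        # ~63% of the fixed point after h/(1-gamma_s) = 100 ms
        p = MotifParams.for_motif("excitatory")
        I = 0.0
        for _ in range(200):  # 100 ms at h = 0.5 ms
            I = shape_input_simple(I, 1.0, p)
        assert I / 0.039 == pytest.approx(1 - np.exp(-1), abs=0.02)

    def test_simple_shaping_rejects_delayed(self):
        with pytest.raises(ValueError):
            shape_input_simple(0.0, 1.0, MotifParams.for_motif("delayed"))


class TestDelayedShaping:
    def test_silent_stimulus_gives_zero_current(self):
        p = MotifParams.for_motif("delayed")
        aux, s_prev = DelayedAux(), 0.0
        for _ in range(1000):
            aux, I = shape_input_delayed(aux, 0.0, s_prev, p)
            assert I == 0.0

    def test_constant_stimulus_decays_highpass_states(self):
        p = MotifParams.for_motif("delayed")
        aux = DelayedAux(I_d=0.5, h_p=0.5, I_p=0.0)
        for _ in range(2000):
            aux, _ = shape_input_delayed(aux, 1.0, 1.0, p)
        assert abs(aux.I_d) < 1e-6
        assert abs(aux.h_p) < 0.4  # slow relaxation, decaying geometrically

    def test_step_onset_dip_then_slow_rise(self):
        p = MotifParams.for_motif("delayed")
        stim = square_pulse(0.1, 4.0, 5.0)
        I = input_current_trace(p, stim.samples)
        # transiently below baseline, bounded by the depth limit L
        assert I.min() < 0
        assert I.min() >= p.L
        # slower time-to-peak than the excitatory motif's current
        I_exc = input_current_trace(MotifParams.for_motif("excitatory"), stim.samples)
        t_peak_delayed = np.argmax(I)
        t_peak_exc = np.argmax(I_exc >= 0.95 * I_exc.max())
        assert t_peak_delayed > t_peak_exc

    def test_trace_matches_stepwise_oracle(self):
        p = MotifParams.for_motif("delayed")
        rng = np.random.default_rng(0)
        s = np.clip(rng.random(500), 0, 1)
        trace = input_current_trace(p, s)
        aux, s_prev, out = DelayedAux(), 0.0, []
        for sn in s:
            out.append(0.0)  # I_n is pre-update state in the trace convention
            aux, I = shape_input_delayed(aux, sn, s_prev, p)
            out[-1] = I
            s_prev = sn
        # trace[n] corresponds to state before consuming s[n]; compare shifted
        assert np.allclose(trace[1:], out[:-1], atol=1e-12)


class TestMotifParams:
    def test_published_table_values(self):
        p = MotifParams.for_motif("excitatory")
        assert (p.a_s, p.gamma_s) == (0.039, 0.995)
        d = MotifParams.for_motif("delayed")
        assert (d.a_p, d.gamma_p, d.a_d, d.gamma_d, d.gamma_h, d.L) == (
            0.08, 0.999, 0.8, 0.99, 0.99985, -0.04)

    def test_sign_conventions(self):
        assert MotifParams.for_motif("excitatory").a_s > 0
        assert MotifParams.for_motif("offset").a_s < 0
        assert MotifParams.for_motif("inhibitory").a_s < 0

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            MotifParams.for_motif("excitatory", gamma_s=1.5)
        with pytest.raises(ValueError):
            MotifParams.for_motif("excitatory", a_p=0.1)
        with pytest.raises(ValueError):
            MotifParams.for_motif("sustained")

    def test_yaml_roundtrip_bit_exact(self, tmp_path):
        path = tmp_path / "params.yaml"
        params_to_yaml(path)
        motifs, noise = params_from_yaml(path)
        for m, p in default_params().items():
            assert motifs[m] == p
        assert noise == NoiseParams()


class TestSimulation:
    def test_quiescent_without_stimulus_or_noise(self):
        p = MotifParams.for_motif("excitatory")
        stim = square_pulse(0.0, 0.0, 2.0)
        spikes = simulate_neuron(p, stim, gain=0.0, noise=NoiseParams(d=0.0))
        assert len(spikes) == 0

    def test_deterministic_given_seed(self):
        p = MotifParams.for_motif("excitatory")
        stim = square_pulse(0.5, 1.0, 2.5)
        a = simulate_neuron(p, stim, seed=7)
        b = simulate_neuron(p, stim, seed=7)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, simulate_neuron(p, stim, seed=8))

    def test_no_consecutive_spike_iterations(self):
        p = MotifParams.for_motif("excitatory")
        stim = square_pulse(0.5, 2.0, 3.0)
        spikes = simulate_neuron(p, stim, seed=3)
        assert len(spikes) > 0
        assert np.all(np.diff(spikes) >= 2 * H_STEP - 1e-12)

    def test_rejects_wrong_sampling(self):
        p = MotifParams.for_motif("excitatory")
        stim = StimulusTrace(np.zeros(100), dt=0.001)
        with pytest.raises(ValueError):
            simulate_neuron(p, stim)

    def test_rejects_out_of_range_gain(self):
        p = MotifParams.for_motif("excitatory")
        stim = square_pulse(0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            simulate_batch(p, stim, np.array([1.5]))

    def test_batch_matches_scalar_oracle(self):
        """The vectorized simulator reproduces a step-by-step scalar loop."""
        p = MotifParams.for_motif("excitatory")
        noise = NoiseParams()
        stim = square_pulse(0.1, 0.3, 0.6)
        seed, nid = 13, 0
        ev = simulate_batch(p, stim, np.array([1.0]), seed=seed,
                            neuron_ids=np.array([nid]))
        batch_steps = set(np.round(ev[:, 2] / H_STEP).astype(int))

        W = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(nid, 0))
        ).standard_normal(len(stim.samples))
        I_trace = input_current_trace(p, stim.samples)
        x = p.sigma - 1.0
        y = x * (1 + p.alpha) - p.alpha
        xi = 0.0
        scalar_steps = set()
        for n, s_n in enumerate(stim.samples):
            beta_n, sigma_n = couple_inputs(xi, I_trace[n], p, noise)
            x_new = map_f(x, y + beta_n, p.alpha)
            y = slow_update(y, x, p.sigma, sigma_n, p.mu)
            x = x_new
            if x == 1.0:
                scalar_steps.add(n + 1)
            xi = step_noise(xi, noise, W[n])
        assert scalar_steps == batch_steps

    def test_population_split_equals_concatenation(self):
        """No cross-neuron coupling: batches can be split without changing spikes."""
        p = MotifParams.for_motif("delayed")
        stim = square_pulse(0.2, 0.5, 1.5)
        gains = np.array([1.0, 0.8, 0.6, 0.9])
        ids = np.arange(4)
        full = simulate_batch(p, stim, gains, seed=5, neuron_ids=ids)
        left = simulate_batch(p, stim, gains[:2], seed=5, neuron_ids=ids[:2])
        right = simulate_batch(p, stim, gains[2:], seed=5, neuron_ids=ids[2:])
        right[:, 0] += 2
        merged = np.vstack([left, right])
        order = np.lexsort((merged[:, 2], merged[:, 1], merged[:, 0]))
        assert np.allclose(full, merged[order])


class TestMotifShapes:
    """Qualitative response shapes of the calibrated motifs (4 s pulse)."""

    @staticmethod
    def _psth(motif, stim, n_rep=30, seed=0, bin_s=0.1):
        p = MotifParams.for_motif(motif)
        ev = simulate_batch(p, stim, np.ones(n_rep), seed=seed,
                            neuron_ids=np.arange(n_rep))
        nb = int(stim.duration / bin_s)
        r = np.zeros(nb)
        if len(ev):
            np.add.at(r, np.minimum((ev[:, 2] / bin_s).astype(int), nb - 1), 1)
        return r / (n_rep * bin_s)

    @pytest.fixture(scope="class")
    @staticmethod
    def pulse():
        return square_pulse(2.0, 4.0, 8.0)

    def test_excitatory_sharp_onset_decaying(self, pulse):
        r = self._psth("excitatory", pulse)
        t = np.arange(len(r)) * 0.1
        pre = r[t < 2].mean()
        during = r[(t >= 2) & (t < 6)]
        assert during.max() > 5 * pre           # strong onset peak
        assert np.argmax(during) <= 3           # within the first 400 ms
        assert during[-10:].mean() < 0.3 * during.max()  # decays during pulse

    def test_offset_suppressed_then_rebounds(self, pulse):
        r = self._psth("offset", pulse)
        t = np.arange(len(r)) * 0.1
        pre = r[t < 2].mean()
        during = r[(t >= 2.5) & (t < 6)].mean()
        post_peak = r[(t >= 6) & (t < 7.5)].max()
        assert during < 0.5 * pre
        assert post_peak > 2.0 * pre

    def test_inhibitory_suppressed_returns_near_baseline(self, pulse):
        r = self._psth("inhibitory", pulse)
        t = np.arange(len(r)) * 0.1
        pre = r[t < 2].mean()
        during = r[(t >= 2.5) & (t < 6)].mean()
        post_peak = r[(t >= 6) & (t < 7.5)].max()
        assert during < 0.5 * pre
        assert post_peak < 0.6 * self._psth("offset", pulse)[
            (t >= 6) & (t < 7.5)].max()

    def test_delayed_slower_rise_than_excitatory(self, pulse):
        r_del = self._psth("delayed", pulse)
        r_exc = self._psth("excitatory", pulse)
        t = np.arange(len(r_del)) * 0.1
        w = (t >= 2) & (t < 6)
        assert np.argmax(r_del[w]) > np.argmax(r_exc[w])
        assert r_del[w].max() > 3 * r_del[t < 2].mean()
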