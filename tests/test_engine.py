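"""Engine: delay-buffered integration, coupling, stimuli, monitors."""

import numpy as np
import pytest

from neuromass import (
    Connectome,
    IntegratorSpec,
    MonitorSpec,
    SimulationExperiment,
    StimulusSpec,
    make_coupling,
    pulse_train,
    resample_waveform,
    run,
)
from neuromass.engine import single_node_experiment
from neuromass.errors import SimulationOverflowError
from neuromass.schema import PulseTrain
from neuromass.timeseries import read_csv, read_npz, write_csv, write_npz

from conftest import build_model, make_experiment


def chain_connectome(length_mm=100.0, weight=1.0):
    """Node 1 feeds node 0 <- no; node 0 feeds node 1 (one-directional)."""
    return Connectome(
        labels=["src", "dst"],
        weights=[[0.0, 0.0], [weight, 0.0]],  # weights[i][j]: j -> i
        tract_lengths=[[0.0, length_mm], [length_mm, 0.0]],
    )


def brute_force_simulate(model_k, x0, W, steps_m, gain, stim, dt, n_steps):
    """Independent oracle: explicit full-history arrays, per-entry sums.

    Simulates dx_i/dt = -k*x_i + gain * sum_j W_ij * x_j(t - tau_ij) + stim_i
    with constant history and forward Euler.
    """
    nr = W.shape[0]
    X = np.empty((n_steps + 1, nr))
    X[0] = x0
    for k in range(n_steps):
        agg = np.zeros(nr)
        for i in range(nr):
            for j in range(nr):
                kd = k - steps_m[i, j]
                xj = X[kd, j] if kd >= 0 else x0[j]
                agg[i] += W[i, j] * xj
        X[k + 1] = X[k] + dt * (-model_k * X[k] + gain * agg + stim[k])
    return X[:n_steps]  # samples at t = 0 .. (n_steps-1)*dt


class TestIntegration:
    def test_linear_decay_matches_closed_form(self, decay_model):
        exp = single_node_experiment(decay_model, duration=1.0, dt=0.001,
                                     method="euler")
        ts = run(exp)["raw"]
        t_last = ts.time[-1]
        assert abs(ts.data[-1, 0, 0, 0] - np.exp(-t_last)) < 1e-3

    def test_euler_error_scales_linearly_with_dt(self, decay_model):
        errs = []
        for dt in (0.02, 0.01, 0.005):
            exp = single_node_experiment(decay_model, duration=2.0, dt=dt,
                                         method="euler")
            ts = run(exp)["raw"]
            errs.append(abs(ts.data[-1, 0, 0, 0] - np.exp(-ts.time[-1])))
        assert 1.7 < errs[0] / errs[1] < 2.3
        assert 1.7 < errs[1] / errs[2] < 2.3

    def test_heun_is_more_accurate_than_euler(self, decay_model):
        out = {}
        for method in ("euler", "heun"):
            exp = single_node_experiment(decay_model, duration=2.0, dt=0.01,
                                         method=method)
            ts = run(exp)["raw"]
            out[method] = abs(ts.data[-1, 0, 0, 0] - np.exp(-ts.time[-1]))
        assert out["heun"] < out["euler"] / 50

    def test_discrete_system_steps_as_a_map(self):
        logistic = build_model([("x", "r*x*(1 - x)")],
                               params=(("r", 2.0),),
                               initial={"x": 0.25}, system_type="discrete")
        exp = single_node_experiment(logistic, duration=5.0, dt=1.0,
                                     method="euler")
        ts = run(exp)["raw"]
        expected = [0.25]
        for _ in range(4):
            expected.append(2.0 * expected[-1] * (1 - expected[-1]))
        assert np.allclose(ts.data[:, 0, 0, 0], expected)

    def test_overflow_aborts_with_step_index(self):
        blow = build_model([("x", "x*x*x")], initial={"x": 5.0})
        exp = single_node_experiment(blow, duration=100.0, dt=0.5,
                                     method="euler")
        with pytest.raises(SimulationOverflowError) as ei:
            run(exp)
        assert "step" in str(ei.value) and ei.value.step < 200


class TestCouplingAndDelays:
    def test_zero_weights_factorizes_into_single_node_runs(self, linear_model,
                                                           small_connectome):
        conn = small_connectome
        conn.weights = np.zeros_like(conn.weights)
        exp = make_experiment(linear_model, conn, gain=0.5, dt=0.1,
                              duration=50.0)
        multi = run(exp)["raw"]
        single = run(single_node_experiment(
            linear_model, duration=50.0, dt=0.1))["raw"]
        for r in range(conn.n):
            assert np.array_equal(multi.data[:, :, r, 0], single.data[:, :, 0, 0])

    def test_matches_brute_force_full_history_oracle(self, linear_model):
        n = 5
        rng = np.random.default_rng(8)
        W = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(W, 0.0)
        L = rng.uniform(10, 90, (n, n))
        L = (L + L.T) / 2
        np.fill_diagonal(L, 0.0)
        conn = Connectome(labels=[f"r{i}" for i in range(n)], weights=W,
                          tract_lengths=L)
        dt, duration, v, gain = 0.5, 60.0, 5.0, 0.3
        stim_spec = StimulusSpec(kind="pulse_train", target_state="x",
                                 pulse=PulseTrain(onset=5.0, period=100.0,
                                                  width=10.0, amplitude=0.7))
        exp = make_experiment(linear_model, conn, gain=gain, dt=dt,
                              duration=duration, method="euler",
                              conduction_speed=v, stimuli=[stim_spec])
        exp.dynamics.parameter("c").value = 0.0
        got = run(exp)["raw"].data[:, 0, :, 0]

        n_steps = int(round(duration / dt))
        steps_m = np.rint(L / v / dt).astype(int)
        wave = pulse_train(5.0, 100.0, 10.0, 0.7, dt, duration)
        stim = np.tile(wave[:, None], (1, n))
        ref = brute_force_simulate(1.0, np.ones(n), W, steps_m, gain, stim,
                                   dt, n_steps)
        assert np.max(np.abs(got - ref)) < 1e-10

    def test_impulse_response_shifts_by_exact_delay_steps(self, linear_model):
        dt, v = 1.0, 10.0
        stim = StimulusSpec(kind="pulse_train", target_state="x",
                            pulse=PulseTrain(onset=5.0, period=1000.0,
                                             width=2.0, amplitude=1.0),
                            region_weights=[1.0, 0.0])
        runs = {}
        for L, tag in ((100.0, "delayed"), (1e-9, "instant")):
            exp = make_experiment(linear_model, chain_connectome(L), gain=1.0,
                                  dt=dt, duration=120.0, method="euler",
                                  conduction_speed=v, stimuli=[stim])
            exp.dynamics.parameter("c").value = 0.0
            exp.dynamics.states[0].initial = 0.0
            runs[tag] = run(exp)["raw"].data[:, 0, :, 0]
        shift = int(round(100.0 / v / dt))  # 10 steps
        # source node identical in both runs
        assert np.array_equal(runs["delayed"][:, 0], runs["instant"][:, 0])
        # destination response is the zero-delay response shifted by 10 steps
        assert np.array_equal(runs["delayed"][shift:, 1],
                              runs["instant"][:-shift, 1])
        onset_inst = np.argmax(runs["instant"][:, 1] != 0)
        onset_del = np.argmax(runs["delayed"][:, 1] != 0)
        assert onset_del - onset_inst == shift

    def test_linear_coupling_gain(self):
        c = make_coupling("linear", {"a": 0.5})
        post = c.post_expr.evaluate({"agg": 2.0, "a": 0.5})
        assert post == 1.0

    def test_sigmoidal_saturation_and_midpoint(self):
        c = make_coupling("sigmoidal", {"c_min": 0.0, "c_max": 2.0,
                                        "r": 1.0, "theta": 3.0})
        binding = {"c_min": 0.0, "c_max": 2.0, "r": 1.0, "theta": 3.0}
        hi = c.post_expr.evaluate({"agg": 1e4, **binding})
        mid = c.post_expr.evaluate({"agg": 3.0, **binding})
        assert hi == pytest.approx(2.0, abs=1e-12)
        assert mid == pytest.approx(1.0, abs=1e-12)

    def test_unknown_coupling_kind_rejected(self):
        with pytest.raises(ValueError):
            make_coupling("quadratic")


class TestStimuli:
    def test_pulse_train_support(self):
        wave = pulse_train(onset=4000, period=8000, width=1000, amplitude=0.05,
                           dt=1.0, duration=8000)
        t = np.arange(8000)
        on = (t >= 4000) & (t < 5000)
        assert np.all(wave[on] == 0.05)
        assert np.all(wave[~on] == 0.0)

    def test_zero_amplitude_and_late_onset_give_silence(self):
        assert not pulse_train(0, 10, 5, 0.0, 1.0, 100).any()
        assert not pulse_train(500, 10, 5, 1.0, 1.0, 100).any()

    def test_width_exceeding_period_rejected(self):
        with pytest.raises(ValueError):
            pulse_train(0, 10, 20, 1.0, 1.0, 100)

    def test_resample_identity_at_matching_rate(self):
        sig = np.sin(np.linspace(0, 4 * np.pi, 200))
        out = resample_waveform(sig, sample_rate=1.0, dt=1.0, duration=150.0)
        assert np.allclose(out, sig[:150])

    def test_resample_constant(self):
        out = resample_waveform(np.full(50, 3.3), sample_rate=0.5, dt=1.0,
                                duration=80.0)
        assert len(out) == 80
        assert np.allclose(out[:49 * 2], 3.3)

    def test_resample_preserves_sine_rms(self):
        # 10 Hz sine sampled at 44.1 kHz, resampled to the 1 kHz grid
        f_khz = 0.01  # cycles per ms
        src_rate = 44.1  # samples per ms
        t_src = np.arange(0, 2000 * src_rate) / src_rate
        sig = np.sin(2 * np.pi * f_khz * t_src)
        out = resample_waveform(sig, sample_rate=src_rate, dt=1.0,
                                duration=2000.0)
        rms = np.sqrt(np.mean(out**2))
        assert abs(rms - 1 / np.sqrt(2)) / (1 / np.sqrt(2)) < 0.01

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            resample_waveform([], 1.0, 1.0, 10.0)

    def test_stimulus_superposition_on_linear_model(self, linear_model,
                                                    small_connectome):
        def response(stimuli):
            exp = make_experiment(linear_model, small_connectome, gain=0.2,
                                  dt=0.5, duration=100.0, method="euler",
                                  stimuli=stimuli)
            return run(exp)["raw"].data

        a = StimulusSpec(kind="pulse_train", target_state="x",
                         pulse=PulseTrain(onset=5, period=200, width=10,
                                          amplitude=0.5))
        b = StimulusSpec(kind="sampled", target_state="x",
                         sampled=__import__("neuromass").schema.SampledWaveform(
                             values=list(np.sin(np.arange(100) / 7.0)),
                             sample_rate=1.0))
        r_ab = response([a, b])
        r_a, r_b, r_0 = response([a]), response([b]), response([])
        assert np.max(np.abs(r_ab - (r_a + r_b - r_0))) < 1e-9


class TestDeterminismAndNoise:
    def test_bitwise_replay_under_fixed_seed(self, linear_model,
                                             small_connectome):
        def go():
            exp = make_experiment(linear_model, small_connectome, gain=0.3,
                                  dt=0.5, duration=100.0,
                                  method="euler_maruyama", seed=99)
            exp.integrator.noise_sigma = 0.05
            return run(exp)["raw"].data

        assert np.array_equal(go(), go())

    def test_zero_noise_euler_maruyama_equals_euler_bitwise(
            self, linear_model, small_connectome):
        outs = {}
        for method in ("euler", "euler_maruyama"):
            exp = make_experiment(linear_model, small_connectome, gain=0.3,
                                  dt=0.5, duration=100.0, method=method,
                                  seed=5)
            outs[method] = run(exp)["raw"].data
        assert np.array_equal(outs["euler"], outs["euler_maruyama"])

    def test_noise_actually_perturbs(self, linear_model, small_connectome):
        exp = make_experiment(linear_model, small_connectome, gain=0.3, dt=0.5,
                              duration=100.0, method="euler_maruyama", seed=1)
        exp.integrator.noise_sigma = 0.1
        noisy = run(exp)["raw"].data
        exp2 = make_experiment(linear_model, small_connectome, gain=0.3, dt=0.5,
                               duration=100.0, method="euler", seed=1)
        clean = run(exp2)["raw"].data
        assert not np.array_equal(noisy, clean)


class TestMonitors:
    def test_temporal_average_of_linear_ramp(self):
        ramp = build_model([("x", "1 + 0*x")], initial={"x": 0.0})
        exp = single_node_experiment(ramp, duration=10.0, dt=1.0,
                                     method="euler")
        exp.monitors = [MonitorSpec(name="avg", kind="temporal_average",
                                    period=2.0)]
        ts = run(exp)["avg"]
        # states before steps 0..9 are 0,1,...,9; pairwise means 0.5,2.5,...
        assert np.allclose(ts.data[:, 0, 0, 0], [0.5, 2.5, 4.5, 6.5, 8.5])

    def test_raw_monitor_subsampling(self, decay_model):
        exp = single_node_experiment(decay_model, duration=10.0, dt=0.5)
        exp.monitors = [MonitorSpec(name="raw", kind="raw", period=2.0)]
        ts = run(exp)["raw"]
        assert np.allclose(np.diff(ts.time), 2.0)

    def test_csv_and_npz_round_trip(self, decay_model, tmp_path):
        exp = single_node_experiment(decay_model, duration=10.0, dt=0.5)
        ts = run(exp)["raw"]
        write_csv(ts, tmp_path / "ts.csv")
        write_npz(ts, tmp_path / "ts.npz")
        from_csv = read_csv(tmp_path / "ts.csv")
        from_npz = read_npz(tmp_path / "ts.npz")
        assert from_npz == ts
        assert np.allclose(from_csv.data, ts.data)
        assert from_csv.state_labels == ts.state_labels
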