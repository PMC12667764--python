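"""Observation DAGs, HRF kernels, convolution, functional connectivity."""

import numpy as np
import pytest

from neuromass import (
    FunctionNode,
    ObservationGraph,
    compare_fc,
    convolve_states,
    downsample,
    execute,
    functional_connectivity,
    hrf_kernel,
)
from neuromass.errors import CycleError
from neuromass.observation import OPERATORS, ObservationError, bold_fc_graph
from neuromass.timeseries import TimeSeries4D


def series(data, dt=1.0, states=None, transient=0.0):
    data = np.asarray(data, dtype=float)
    while data.ndim < 4:
        data = data[..., None]
    nt, ns = data.shape[:2]
    return TimeSeries4D(
        data=data,
        time=np.arange(nt) * dt,
        state_labels=states or [f"s{i}" for i in range(ns)],
        region_labels=[f"r{i}" for i in range(data.shape[2])],
        sample_period=dt,
        transient=transient,
    )


class TestHRFKernel:
    @pytest.mark.parametrize("kind,params", [
        ("canonical", {}),
        ("canonical", {"peak": 5.0, "undershoot": 12.0, "ratio": 0.2}),
        ("volterra", {}),
        ("volterra", {"tau_s": 1.2, "tau_f": 0.5}),
    ])
    def test_unit_area(self, kind, params):
        for dt in (0.1, 0.05):
            k = hrf_kernel(kind, dict(params), dt=dt)
            assert abs(k.sum() * dt - 1.0) <= 1e-6

    def test_amplitude_is_normalized_away(self):
        a = hrf_kernel("canonical", {"amplitude": 1.0}, dt=0.1)
        b = hrf_kernel("canonical", {"amplitude": 2.0}, dt=0.1)
        assert np.array_equal(a, b)

    def test_halving_dt_keeps_unit_area(self):
        for dt in (0.2, 0.1, 0.05):
            k = hrf_kernel("volterra", dt=dt)
            assert abs(k.sum() * dt - 1.0) <= 1e-6

    def test_canonical_has_undershoot(self):
        k = hrf_kernel("canonical", dt=0.1)
        assert k.max() > 0 and k.min() < 0
        assert np.argmax(k) < np.argmin(k)

    @pytest.mark.parametrize("kind,params", [
        ("canonical", {"peak": -1.0}),
        ("volterra", {"tau_s": 0.0}),
        ("volterra", {"tau_f": 10.0}),  # overdamped: no oscillatory kernel
        ("gauss", {}),
    ])
    def test_invalid_kinds_and_constants_rejected(self, kind, params):
        with pytest.raises(ValueError):
            hrf_kernel(kind, params, dt=0.1)


class TestConvolve:
    def test_delta_kernel_is_identity(self, rng):
        ts = series(rng.normal(size=(64, 1, 3)), dt=0.5)
        out = convolve_states(ts, np.array([1.0 / 0.5]))
        assert np.allclose(out.data, ts.data, atol=1e-12)

    def test_length_preserved(self, rng):
        ts = series(rng.normal(size=(100, 2, 2)))
        out = convolve_states(ts, hrf_kernel("canonical", dt=1.0))
        assert out.n_times == 100

    def test_matches_naive_direct_convolution(self, rng):
        sig = rng.normal(size=40)
        ker = rng.normal(size=7)
        ts = series(sig[:, None, None])
        out = convolve_states(ts, ker).data[:, 0, 0, 0]
        # O(T*K) causal oracle
        ref = np.zeros(40)
        for t in range(40):
            for k in range(min(7, t + 1)):
                ref[t] += ker[k] * sig[t - k] * 1.0  # dt = 1
        assert np.max(np.abs(out - ref)) <= 1e-10

    def test_causality(self, rng):
        sig = np.zeros(50)
        sig[20] = 1.0
        out = convolve_states(series(sig[:, None, None]),
                              hrf_kernel("canonical", dt=1.0))
        assert np.allclose(out.data[:20, 0, 0, 0], 0.0, atol=1e-15)

    def test_unit_area_kernel_preserves_constant_mean(self):
        ts = series(np.full((4000, 1, 1), 2.5), dt=1.0)
        k = hrf_kernel("canonical", dt=1.0)
        out = convolve_states(ts, k).data[:, 0, 0, 0]
        # past the kernel support the output equals the input level
        assert abs(out[-1000:].mean() - 2.5) < 1e-3

    def test_unselected_states_pass_through(self, rng):
        ts = series(rng.normal(size=(30, 2, 1)), states=["V", "W"])
        out = convolve_states(ts, np.array([0.25, 0.25, 0.25, 0.25]),
                              states=["V"])
        assert np.array_equal(out.data[:, 1], ts.data[:, 1])
        assert not np.array_equal(out.data[:, 0], ts.data[:, 0])

    def test_kernel_longer_than_signal_warns(self, rng):
        ts = series(rng.normal(size=(5, 1, 1)))
        with pytest.warns(UserWarning):
            out = convolve_states(ts, np.ones(11) / 11.0)
        assert out.n_times == 5


class TestDownsample:
    def test_4000ms_at_tr_500_gives_8_samples(self):
        ts = series(np.zeros((4000, 1, 1)), dt=1.0)
        assert downsample(ts, tr=500.0).n_times == 8

    def test_tr_equal_period_is_identity(self, rng):
        ts = series(rng.normal(size=(16, 1, 1)), dt=2.0)
        out = downsample(ts, tr=2.0)
        assert np.array_equal(out.data, ts.data)

    def test_tr_below_period_rejected(self):
        ts = series(np.zeros((10, 1, 1)), dt=2.0)
        with pytest.raises(ValueError):
            downsample(ts, tr=1.0)

    def test_time_base_retained(self):
        ts = series(np.zeros((100, 1, 1)), dt=1.0)
        out = downsample(ts, tr=10.0)
        assert np.allclose(np.diff(out.time), 10.0)
        assert out.sample_period == 10.0


class TestFunctionalConnectivity:
    def test_identical_traces_correlate_fully(self, rng):
        x = rng.normal(size=20)
        ts = series(np.stack([x, x], axis=1)[:, None, :])
        fc = functional_connectivity(ts)
        assert fc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_trace_anticorrelates(self, rng):
        x = rng.normal(size=20)
        ts = series(np.stack([x, -x], axis=1)[:, None, :])
        fc = functional_connectivity(ts)
        assert fc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_per_pair_two_pass_oracle(self, rng):
        data = rng.normal(size=(50, 1, 5))
        fc = functional_connectivity(series(data))
        x = data[:, 0, :]
        for i in range(5):
            for j in range(5):
                xi, xj = x[:, i], x[:, j]
                cov = np.mean((xi - xi.mean()) * (xj - xj.mean()))
                ref = cov / (xi.std() * xj.std())
                assert abs(fc[i, j] - ref) <= 1e-10

    def test_symmetric_unit_diagonal_bounded(self, rng):
        fc = functional_connectivity(series(rng.normal(size=(40, 1, 6))))
        assert np.allclose(fc, fc.T)
        assert np.allclose(np.diag(fc), 1.0)
        assert np.all(np.abs(fc) <= 1.0)

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(60, 1, 4))
        fc_a = functional_connectivity(series(data))
        scaled = data * np.array([2.0, -3.0, 0.5, 10.0]) + \
            np.array([1.0, -5.0, 0.0, 2.0])
        fc_b = functional_connectivity(series(scaled))
        sign = np.sign(np.array([2.0, -3.0, 0.5, 10.0]))
        assert np.allclose(fc_b, fc_a * np.outer(sign, sign), atol=1e-12)

    def test_zero_variance_region_marked_undefined(self, rng):
        data = rng.normal(size=(30, 1, 3))
        data[:, 0, 2] = 4.2
        with pytest.warns(UserWarning):
            fc = functional_connectivity(series(data))
        assert np.isnan(fc[2, 0]) and np.isnan(fc[0, 2])
        assert not np.isnan(fc[0, 1])

    def test_transient_excluded(self, rng):
        data = rng.normal(size=(40, 1, 2))
        ts = series(data, dt=1.0, transient=20.0)
        fc = functional_connectivity(ts)
        ref = functional_connectivity(series(data[20:]))
        assert np.allclose(fc, ref)


class TestCompareFC:
    def test_equal_inputs_zero_difference(self, rng):
        fc = functional_connectivity(series(rng.normal(size=(30, 1, 4))))
        comp, diff = compare_fc(fc, fc)
        assert diff == 0.0

    def test_triangles_recoverable(self, rng):
        a = functional_connectivity(series(rng.normal(size=(30, 1, 4))))
        b = functional_connectivity(series(rng.normal(size=(30, 1, 4))))
        comp, _ = compare_fc(a, b)
        iu = np.triu_indices(4, 1)
        il = np.tril_indices(4, -1)
        assert np.array_equal(comp[iu], a[iu])
        assert np.array_equal(comp[il], b[il])
        assert np.all(np.diag(comp) == 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_fc(np.eye(3), np.eye(4))


class TestGraphExecution:
    def test_identity_node(self, rng):
        ts = series(rng.normal(size=(10, 1, 2)))
        g = ObservationGraph(nodes=[
            FunctionNode(name="out", op="identity", inputs=["sim"])])
        res = execute(g, {"sim": ts})
        assert res["out"] is ts

    def test_cycle_detected(self):
        g = ObservationGraph(nodes=[
            FunctionNode(name="A", op="identity", inputs=["B"]),
            FunctionNode(name="B", op="identity", inputs=["A"]),
        ])
        with pytest.raises(CycleError):
            execute(g, {})

    def test_missing_input_reported(self):
        g = ObservationGraph(nodes=[
            FunctionNode(name="A", op="identity", inputs=["nope"])])
        with pytest.raises(ObservationError, match="nope"):
            execute(g, {})

    def test_diamond_evaluates_shared_upstream_once(self, rng):
        calls = {"n": 0}

        def counting(node, args):
            calls["n"] += 1
            return args[0]

        OPERATORS["_counting"] = counting
        try:
            ts = series(rng.normal(size=(10, 1, 2)))
            g = ObservationGraph(nodes=[
                FunctionNode(name="shared", op="_counting", inputs=["sim"]),
                FunctionNode(name="left", op="identity", inputs=["shared"]),
                FunctionNode(name="right", op="identity", inputs=["shared"]),
                FunctionNode(name="merge", op="compare_fc",
                             inputs=["left_fc", "right_fc"]),
                FunctionNode(name="left_fc", op="functional_connectivity",
                             inputs=["left"]),
                FunctionNode(name="right_fc", op="functional_connectivity",
                             inputs=["right"]),
            ])
            res = execute(g, {"sim": ts})
        finally:
            del OPERATORS["_counting"]
        assert calls["n"] == 1
        assert res["merge"]["max_abs_diff"] == 0.0

    def test_expression_node(self, rng):
        ts = series(rng.normal(size=(10, 2, 2)), states=["V", "W"])
        g = ObservationGraph(nodes=[
            FunctionNode(name="scaled", expression="2*sim + 1", inputs=["sim"])])
        res = execute(g, {"sim": ts})
        assert np.allclose(res["scaled"].data, 2 * ts.data + 1)

    def test_execution_is_bitwise_deterministic(self, rng):
        ts = series(rng.normal(size=(200, 2, 3)), states=["V", "W"])
        g = bold_fc_graph(state="V")
        a = execute(g, {"sim": ts})
        b = execute(g, {"sim": ts})
        assert np.array_equal(a["bold"].data, b["bold"].data)
        assert np.array_equal(a["fc_bold"], b["fc_bold"])

    def test_selector_mismatch_reported(self, rng):
        ts = series(rng.normal(size=(10, 1, 2)), states=["V"])
        g = ObservationGraph(nodes=[
            FunctionNode(name="sel", op="select", inputs=["sim"],
                         states=["Q"])])
        with pytest.raises(ObservationError, match="Q"):
            execute(g, {"sim": ts})

    def test_rank_expansion_to_4d(self):
        from neuromass.timeseries import expand_to_4d

        assert expand_to_4d(np.zeros(5)).shape == (5, 1, 1, 1)
        assert expand_to_4d(np.zeros((5, 2))).shape == (5, 2, 1, 1)
        assert expand_to_4d(np.zeros((5, 2, 3, 1))).shape == (5, 2, 3, 1)
        with pytest.raises(ValueError):
            expand_to_4d(np.zeros((2, 2, 2, 2, 2)))
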