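"""Observation pipelines: executable DAGs from simulated states to signals.

An observation graph wires :class:`FunctionNode` objects — each either a
registered operator (HRF convolution, downsampling, functional
connectivity, ...) or an elementwise symbolic expression over its inputs —
and executes them once each in topological order.  Inputs below rank 4 are
expanded to four axes (time x state x region x mode) before evaluation;
derivative nodes such as functional connectivity are endpoints of the DAG
and may change dimensionality.

The BOLD forward path is: build a hemodynamic response function (HRF)
kernel normalized to unit area, convolve the selected states with it using
an FFT-based routine that preserves signal length and causality, and
optionally downsample to a target repetition time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gammaln

from . import symbolic
from .errors import CycleError, NeuromassError
from .timeseries import TimeSeries4D, expand_to_4d


class ObservationError(NeuromassError):
    pass


# ---------------------------------------------------------------------------
# HRF kernels
# ---------------------------------------------------------------------------

def _gamma_pdf(t, shape, scale=1.0):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp - gammaln(shape)
    ) / scale
    return out


def hrf_kernel(kind: str = "canonical", params: Optional[dict] = None,
               dt: float = 0.5) -> np.ndarray:
    """Discrete hemodynamic response kernel, normalized to unit area.

    ``dt`` is the kernel sample step in seconds.  The ``canonical`` kernel
    is a difference of two gamma densities (response peak ~6 s, undershoot
    ~16 s, undershoot ratio 1/6); the ``volterra`` kernel is a first-order
    exponentially damped sine parameterized by signal-decay and feedback
    time constants.  Support is extended until the truncated tail mass is
    below 1e-6, and the discrete integral sum(k) * dt equals 1 within 1e-6
    regardless of the amplitude parameter.
    """
    if dt <= 0:
        raise ValueError("kernel step must be positive")
    params = dict(params or {})
    amplitude = params.pop("amplitude", 1.0)
    if kind == "canonical":
        peak = params.pop("peak", 6.0)
        under = params.pop("undershoot", 16.0)
        ratio = params.pop("ratio", 1.0 / 6.0)
        if peak <= 0 or under <= 0:
            raise ValueError("time constants must be positive")
        if params:
            raise ValueError(f"unknown kernel parameter(s): {sorted(params)}")
        support = max(under, peak) + 16.0
        t = np.arange(0.0, support, dt)
        k = amplitude * (_gamma_pdf(t, peak) - ratio * _gamma_pdf(t, under))
    elif kind == "volterra":
        tau_s = params.pop("tau_s", 0.8)
        tau_f = params.pop("tau_f", 0.4)
        if tau_s <= 0 or tau_f <= 0:
            raise ValueError("time constants must be positive")
        if params:
            raise ValueError(f"unknown kernel parameter(s): {sorted(params)}")
        om_sq = 1.0 / tau_f - 1.0 / (4.0 * tau_s**2)
        if om_sq <= 0:
            raise ValueError("underdamped kernel requires 1/tau_f > 1/(4 tau_s^2)")
        om = np.sqrt(om_sq)
        decay = 2.0 * tau_s
        support = decay * np.log(1e8)  # tail mass < 1e-6 of total
        t = np.arange(0.0, support, dt)
        k = amplitude * np.exp(-t / decay) * np.sin(om * t)
    else:
        raise ValueError(f"unknown HRF kind {kind!r}")
    area = k.sum() * dt
    if abs(area) < 1e-12:
        raise ValueError("kernel has (near) zero area; cannot normalize")
    return k / area


# ---------------------------------------------------------------------------
# convolution / downsampling / connectivity
# ---------------------------------------------------------------------------

def convolve_states(ts: TimeSeries4D, kernel: np.ndarray,
                    states: Optional[Sequence[str]] = None,
                    kernel_dt: Optional[float] = None) -> TimeSeries4D:
    """Causally convolve selected states with a kernel; length preserved.

    The signal is zero-padded for the FFT and the full convolution trimmed
    to [0, T), so output[t] depends only on input[<= t] and the output has
    the input's length.  Non-selected states pass through unchanged.  The
    kernel is assumed sampled at the series' own period; ``kernel_dt`` is
    that period expressed in the kernel's time unit (default: the period in
    ms), so a kernel of unit area in its own unit preserves the mean of a
    long constant signal.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("empty kernel")
    T = ts.n_times
    if kernel.size > T:
        warnings.warn("kernel longer than signal; output is still valid but "
                      "dominated by edge effects")
    sel = list(ts.state_labels) if states is None else list(states)
    idx = [ts.state_index(s) for s in sel]
    dt = ts.sample_period if kernel_dt is None else kernel_dt
    out = ts.data.astype(float).copy()
    block = out[:, idx]  # (T, n_sel, R, M)
    conv = fftconvolve(block, kernel[:, None, None, None] * dt, mode="full",
                       axes=0)[:T]
    out[:, idx] = conv
    return TimeSeries4D(
        data=out,
        time=ts.time,
        state_labels=list(ts.state_labels),
        region_labels=list(ts.region_labels),
        sample_period=ts.sample_period,
        transient=ts.transient,
        mode_labels=list(ts.mode_labels),
    )


def downsample(ts: TimeSeries4D, tr: float) -> TimeSeries4D:
    """Keep samples aligned to a target repetition time ``tr`` (ms).

    The original simulation time base is retained in the sample metadata;
    ``tr`` must be at least the current sample period.
    """
    if tr < ts.sample_period:
        raise ValueError(
            f"target period {tr} ms is below the sample period {ts.sample_period} ms")
    every = int(round(tr / ts.sample_period))
    # floor(T_total / tr) samples, one per completed repetition interval
    idx = np.arange(every - 1, ts.n_times, every)
    return TimeSeries4D(
        data=ts.data[idx],
        time=ts.time[idx],
        state_labels=list(ts.state_labels),
        region_labels=list(ts.region_labels),
        sample_period=every * ts.sample_period,
        transient=ts.transient,
        mode_labels=list(ts.mode_labels),
    )


def functional_connectivity(ts: TimeSeries4D, state: Optional[str] = None,
                            use_transient: bool = False) -> np.ndarray:
    """Pairwise Pearson correlation matrix of regional time series.

    Regional traces of the selected state (default: the first) are z-scored
    along time and correlated pairwise; the matrix is symmetric with a unit
    diagonal, and the upper triangle is the conventionally reported set.
    Zero-variance regions yield NaN entries with a warning.
    """
    if not use_transient:
        ts = ts.post_transient()
    if ts.n_times < 3:
        raise ValueError("need at least 3 time samples for a correlation")
    si = ts.state_index(state) if state is not None else 0
    x = ts.data[:, si, :, 0]  # (T, R)
    sd = x.std(axis=0)
    # a constant trace accumulates ~1e-16 rounding in the mean; compare the
    # spread against the trace's own scale
    bad = sd <= 1e-12 * np.maximum(1.0, np.abs(x).max(axis=0))
    if bad.any():
        warnings.warn(f"zero-variance region(s) {np.flatnonzero(bad).tolist()}; "
                      "correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - x.mean(axis=0)) / sd
        fc = (z.T @ z) / x.shape[0]
    np.clip(fc, -1.0, 1.0, out=fc)
    fc[bad, :] = np.nan
    fc[:, bad] = np.nan
    np.fill_diagonal(fc, np.where(bad, np.nan, 1.0))
    return fc


def compare_fc(fc_a: np.ndarray, fc_b: np.ndarray):
    """Composite matrix (upper triangle a, lower triangle b) + summary.

    Returns ``(composite, max_abs_diff)`` where the summary is the maximum
    absolute off-diagonal difference between the two matrices.
    """
    fc_a, fc_b = np.asarray(fc_a, float), np.asarray(fc_b, float)
    if fc_a.shape != fc_b.shape or fc_a.ndim != 2 or fc_a.shape[0] != fc_a.shape[1]:
        raise ValueError(f"shape mismatch: {fc_a.shape} vs {fc_b.shape}")
    n = fc_a.shape[0]
    comp = np.eye(n)
    iu, il = np.triu_indices(n, 1), np.tril_indices(n, -1)
    comp[iu] = fc_a[iu]
    comp[il] = fc_b[il]
    if n < 2:
        return comp, 0.0
    off = ~np.eye(n, dtype=bool)
    return comp, float(np.nanmax(np.abs(fc_a - fc_b)[off]))


# ---------------------------------------------------------------------------
# observation graphs
# ---------------------------------------------------------------------------

@dataclass
class FunctionNode:
    """One step of an observation pipeline.

    ``op`` names a registered operator, or ``expression`` gives an
    elementwise symbolic expression over the input names.  ``states``
    optionally restricts the operator to a state subset.  ``software``
    records name+version strings for provenance.
    """

    name: str
    op: Optional[str] = None
    expression: Optional[str] = None
    inputs: list = field(default_factory=list)
    states: Optional[list] = None
    params: dict = field(default_factory=dict)
    software: list = field(default_factory=list)


@dataclass
class ObservationGraph:
    nodes: list

    def __post_init__(self):
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ObservationError("duplicate node names")

    def node(self, name):
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        names = {n.name for n in self.nodes}
        for n in self.nodes:
            g.add_node(n.name)
            for src in n.inputs:
                if src in names:
                    g.add_edge(src, n.name)
        return g


def _op_identity(node, args):
    return args[0]


def _op_select(node, args):
    ts = args[0]
    return ts.select_states(node.states or ts.state_labels)


def _op_hrf_convolve(node, args):
    ts = args[0]
    p = dict(node.params)
    kind = p.pop("kind", "canonical")
    dt_s = ts.sample_period / 1000.0  # hemodynamic constants are in seconds
    kernel = hrf_kernel(kind, p, dt=dt_s)
    return convolve_states(ts, kernel, states=node.states, kernel_dt=dt_s)


def _op_downsample(node, args):
    return downsample(args[0], tr=node.params["tr"])


def _op_fc(node, args):
    return functional_connectivity(
        args[0], state=(node.states[0] if node.states else None))


def _op_compare_fc(node, args):
    comp, diff = compare_fc(args[0], args[1])
    return {"composite": comp, "max_abs_diff": diff}


OPERATORS: Mapping[str, Callable] = {
    "identity": _op_identity,
    "select": _op_select,
    "hrf_convolve": _op_hrf_convolve,
    "downsample": _op_downsample,
    "functional_connectivity": _op_fc,
    "compare_fc": _op_compare_fc,
}


def _eval_expression_node(node, args, arg_names):
    expr = symbolic.parse_expression(node.expression, set(arg_names) | {"t"})
    arrays = {}
    time = None
    template = None
    for nm, a in zip(arg_names, args):
        if isinstance(a, TimeSeries4D):
            template = a
            time = a.time
            arrays[nm] = a.data
        else:
            arrays[nm] = expand_to_4d(np.asarray(a, float))
    fn = symbolic.lambdify_exprs(list(arrays) + ["t"], [expr.tree])
    tcol = (time[:, None, None, None] if time is not None else 0.0)
    out = fn(*arrays.values(), tcol)[0]
    out = np.broadcast_to(out, next(iter(arrays.values())).shape).astype(float)
    if template is not None:
        return TimeSeries4D(
            data=out.copy(), time=template.time,
            state_labels=list(template.state_labels),
            region_labels=list(template.region_labels),
            sample_period=template.sample_period,
            transient=template.transient,
            mode_labels=list(template.mode_labels),
        )
    return out


def execute(graph: ObservationGraph, inputs: Mapping[str, object],
            trace: Optional[list] = None) -> dict:
    """Run an observation graph; returns a map node name -> output.

    Nodes are evaluated exactly once each, in topological order, with
    memoized outputs (a diamond's shared upstream is computed once).
    TimeSeries inputs are already rank-4; plain arrays are expanded.
    ``trace``, if given, collects (node, input names) pairs for provenance.
    """
    g = graph.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise CycleError({u for u, v in cyc}, what="observation nodes")
    cache: dict = {}
    for k, v in inputs.items():
        cache[k] = v
    for name in nx.lexicographical_topological_sort(g):
        node = graph.node(name)
        if not node.inputs and name in cache:  # source node fed externally
            if trace is not None:
                trace.append((node, []))
            continue
        missing = [i for i in node.inputs if i not in cache]
        if missing:
            raise ObservationError(
                f"node {name!r} is missing input(s) {missing}; provide them in "
                "`inputs` or as upstream nodes")
        args = [cache[i] for i in node.inputs]
        for a in args:
            if isinstance(a, TimeSeries4D) and node.states:
                bad = set(node.states) - set(a.state_labels)
                if bad:
                    raise ObservationError(
                        f"node {name!r}: selector references unknown state(s) {sorted(bad)}")
        if node.op is not None:
            if node.op not in OPERATORS:
                raise ObservationError(f"unknown operator {node.op!r} in node {name!r}")
            cache[name] = OPERATORS[node.op](node, args)
        elif node.expression is not None:
            cache[name] = _eval_expression_node(node, args, node.inputs)
        else:
            raise ObservationError(f"node {name!r} has neither op nor expression")
        if trace is not None:
            trace.append((node, list(node.inputs)))
    return {n.name: cache[n.name] for n in graph.nodes if n.name in cache}


def bold_fc_graph(state: str, tr: Optional[float] = None,
                  hrf_kind: str = "canonical") -> ObservationGraph:
    """The standard BOLD forward pipeline ending in FC derivatives.

    raw -> HRF convolution -> (optional TR downsampling) -> FC(bold),
    plus an identical FC derivative on the raw signals for comparison.
    """
    nodes = [
        FunctionNode(name="raw", op="identity", inputs=["sim"]),
        FunctionNode(name="bold", op="hrf_convolve", inputs=["raw"],
                     states=[state], params={"kind": hrf_kind},
                     software=[f"numpy {np.__version__}", "scipy fftconvolve"]),
    ]
    tail = "bold"
    if tr is not None:
        nodes.append(FunctionNode(name="bold_tr", op="downsample",
                                  inputs=["bold"], params={"tr": tr}))
        tail = "bold_tr"
    nodes.append(FunctionNode(name="fc_bold", op="functional_connectivity",
                              inputs=[tail], states=[state]))
    nodes.append(FunctionNode(name="fc_raw", op="functional_connectivity",
                              inputs=["raw"], states=[state]))
    return ObservationGraph(nodes=nodes)
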