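"""Delay-buffered network simulation engine.

Executes a :class:`~neuromass.schema.SimulationExperiment`: per step, each
region reads delayed afferent states from a ring buffer, applies the
coupling's pre-synaptic transform per edge, forms the weighted afferent sum
agg_i = sum_j W_ij * pre(x_j(t - tau_ij), x_i(t)), applies the post-synaptic
transform, evaluates the local derivatives (with derived variables inlined
in topological order) plus any stimulus, and advances with the configured
scheme.  History is initialized constant at the initial state (the standard
delay-differential-equation convention); coupling reads history from
previous steps only, so there is no within-step simultaneity.

Stochastic integration (euler_maruyama) adds independent N(0, sigma^2 * dt)
increments per state and region, drawn from one generator seeded by the
integrator spec in a fixed (state, region) order, which makes replay under
a fixed seed bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import symbolic
from .errors import SimulationOverflowError
from .network import Connectome, compute_delays
from .schema import (
    CouplingSpec,
    DynamicsSpec,
    IntegratorSpec,
    MonitorSpec,
    SimulationExperiment,
    StimulusSpec,
    PulseTrain,
    SampledWaveform,
    resolve_coupling,
    validate,
)
from .timeseries import TimeSeries4D

OVERFLOW_BOUND = 1e10


# ---------------------------------------------------------------------------
# model compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledDynamics:
    """Numpy-backed derivative function compiled from the symbolic model."""

    model: DynamicsSpec
    param_names: list
    uses_stim: bool
    _f: Callable
    _out: Optional[Callable]

    def __call__(self, states, c_glob, stim, t, pvec):
        """Derivatives: states (ns, nr), c_glob (nr,), stim (nr,) -> (ns, nr)."""
        nr = states.shape[1]
        vals = self._f(*states, c_glob, 0.0, stim, t, *pvec)
        return np.stack([np.broadcast_to(np.asarray(v, float), (nr,)) for v in vals])

    def output(self, states, pvec):
        if self._out is None:
            return states[0]
        nr = states.shape[1]
        v = self._out(*states, 0.0, 0.0, 0.0, 0.0, *pvec)
        return np.broadcast_to(np.asarray(v, float), (nr,)).copy()

    def param_vector(self, overrides=None):
        base = self.model.parameter_values()
        if overrides:
            unknown = set(overrides) - set(base)
            if unknown:
                raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
            base = {**base, **overrides}
        return np.array([base[n] for n in self.param_names], dtype=float)


def compile_dynamics(model: DynamicsSpec) -> CompiledDynamics:
    """Inline derived variables and lambdify the per-state derivatives."""
    rhs = symbolic.inline_derivatives(model)
    uses_stim = any(
        symbolic.STIMULUS_SYMBOL in {str(s) for s in e.free_symbols} for e in rhs
    )
    arg_names = (
        list(model.state_names)
        + [*symbolic.COUPLING_SYMBOLS, symbolic.STIMULUS_SYMBOL, symbolic.TIME_SYMBOL]
        + list(model.parameter_names)
    )
    f = symbolic.lambdify_exprs(arg_names, rhs)
    out = None
    if model.output_expression is not None:
        tree = model.output_expression.tree.xreplace(
            dict(symbolic.derived_substitutions(model)))
        out = symbolic.lambdify_exprs(arg_names, [tree])
        _out_inner = out
        out = lambda *a: _out_inner(*a)[0]  # noqa: E731
    return CompiledDynamics(
        model=model,
        param_names=list(model.parameter_names),
        uses_stim=uses_stim,
        _f=f,
        _out=out,
    )


# ---------------------------------------------------------------------------
# coupling
# ---------------------------------------------------------------------------

def make_coupling(kind: str, params: Optional[dict] = None) -> CouplingSpec:
    """Construct a standard coupling: ``linear`` or ``sigmoidal``.

    linear:    pre = x_j, post = a * agg            (a: global gain)
    sigmoidal: pre = x_j,
               post = c_min + (c_max - c_min) / (1 + exp(-r*(agg - theta)))
    """
    params = dict(params or {})
    if kind == "linear":
        defaults = {"a": 0.5}
        pre, post = "x_j", "a*agg"
    elif kind == "sigmoidal":
        defaults = {"c_min": 0.0, "c_max": 0.005, "r": 0.56, "theta": 6.0}
        pre, post = "x_j", "c_min + (c_max - c_min)/(1 + exp(-r*(agg - theta)))"
    else:
        raise ValueError(f"unknown coupling kind {kind!r}")
    unknown = set(params) - set(defaults)
    if unknown:
        raise ValueError(f"unknown coupling parameter(s): {sorted(unknown)}")
    merged = {**defaults, **params}
    from .schema import Parameter

    spec = CouplingSpec(
        name=kind,
        pre=pre,
        post=post,
        parameters=[Parameter(name=k, value=v) for k, v in merged.items()],
    )
    resolve_coupling(spec)
    return spec


def _compile_coupling(coupling: CouplingSpec):
    if coupling.pre_expr is None or coupling.post_expr is None:
        violations = resolve_coupling(coupling)
        if violations:
            from .errors import SpecValidationError

            raise SpecValidationError(violations)
    pvals = coupling.parameter_values()
    pre_tree = coupling.pre_expr.tree.xreplace(
        {symbolic.sp.Symbol(k): v for k, v in pvals.items()})
    post_tree = coupling.post_expr.tree.xreplace(
        {symbolic.sp.Symbol(k): v for k, v in pvals.items()})
    pre = symbolic.lambdify_exprs(["x_j", "x_i"], [pre_tree])
    post = symbolic.lambdify_exprs(["agg"], [post_tree])
    return (
        lambda xj, xi: np.asarray(pre(xj, xi)[0], dtype=float),
        lambda agg: np.asarray(post(agg)[0], dtype=float),
    )


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def pulse_train(onset: float, period: float, width: float, amplitude: float,
                dt: float, duration: float) -> np.ndarray:
    """Rectangular pulse train sampled on the simulation grid.

    Value is ``amplitude`` on [onset + k*period, onset + k*period + width)
    for k = 0, 1, ... and 0 elsewhere; one sample per step, t = k*dt.
    """
    if width > period:
        raise ValueError(f"pulse width {width} exceeds period {period}")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    phase = t - onset
    on = (phase >= 0) & (np.mod(phase, period) < width)
    return np.where(on, amplitude, 0.0)


def resample_waveform(values, sample_rate: float, dt: float,
                      duration: float) -> np.ndarray:
    """Linearly resample a sampled signal onto the simulation grid.

    ``sample_rate`` is in samples per ms.  The result has duration/dt
    samples; the signal is truncated to the run duration and zero-padded
    if shorter.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty stimulus signal")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    src_t = np.arange(values.size) / sample_rate
    return np.interp(t, src_t, values, left=0.0, right=0.0)


def _stimulus_waveform(st: StimulusSpec, dt: float, duration: float) -> np.ndarray:
    if st.pulse is not None:
        p: PulseTrain = st.pulse
        return pulse_train(p.onset, p.period, p.width, p.amplitude, dt, duration)
    w: SampledWaveform = st.sampled
    return w.amplitude * resample_waveform(w.values, w.sample_rate, dt, duration)


def _region_weights(st: StimulusSpec, nr: int) -> np.ndarray:
    rw = st.region_weights
    if isinstance(rw, (int, float)):
        return np.full(nr, float(rw))
    return np.asarray(rw, dtype=float)


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------

class _Monitor:
    def __init__(self, spec: MonitorSpec, dt: float, n_steps: int, ns: int, nr: int):
        self.spec = spec
        period = spec.period if spec.period is not None else dt
        self.every = max(1, int(round(period / dt)))
        self.dt = dt
        if spec.kind == "temporal_average":
            self.n_out = n_steps // self.every
            self._acc = np.zeros((ns, nr))
        else:
            self.n_out = (n_steps + self.every - 1) // self.every
        self.samples = np.empty((self.n_out, ns, nr))
        self.times = np.empty(self.n_out)
        self._i = 0

    def record(self, k: int, x: np.ndarray):
        if self.spec.kind == "raw":
            if k % self.every == 0 and self._i < self.n_out:
                self.samples[self._i] = x
                self.times[self._i] = k * self.dt
                self._i += 1
        else:
            self._acc += x
            if (k + 1) % self.every == 0 and self._i < self.n_out:
                self.samples[self._i] = self._acc / self.every
                self.times[self._i] = (k + 1) * self.dt
                self._i += 1
                self._acc[:] = 0.0

    def finish(self, model, connectome, transient) -> TimeSeries4D:
        return TimeSeries4D(
            data=self.samples[: self._i, :, :, np.newaxis],
            time=self.times[: self._i],
            state_labels=list(model.state_names),
            region_labels=list(connectome.labels),
            sample_period=self.every * self.dt,
            transient=transient,
        )


def run(exp: SimulationExperiment,
        compiled: Optional[CompiledDynamics] = None,
        dfun_override: Optional[Callable] = None,
        param_overrides: Optional[dict] = None) -> dict:
    """Execute an experiment; returns a map monitor name -> TimeSeries4D.

    ``dfun_override`` replaces the symbolic derivative path with a callable
    of the same signature (used to cross-check generated code);
    ``param_overrides`` substitutes model parameter values without mutating
    the spec (used by parameter sweeps).
    """
    from .errors import SpecValidationError

    violations = validate(exp)
    if violations:
        raise SpecValidationError(violations)

    model = exp.dynamics
    conn: Connectome = exp.connectome
    integ: IntegratorSpec = exp.integrator
    dt = integ.dt
    n_steps = int(round(exp.duration / dt))
    ns, nr = len(model.states), conn.n

    if compiled is None:
        compiled = compile_dynamics(model)
    pvec = compiled.param_vector(param_overrides)
    f = dfun_override if dfun_override is not None else compiled

    pre_fn, post_fn = _compile_coupling(exp.coupling)
    delays = compute_delays(conn, exp.conduction_speed, dt)
    steps_m = delays.steps
    H = delays.horizon
    W = conn.weights
    cvar = model.coupling_variable or model.state_names[0]
    ci = model.state_names.index(cvar)
    col = np.arange(nr)[np.newaxis, :]

    # stimuli sampled on the grid
    stim_total = np.zeros((n_steps, nr))
    additive: dict[int, np.ndarray] = {}
    for st in exp.stimuli:
        wave = _stimulus_waveform(st, dt, exp.duration)
        arr = wave[:, np.newaxis] * _region_weights(st, nr)[np.newaxis, :]
        stim_total += arr
        ti = model.state_names.index(st.target_state)
        additive[ti] = additive.get(ti, np.zeros((n_steps, nr))) + arr

    sigma = integ.sigma_vector(ns)
    stochastic = integ.method == "euler_maruyama" and np.any(sigma > 0)
    rng = np.random.default_rng(integ.seed)
    discrete = model.system_type == "discrete"

    monitors = [_Monitor(m, dt, n_steps, ns, nr) for m in exp.monitors]
    x = np.tile(model.initial_state()[:, np.newaxis], (1, nr))
    buf = np.tile(x[ci], (H, 1))  # constant history

    zeros_nr = np.zeros(nr)

    def deriv_at(xs, hist_k, stim_k, t):
        # coupling always reads history written at steps <= hist_k
        buf_idx = (hist_k - steps_m) % H
        delayed = buf[buf_idx, col]
        pre_v = np.broadcast_to(pre_fn(delayed, xs[ci][:, np.newaxis]), (nr, nr))
        agg = (W * pre_v).sum(axis=1)
        cg = np.broadcast_to(post_fn(agg), (nr,))
        kk = min(stim_k, n_steps - 1)
        s_in = stim_total[kk] if compiled.uses_stim else zeros_nr
        d = f(xs, cg, s_in, t, pvec)
        if not compiled.uses_stim and additive:
            d = np.array(d, copy=True)
            for ti, arr in additive.items():
                d[ti] += arr[kk]
        return d

    for k in range(n_steps):
        buf[k % H] = x[ci]
        for mon in monitors:
            mon.record(k, x)
        t = k * dt
        d1 = deriv_at(x, k, k, t)
        if discrete:
            x_new = d1
        elif integ.method in ("euler", "euler_maruyama"):
            x_new = x + dt * d1
            if stochastic:
                x_new = x_new + np.sqrt(dt) * sigma[:, np.newaxis] * \
                    rng.standard_normal((ns, nr))
        elif integ.method == "heun":
            xp = x + dt * d1
            d2 = deriv_at(xp, k, k + 1, t + dt)
            x_new = x + 0.5 * dt * (d1 + d2)
        else:  # pragma: no cover - blocked by validation
            raise ValueError(integ.method)
        if not np.all(np.isfinite(x_new)) or np.max(np.abs(x_new)) > OVERFLOW_BOUND:
            raise SimulationOverflowError(k, t, OVERFLOW_BOUND)
        x = x_new

    return {mon.spec.name: mon.finish(model, conn, exp.transient) for mon in monitors}


# ---------------------------------------------------------------------------
# convenience builders
# ---------------------------------------------------------------------------

def single_node_experiment(model: DynamicsSpec, duration: float, dt: float = 0.1,
                           transient: float = 0.0, method: str = "heun",
                           seed: int = 0, stimuli: Optional[list] = None,
                           monitor_period: Optional[float] = None) -> SimulationExperiment:
    """An uncoupled single-region experiment around one model."""
    conn = Connectome(labels=["node_0"], weights=np.zeros((1, 1)),
                      tract_lengths=np.zeros((1, 1)))
    return SimulationExperiment(
        dynamics=model,
        connectome=conn,
        coupling=make_coupling("linear", {"a": 0.0}),
        integrator=IntegratorSpec(method=method, dt=dt, seed=seed),
        monitors=[MonitorSpec(name="raw", kind="raw", period=monitor_period)],
        stimuli=list(stimuli or []),
        duration=duration,
        transient=transient,
        conduction_speed=10.0,
    )
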