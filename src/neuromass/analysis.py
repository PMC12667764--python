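"""Bifurcation and regime analysis driven by the symbolic model.

Fixed points come from Newton iterations (multi-start over the declared
state domains) on the compiled single-node vector field, with stability
read off the eigenvalues of the symbolic Jacobian.  One-parameter
continuation traces fixed-point branches with natural-parameter stepping
(adaptive step in [ds_min, ds_max], Newton correction, bisection to locate
folds and stability changes), and detects limit cycles by integrating past
Hopf candidates and measuring sustained post-transient oscillation of the
variable of interest.

Regime classification distinguishes, per parameter value,
``quiescent`` (a single stable low-activity fixed point),
``bistable`` (two or more coexisting stable attractors) and
``oscillatory/overexcited`` (a stable limit cycle, or a single stable
high-activity fixed point); contiguous runs of one label form a regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import symbolic
from .engine import compile_dynamics, run, single_node_experiment
from .schema import DynamicsSpec

_FP_TOL = 1e-10
_MERGE_TOL = 1e-6
_BISECT_TOL = 1e-6
_CYCLE_P2P = 1e-6


# ---------------------------------------------------------------------------
# compiled single-node helpers
# ---------------------------------------------------------------------------

class _NodeSystem:
    """Single-node (uncoupled, unstimulated) vector field and Jacobian."""

    def __init__(self, model: DynamicsSpec):
        self.model = model
        self.compiled = compile_dynamics(model)
        self.n = len(model.states)
        rhs = symbolic.inline_derivatives(model)
        zero = {sp.Symbol(s): sp.Integer(0)
                for s in (*symbolic.COUPLING_SYMBOLS, symbolic.STIMULUS_SYMBOL)}
        rhs0 = [e.xreplace(zero) for e in rhs]
        args = list(model.state_names) + list(model.parameter_names)
        self._f = symbolic.lambdify_exprs(args, rhs0)
        jac_rows = []
        for f_i in rhs0:
            jac_rows.append([sp.diff(f_i, sp.Symbol(s)) for s in model.state_names])
        self._jac = symbolic.lambdify_exprs(args, [e for row in jac_rows for e in row])

    def f(self, x, pvec):
        with np.errstate(over="ignore", invalid="ignore"):
            return np.array(self._f(*x, *pvec), dtype=float)

    def jac(self, x, pvec):
        with np.errstate(over="ignore", invalid="ignore"):
            flat = np.array(self._jac(*x, *pvec), dtype=float)
        return flat.reshape(self.n, self.n)

    def pvec(self, overrides=None):
        return self.compiled.param_vector(overrides)

    def domains(self):
        lo, hi = [], []
        for sv in self.model.states:
            d = sv.domain
            lo.append(d.lo if d and d.lo is not None else -5.0)
            hi.append(d.hi if d and d.hi is not None else 5.0)
        return np.array(lo), np.array(hi)


@dataclass
class FixedPoint:
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool

    @property
    def max_real(self):
        return float(self.eigenvalues.real.max())


def _newton_root(sys_: _NodeSystem, x0, pvec):
    try:
        sol = root(lambda x: sys_.f(x, pvec), x0,
                   jac=lambda x: sys_.jac(x, pvec), method="hybr",
                   options={"xtol": 1e-13})
    except Exception:
        return None
    if not sol.success:
        return None
    x = sol.x
    if not np.all(np.isfinite(x)):
        return None
    if np.linalg.norm(sys_.f(x, pvec)) >= _FP_TOL:
        return None
    return x


def _classify_fp(sys_: _NodeSystem, x, pvec) -> FixedPoint:
    ev = np.linalg.eigvals(sys_.jac(x, pvec))
    return FixedPoint(state=np.asarray(x, float), eigenvalues=ev,
                      stable=bool(ev.real.max() < 0))


def find_fixed_points(model: DynamicsSpec, params: Optional[dict] = None,
                      search: Optional[Sequence] = None, n_random: int = 25,
                      seed: int = 0) -> list:
    """Fixed points of the uncoupled model at the given parameter values.

    Initial guesses combine the supplied ``search`` grid (if any) with
    ``n_random`` uniform draws over the declared state domains (fixed
    seed).  Converged roots with residual norm below 1e-10 are merged when
    closer than 1e-6; returns [] with a warning when nothing converges.
    """
    if model.system_type != "continuous":
        raise ValueError("fixed-point search requires a continuous system")
    sys_ = _NodeSystem(model)
    return _find_fixed_points(sys_, sys_.pvec(params), search, n_random, seed)


def _find_fixed_points(sys_: _NodeSystem, pvec, search=None, n_random=25,
                       seed=0, extra_starts=()) -> list:
    lo, hi = sys_.domains()
    rng = np.random.default_rng(seed)
    guesses = [np.asarray(g, float) for g in (search or [])]
    guesses += [np.asarray(g, float) for g in extra_starts]
    guesses += list(rng.uniform(lo, hi, size=(n_random, sys_.n)))
    found: list = []
    for g in guesses:
        x = _newton_root(sys_, g, pvec)
        if x is None:
            continue
        if any(np.linalg.norm(x - fp.state) < _MERGE_TOL * (1 + np.linalg.norm(x))
               for fp in found):
            continue
        found.append(_classify_fp(sys_, x, pvec))
    if not found:
        warnings.warn("no fixed point converged from any initial guess")
    return sorted(found, key=lambda fp: tuple(fp.state))


# ---------------------------------------------------------------------------
# continuation
# ---------------------------------------------------------------------------

@dataclass
class BranchPoint:
    param: float
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool


@dataclass
class SpecialPoint:
    kind: str          # "fold" | "hopf"
    param: float
    state: np.ndarray


@dataclass
class PeriodicOrbit:
    param: float
    minimum: float
    maximum: float

    @property
    def amplitude(self):
        return 0.5 * (self.maximum - self.minimum)


@dataclass
class RegimeSample:
    """Attractor inventory at one sampled parameter value."""

    param: float
    stable_outputs: list
    n_stable: int
    has_cycle: bool
    cycle_level: Optional[float] = None


@dataclass
class ContinuationResult:
    parameter: str
    lo: float
    hi: float
    variable_of_interest: str
    branch: list = field(default_factory=list)       # BranchPoint, sorted by param
    special_points: list = field(default_factory=list)
    periodic_orbits: list = field(default_factory=list)
    samples: list = field(default_factory=list)      # RegimeSample, sorted by param

    @property
    def folds(self):
        return [s for s in self.special_points if s.kind == "fold"]

    @property
    def hopf_candidates(self):
        return [s for s in self.special_points if s.kind == "hopf"]


def _voi_value(model: DynamicsSpec, voi: str, state: np.ndarray, pvec,
               sys_: _NodeSystem):
    """Value of the variable of interest (a state name or the output expr)."""
    names = model.state_names
    if voi in names:
        return float(state[names.index(voi)])
    # fall back to the model output expression
    return float(sys_.compiled.output(np.asarray(state)[:, None], pvec)[0])


def _march_branch(sys_, pvec_of, x0, p0, p_end, controls):
    """Natural-parameter continuation from (x0, p0) toward p_end.

    Adaptive step in [ds_min, ds_max]; Newton correction at each step; the
    march stops (at fold or domain end) when the step collapses below
    ds_min.  Returns (points, last_good, first_failed_param).
    """
    ds0 = max(controls.get("ds", 1e-8), controls.get("ds_min", 1e-10))
    ds_min = controls.get("ds_min", 1e-10)
    ds_max = controls.get("ds_max", 1e-2)
    direction = 1.0 if p_end >= p0 else -1.0
    ds = min(max(ds0, 1e-6), ds_max)
    p, x = p0, np.asarray(x0, float)
    pts = []
    while direction * (p_end - p) > 1e-12:
        step = min(ds, abs(p_end - p))
        cand = _newton_root(sys_, x, pvec_of(p + direction * step))
        if cand is not None and np.linalg.norm(cand - x) < 1.0 + 10 * np.linalg.norm(x):
            p = p + direction * step
            x = cand
            pts.append((p, x))
            ds = min(ds * 2.0, ds_max)
        else:
            ds = ds / 2.0
            if ds < ds_min:
                return pts, (p, x), p + direction * max(step, ds_min)
    return pts, (p, x), None


def _bisect_existence(sys_, pvec_of, x_good, p_good, p_bad, tol=_BISECT_TOL):
    """Refine a fold: bisection on whether a nearby root exists."""
    x = np.asarray(x_good, float)
    for _ in range(80):
        if abs(p_bad - p_good) < tol:
            break
        mid = 0.5 * (p_good + p_bad)
        cand = _newton_root(sys_, x, pvec_of(mid))
        if cand is not None and np.linalg.norm(cand - x) < 0.5 * (1 + np.linalg.norm(x)):
            p_good, x = mid, cand
        else:
            p_bad = mid
    return p_good, x


def _bisect_stability(sys_, pvec_of, xa, pa, xb, pb, tol=_BISECT_TOL):
    """Locate a stability change between two nearby branch points."""
    fa = _classify_fp(sys_, xa, pvec_of(pa)).stable
    x = np.asarray(xa, float)
    for _ in range(80):
        if abs(pb - pa) < tol:
            break
        mid = 0.5 * (pa + pb)
        cand = _newton_root(sys_, x, pvec_of(mid))
        if cand is None:
            break
        if _classify_fp(sys_, cand, pvec_of(mid)).stable == fa:
            pa, x = mid, cand
        else:
            pb = mid
    return 0.5 * (pa + pb), x


def _simulate_cycle(sys_: _NodeSystem, pvec, start, voi_fn, t_total=6000.0,
                    transient_frac=0.5):
    """Integrate from ``start``; return (sustained?, min, max, mean) of the VOI."""
    with np.errstate(over="ignore", invalid="ignore"):
        sol = solve_ivp(
            lambda t, y: sys_.f(y, pvec), (0.0, t_total), np.asarray(start, float),
            rtol=1e-8, atol=1e-10, max_step=t_total / 600.0, dense_output=False)
    if not sol.success or sol.y.shape[1] < 10:
        return False, np.nan, np.nan, np.nan
    voi = np.array([voi_fn(sol.y[:, i]) for i in range(sol.y.shape[1])])
    t = sol.t
    tail = voi[t >= transient_frac * t_total]
    mid = voi[(t >= 0.25 * t_total) & (t < transient_frac * t_total)]
    p2p_tail = float(tail.max() - tail.min()) if tail.size else 0.0
    p2p_mid = float(mid.max() - mid.min()) if mid.size else 0.0
    sustained = p2p_tail > _CYCLE_P2P and (p2p_mid == 0.0 or p2p_tail > 0.3 * p2p_mid)
    return sustained, float(tail.min()), float(tail.max()), float(tail.mean())


def continue_branch(model: DynamicsSpec, param: str, p_range, var_of_interest,
                    controls: Optional[dict] = None, detect_periodic: bool = False,
                    params: Optional[dict] = None, n_scan: Optional[int] = None,
                    n_starts: int = 25, seed: int = 0,
                    cycle_t: float = 6000.0, direction: int = 1) -> ContinuationResult:
    """Trace fixed-point branches of one parameter across a range.

    Seeds fixed points by multi-start Newton search at scan values across
    the range (catching disconnected branches), marches each seed with
    natural-parameter continuation at adaptive steps within
    [ds_min, ds_max], refines folds by existence bisection and stability
    changes by eigenvalue bisection (parameter tolerance 1e-6), and — when
    ``detect_periodic`` — estimates limit-cycle extrema of the variable of
    interest by long simulation wherever an unstable focus or an
    attractor-free region indicates one.
    """
    controls = dict(controls or {})
    controls.setdefault("ds", 1e-8)
    controls.setdefault("ds_min", 1e-10)
    controls.setdefault("ds_max", 1e-2)
    lo, hi = float(p_range[0]), float(p_range[1])
    if not lo < hi:
        raise ValueError("empty parameter range")
    sys_ = _NodeSystem(model)
    base = dict(params or {})
    if param not in model.parameter_names:
        raise KeyError(f"{param!r} is not a parameter of {model.name!r}")

    def pvec_of(p):
        return sys_.pvec({**base, param: p})

    def voi_fn(state):
        return _voi_value(model, var_of_interest, state, pvec_of(lo), sys_)

    if n_scan is None:
        n_scan = int(min(81, max(41, np.ceil((hi - lo) / controls["ds_max"]) + 1)))
    scan = np.linspace(lo, hi, n_scan)

    result = ContinuationResult(parameter=param, lo=lo, hi=hi,
                                variable_of_interest=var_of_interest)

    # 1) multi-start inventory at every scan value, warm-started by neighbors;
    #    `direction` only controls the order of the scan (continuation from
    #    the low or the high end), which classification must not depend on
    inv_map: dict = {}
    prev_states: list = []
    for p in (scan if direction >= 0 else scan[::-1]):
        fps = _find_fixed_points(sys_, pvec_of(p), n_random=n_starts, seed=seed,
                                 extra_starts=prev_states)
        inv_map[float(p)] = fps
        prev_states = [fp.state for fp in fps]
    inventory = [inv_map[float(p)] for p in scan]
    for p, fps in zip(scan, inventory):
        for fp in fps:
            result.branch.append(BranchPoint(
                param=float(p), state=fp.state, eigenvalues=fp.eigenvalues,
                stable=fp.stable))

    # 2) link fixed points across adjacent scan values; refine fold/stability
    def nearest(fps, x):
        if not fps:
            return None
        d = [np.linalg.norm(fp.state - x) for fp in fps]
        i = int(np.argmin(d))
        return fps[i] if d[i] < 0.5 * (1 + np.linalg.norm(x)) else None

    def refine_fold(x_seed, p_seed, p_target):
        # march toward the range end; a collapse of the adaptive step below
        # ds_min before reaching it brackets a fold, refined by bisection
        _, (pg, xg), p_fail = _march_branch(
            sys_, pvec_of, x_seed, p_seed, p_target, controls)
        if p_fail is None:
            return
        if abs(pg - p_target) < _BISECT_TOL:
            return
        p_bad = min((p_fail, p_target), key=lambda q: abs(q - pg))
        p_fold, x_fold = _bisect_existence(sys_, pvec_of, xg, pg, p_bad)
        result.special_points.append(SpecialPoint(
            kind="fold", param=float(p_fold), state=x_fold))

    for i, p in enumerate(scan):
        for fp in inventory[i]:
            if i + 1 < len(scan):
                nxt = nearest(inventory[i + 1], fp.state)
                if nxt is None:
                    refine_fold(fp.state, p, hi)
                elif nxt.stable != fp.stable:
                    p_c, x_c = _bisect_stability(
                        sys_, pvec_of, fp.state, p, nxt.state, scan[i + 1])
                    ev = np.linalg.eigvals(sys_.jac(x_c, pvec_of(p_c)))
                    near0 = ev[np.argsort(np.abs(ev.real))[:2]]
                    kind = "hopf" if np.any(np.abs(near0.imag) > 1e-8) else "fold"
                    result.special_points.append(SpecialPoint(
                        kind=kind, param=float(p_c), state=x_c))
            if i > 0 and nearest(inventory[i - 1], fp.state) is None:
                refine_fold(fp.state, p, lo)

    # deduplicate special points
    dedup: list = []
    for spt in sorted(result.special_points, key=lambda s: s.param):
        if not any(s.kind == spt.kind and abs(s.param - spt.param) < 1e-4
                   for s in dedup):
            dedup.append(spt)
    result.special_points = dedup

    # 3) regime samples (+ optional cycle detection by simulation)
    for p, fps in zip(scan, inventory):
        pvec = pvec_of(p)
        stable = [fp for fp in fps if fp.stable]
        outputs = [_voi_value(model, var_of_interest, fp.state, pvec, sys_)
                   for fp in stable]
        has_cycle = False
        cycle_level = None
        if detect_periodic:
            foci = [fp for fp in fps
                    if not fp.stable and np.any(np.abs(fp.eigenvalues.imag) > 1e-8)]
            starts = []
            for fp in foci:
                starts.append(fp.state + 1e-3 * (1 + np.abs(fp.state)))
            if not fps or (not stable and not foci):
                starts.append(sys_.compiled.model.initial_state())
            for st in starts:
                ok, mn, mx, mean = _simulate_cycle(sys_, pvec, st, voi_fn,
                                                   t_total=cycle_t)
                if ok:
                    has_cycle = True
                    cycle_level = mean
                    result.periodic_orbits.append(
                        PeriodicOrbit(param=float(p), minimum=mn, maximum=mx))
                    break
        result.samples.append(RegimeSample(
            param=float(p), stable_outputs=outputs, n_stable=len(stable),
            has_cycle=has_cycle, cycle_level=cycle_level))

    result.branch.sort(key=lambda b: b.param)
    result.samples.sort(key=lambda s: s.param)
    return result


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------

QUIESCENT = "monostable-quiescent"
BISTABLE = "bistable"
OVEREXCITED = "oscillatory/overexcited"


def classify_regimes(result: ContinuationResult):
    """Label each sampled parameter value and merge contiguous regimes.

    Returns ``(intervals, count)`` where ``intervals`` is an ordered list
    of ((param_lo, param_hi), label).  The quiescent/overexcited split for
    a single stable fixed point uses the midpoint of the smallest and
    largest stable-attractor level observed across the whole scan (the two
    branches are well separated in every bundled model).
    """
    if not result.samples:
        raise ValueError("continuation result has no samples")
    # The quiescent/overexcited distinction for a lone stable fixed point
    # requires the stable-level distribution to be genuinely bimodal: the
    # largest gap between sorted levels must dominate the overall spread.
    # A single attractor drifting continuously with the parameter has no
    # such gap and is classified as one quiescent regime.
    levels = sorted(o for s in result.samples for o in s.stable_outputs)
    threshold = None
    if len(levels) >= 2:
        spread = levels[-1] - levels[0]
        if spread > 1e-6:
            gaps = np.diff(levels)
            g = int(np.argmax(gaps))
            if gaps[g] > 0.25 * spread:
                threshold = 0.5 * (levels[g] + levels[g + 1])

    labels = []
    for s in result.samples:
        n_attr = s.n_stable + (1 if s.has_cycle else 0)
        if n_attr >= 2:
            labels.append(BISTABLE)
        elif s.has_cycle:
            labels.append(OVEREXCITED)
        elif s.n_stable == 1:
            high = threshold is not None and s.stable_outputs[0] > threshold
            labels.append(OVEREXCITED if high else QUIESCENT)
        else:
            labels.append(labels[-1] if labels else QUIESCENT)

    intervals = []
    start = result.samples[0].param
    cur = labels[0]
    for s, lab in zip(result.samples[1:], labels[1:]):
        if lab != cur:
            intervals.append(((start, s.param), cur))
            start, cur = s.param, lab
    intervals.append(((start, result.samples[-1].param), cur))
    return intervals, len(intervals)


# ---------------------------------------------------------------------------
# memoized 2-D sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    p1_name: str
    p1_values: np.ndarray
    p2_name: str
    p2_values: np.ndarray
    mean: np.ndarray
    maximum: np.ndarray
    variance: np.ndarray
    from_cache: np.ndarray  # bool grid: cell served from the memo cache

    @property
    def shape(self):
        return self.mean.shape


_SWEEP_CACHE: dict = {}


def clear_sweep_cache():
    _SWEEP_CACHE.clear()


def _cache_key(model_name, p1, v1, p2, v2, output, duration, transient):
    # parameter values are rounded to three decimals in the key
    return (model_name, p1, round(float(v1), 3), p2, round(float(v2), 3),
            output, float(duration), float(transient))


def sweep2d(model: DynamicsSpec, p1, p2, n1: int = 20, n2: int = 20,
            output_expr: Optional[str] = None, duration: float = 8000.0,
            transient: float = 2000.0, dt: float = 0.1,
            method: str = "heun", params: Optional[dict] = None) -> SweepResult:
    """Grid statistics of the model output over two parameter ranges.

    ``p1`` / ``p2`` are (name, lo, hi) triples; each cell simulates a
    single uncoupled node for ``duration`` ms, discards ``transient`` ms
    and records mean, maximum and variance of the output expression over
    the retained samples.  Results are memoized in-process keyed by model
    name, parameter names and 3-decimal-rounded values and the output
    expression; a cell that overflows is recorded as NaN and the sweep
    continues.
    """
    (n1_name, lo1, hi1), (n2_name, lo2, hi2) = p1, p2
    for nm in (n1_name, n2_name):
        if nm not in model.parameter_names:
            raise KeyError(f"{nm!r} is not a parameter of {model.name!r}")
    v1 = np.linspace(lo1, hi1, n1)
    v2 = np.linspace(lo2, hi2, n2)
    out_name = output_expr or model.output_expr or model.state_names[0]
    out_fn = _make_output_fn(model, out_name)
    compiled = compile_dynamics(model)
    base = dict(params or {})

    mean = np.full((n1, n2), np.nan)
    maxi = np.full((n1, n2), np.nan)
    var = np.full((n1, n2), np.nan)
    hit = np.zeros((n1, n2), dtype=bool)
    exp = single_node_experiment(model, duration=duration, dt=dt,
                                 transient=transient, method=method)
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            key = _cache_key(model.name, n1_name, a, n2_name, b, out_name,
                             duration, transient)
            if key in _SWEEP_CACHE:
                mean[i, j], maxi[i, j], var[i, j] = _SWEEP_CACHE[key]
                hit[i, j] = True
                continue
            overrides = {**base, n1_name: float(a), n2_name: float(b)}
            try:
                ts = run(exp, compiled=compiled,
                         param_overrides=overrides)["raw"].post_transient()
                y = out_fn(ts, overrides)
                cell = (float(y.mean()), float(y.max()), float(y.var()))
            except Exception:
                cell = (np.nan, np.nan, np.nan)
            _SWEEP_CACHE[key] = cell
            mean[i, j], maxi[i, j], var[i, j] = cell
    return SweepResult(p1_name=n1_name, p1_values=v1, p2_name=n2_name,
                       p2_values=v2, mean=mean, maximum=maxi, variance=var,
                       from_cache=hit)


def _make_output_fn(model: DynamicsSpec, output_expr: str):
    expr = symbolic.parse_expression(output_expr, model.known_symbols())
    tree = expr.tree.xreplace(dict(symbolic.derived_substitutions(model)))
    args = list(model.state_names) + list(model.parameter_names)
    fn = symbolic.lambdify_exprs(args, [tree])

    def evaluate(ts, overrides):
        vals = model.parameter_values()
        vals.update(overrides or {})
        states = [ts.data[:, i, :, 0] for i in range(len(model.states))]
        pv = [vals[n] for n in model.parameter_names]
        return np.broadcast_to(np.asarray(fn(*states, *pv)[0], float),
                               states[0].shape)

    return evaluate
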