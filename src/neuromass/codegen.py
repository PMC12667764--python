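"""Code generation: render a model into standalone source text.

A single target is supported: a plain numpy-compatible Python function
(``plain_function``; ``standalone_script`` wraps the same function with a
tiny driver).  Derived variables are emitted in topological order and
conditional equations as explicit branch chains (nested ``numpy.where``)
in declaration order, matching the symbolic evaluator's dispatch.  The
template layer is a set of string blocks, so adding a target means adding
a template, not touching the engine.

:func:`verify_equivalence` closes the loop: the generated function is
loaded and compared against the symbolic evaluation path at random
in-domain points.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import sympy as sp
from sympy.printing.numpy import NumPyPrinter

from . import symbolic
from .engine import compile_dynamics
from .errors import NeuromassError
from .schema import DynamicsSpec

TARGETS = ("plain_function", "standalone_script")


class CodegenError(NeuromassError):
    pass


class _Printer(NumPyPrinter):
    """NumPy printer emitting Piecewise as a declaration-order where-chain."""

    def _print_Piecewise(self, expr):
        out = None
        for tree, cond in reversed(expr.args):
            body = self._print(tree)
            if cond == sp.true:
                out = body
            elif out is None:
                out = body  # last branch acts as default
            else:
                out = f"numpy.where({self._print(cond)}, {body}, {out})"
        return out


@dataclass
class GeneratedArtifact:
    source: str
    target: str
    symbol_map: dict
    checksum: str

    def load(self):
        """Execute the source text and return the derivative function."""
        ns: dict = {}
        exec(compile(self.source, "<generated>", "exec"), ns)  # noqa: S102
        return ns["dynamics"]


_HEADER = '''"""Derivative function for the {name} model.

Generated from its declarative specification; signature
``dynamics(state, coupling, params, stimulus, t)`` where ``state`` is a
sequence of per-state arrays (or scalars), ``coupling`` the aggregated
network input, ``params`` an optional mapping overriding the defaults.
Returns the stacked derivative array.
"""
import numpy
import numpy as np

PARAM_DEFAULTS = {defaults}


def dynamics(state, coupling=0.0, params=None, stimulus=0.0, t=0.0):
    p = dict(PARAM_DEFAULTS)
    if params:
        p.update(params)
'''

_FOOTER_SCRIPT = '''

if __name__ == "__main__":
    import json
    state0 = [0.0] * {n_states}
    d = dynamics(state0)
    print(json.dumps({{"state": state0, "derivative": [float(v) for v in d]}}))
'''


def generate(model: DynamicsSpec, target: str = "plain_function") -> GeneratedArtifact:
    """Render the model's derivative function as standalone source text."""
    if target not in TARGETS:
        raise CodegenError(f"unknown target {target!r}; expected one of {TARGETS}")
    printer = _Printer()
    lines = []
    ind = "    "
    for i, s in enumerate(model.state_names):
        lines.append(f"{ind}{s} = state[{i}]")
    for pn in model.parameter_names:
        lines.append(f'{ind}{pn} = p["{pn}"]')
    lines.append(f"{ind}c_glob = coupling")
    lines.append(f"{ind}c_local = 0.0")
    lines.append(f"{ind}stim = stimulus")

    def emit(tree, context):
        try:
            code = printer.doprint(tree)
        except Exception as exc:
            raise CodegenError(
                f"unsupported construct in equation for {context!r}: {exc}") from None
        if "Not supported" in code:
            raise CodegenError(
                f"unsupported construct in equation for {context!r}")
        return code

    ordered = symbolic.order_derived(model.derived)
    groups: dict = {}
    names = []
    for eq in ordered:
        if eq.lhs not in groups:
            groups[eq.lhs] = []
            names.append(eq.lhs)
        groups[eq.lhs].append(eq)
    if names:
        lines.append(f"{ind}# derived variables (topological order)")
    for nm in names:
        tree = symbolic.branches_to_piecewise(groups[nm])
        lines.append(f"{ind}{nm} = {emit(tree, nm)}")

    lines.append(f"{ind}# state derivatives")
    dnames = []
    for s in model.state_names:
        eq = model.derivative_for(s)
        tree = symbolic.branches_to_piecewise(eq if isinstance(eq, list) else [eq])
        dn = f"d_{s}"
        dnames.append(dn)
        lines.append(f"{ind}{dn} = {emit(tree, s)}")
    lines.append(f"{ind}_shape = numpy.zeros_like(numpy.asarray(state[0], dtype=float))")
    joined = ", ".join(f"{d} + _shape" for d in dnames)
    lines.append(f"{ind}return numpy.stack([{joined}])")

    defaults = {p.name: p.value for p in model.parameters}
    missing = [k for k, v in defaults.items() if v is None]
    if missing:
        from .errors import NotReportedError

        raise NotReportedError(missing)
    source = _HEADER.format(name=model.name, defaults=repr(defaults))
    source += "\n".join(lines) + "\n"
    if target == "standalone_script":
        source += _FOOTER_SCRIPT.format(n_states=len(model.states))
    symbol_map = {n: n for n in (*model.state_names, *model.parameter_names)}
    checksum = hashlib.sha256(source.encode()).hexdigest()
    return GeneratedArtifact(source=source, target=target,
                             symbol_map=symbol_map, checksum=checksum)


@dataclass
class EquivalenceReport:
    n_points: int
    max_abs: float
    max_rel: float
    worst_point: Optional[np.ndarray]
    passed: bool


def verify_equivalence(model: DynamicsSpec, artifact: GeneratedArtifact,
                       n_points: int = 100, seed: int = 0,
                       rel_tol: float = 1e-10) -> EquivalenceReport:
    """Compare generated code against the symbolic evaluator.

    Samples ``n_points`` random states inside the declared domains (with
    random coupling and stimulus inputs) and reports the worst absolute
    and relative deviation; passes iff the relative deviation is at most
    ``rel_tol``.
    """
    try:
        fn = artifact.load()
    except Exception as exc:
        raise CodegenError(f"generated artifact failed to load: {exc}") from None
    if n_points <= 0:
        import warnings

        warnings.warn("verify_equivalence called with n_points=0: trivial pass")
        return EquivalenceReport(0, 0.0, 0.0, None, True)
    compiled = compile_dynamics(model)
    pvec = compiled.param_vector()
    rng = np.random.default_rng(seed)
    lo = np.array([s.domain.lo if s.domain and s.domain.lo is not None else -2.0
                   for s in model.states])
    hi = np.array([s.domain.hi if s.domain and s.domain.hi is not None else 2.0
                   for s in model.states])
    max_abs = max_rel = 0.0
    worst = None
    for _ in range(n_points):
        x = rng.uniform(lo, hi)
        cg = rng.uniform(-1, 1)
        stim_v = rng.uniform(-1, 1)
        ref = compiled(x[:, None], np.array([cg]), np.array([stim_v]), 0.0, pvec)[:, 0]
        got = np.asarray(fn(list(x), coupling=cg, stimulus=stim_v), dtype=float).ravel()
        adev = np.max(np.abs(got - ref))
        rdev = np.max(np.abs(got - ref) / np.maximum(np.abs(ref), 1e-12))
        if adev > max_abs:
            max_abs = adev
        if rdev > max_rel:
            max_rel, worst = rdev, x
    return EquivalenceReport(n_points=n_points, max_abs=float(max_abs),
                             max_rel=float(max_rel), worst_point=worst,
                             passed=bool(max_rel <= rel_tol))
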