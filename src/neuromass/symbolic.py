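"""Symbolic expression layer.

Every equation in a model specification is held in one normalized symbolic
form (a sympy tree) that single-sources numerical evaluation, Jacobians,
LaTeX rendering, code generation and dependency analysis.  The grammar is
deliberately small: infix arithmetic with ``**``, the function names listed
in :data:`ALLOWED_FUNCTIONS`, and plain identifiers.  ``t`` is the reserved
time symbol; ``c_glob``, ``c_local`` and ``stim`` are the reserved coupling-
and stimulus-input symbols injected by the engine.

Equality of :class:`Expression` objects is structural (sympy's canonical
ordering of commutative operands), not algebraic.
"""

from __future__ import annotations

import tokenize
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import sympy as sp
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

from .errors import (
    CycleError,
    ExpressionSyntaxError,
    NonDifferentiableError,
    UnknownSymbolError,
)

#: reserved symbols every model may reference without declaring them
TIME_SYMBOL = "t"
COUPLING_SYMBOLS = ("c_glob", "c_local")
STIMULUS_SYMBOL = "stim"
RESERVED_SYMBOLS = frozenset({TIME_SYMBOL, STIMULUS_SYMBOL, *COUPLING_SYMBOLS})

ALLOWED_FUNCTIONS = {
    "exp": sp.exp,
    "log": sp.log,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "sinh": sp.sinh,
    "cosh": sp.cosh,
    "tanh": sp.tanh,
    "sqrt": sp.sqrt,
    "abs": sp.Abs,
    "Abs": sp.Abs,
    "min": sp.Min,
    "max": sp.Max,
    "Min": sp.Min,
    "Max": sp.Max,
    "heaviside": lambda x: sp.Heaviside(x, 0),
    "Heaviside": sp.Heaviside,
    "pi": sp.pi,
}

_GLOBAL_DICT = {
    "Symbol": sp.Symbol,
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    "Function": sp.Function,  # unknown calls become AppliedUndef, rejected below
    **ALLOWED_FUNCTIONS,
}


@dataclass(frozen=True)
class Expression:
    """A parsed expression: a normalized sympy tree plus its free symbols."""

    tree: sp.Expr
    free_symbols: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.free_symbols:
            object.__setattr__(
                self,
                "free_symbols",
                frozenset(str(s) for s in self.tree.free_symbols),
            )

    def __eq__(self, other):
        if isinstance(other, Expression):
            return self.tree == other.tree
        return NotImplemented

    def __hash__(self):
        return hash(self.tree)

    def evaluate(self, bindings: Mapping[str, float]) -> float:
        """Evaluate at a full symbol binding; deterministic by construction."""
        subs = {sp.Symbol(k): v for k, v in bindings.items()}
        out = self.tree.xreplace(subs)
        return float(out)

    def __repr__(self):
        return f"Expression({sp.sstr(self.tree)})"


def parse_expression(text: str, known: Iterable[str]) -> Expression:
    """Parse ``text`` over the declared symbol set ``known``.

    Constants are folded (``2*3 + x`` parses equal to ``6 + x``).  Raises
    :class:`ExpressionSyntaxError` with a character position on malformed
    input and :class:`UnknownSymbolError` when a free symbol is neither in
    ``known`` nor reserved.
    """
    known = set(known)
    if not known:
        raise ValueError("known symbol set must be non-empty")
    local = {name: sp.Symbol(name) for name in known | RESERVED_SYMBOLS}
    # declared names shadow function names only if explicitly declared
    for fname in ALLOWED_FUNCTIONS:
        if fname in known:
            local[fname] = sp.Symbol(fname)
    # a plain-Python syntax check reports a truthful position in `text`
    # (sympy's own errors point into its transformed source); compiling in
    # eval mode executes nothing
    try:
        compile(text, "<expression>", "eval")
    except SyntaxError as exc:
        # a zero/absent offset means the parser ran off the end of the text
        pos = len(text) if not exc.offset else max(0, min(exc.offset - 1, len(text)))
        raise ExpressionSyntaxError(text, pos, exc.msg or "invalid syntax") from None
    try:
        tree = parse_expr(
            text,
            local_dict=local,
            global_dict=_GLOBAL_DICT,
            transformations=standard_transformations,
            evaluate=True,
        )
    except (SyntaxError, tokenize.TokenError) as exc:
        pos = getattr(exc, "offset", None)
        if pos is None:
            pos = len(text)
        pos = max(0, min(int(pos) - 1 if pos else 0, len(text)))
        raise ExpressionSyntaxError(text, pos, str(exc)) from None
    except Exception as exc:  # sympify errors on e.g. stray operators
        raise ExpressionSyntaxError(text, len(text) - 1, str(exc)) from None
    if not isinstance(tree, (sp.Expr, sp.logic.boolalg.Boolean)):
        raise ExpressionSyntaxError(text, 0, f"not an expression: {type(tree).__name__}")
    unknown = {str(s) for s in tree.free_symbols} - known - RESERVED_SYMBOLS
    unknown |= {f.func.__name__ for f in tree.atoms(sp.core.function.AppliedUndef)}
    if unknown:
        raise UnknownSymbolError(unknown, text)
    return Expression(sp.sympify(tree))


def render(expr: Expression | sp.Expr, dialect: str = "plain") -> str:
    """Render an expression; ``plain`` re-parses to an equal tree."""
    tree = expr.tree if isinstance(expr, Expression) else expr
    if dialect == "plain":
        return sp.sstr(tree)
    if dialect == "latex":
        return sp.latex(tree)
    raise ValueError(f"unknown dialect {dialect!r}")


def render_cases(branches: Sequence, dialect: str = "latex") -> str:
    """Render conditional branches of one equation.

    ``branches`` is a sequence of ``EquationDef``-like objects (``rhs_expr``,
    ``condition_expr``).  In LaTeX a ``cases`` construct is produced with one
    line per branch; in plain dialect a chained conditional string.
    """
    if dialect == "latex":
        lines = []
        for br in branches:
            rhs = sp.latex(br.rhs_expr.tree)
            if br.condition_expr is not None:
                lines.append(rf"{rhs} & \text{{if }} {sp.latex(br.condition_expr.tree)}")
            else:
                lines.append(rf"{rhs} & \text{{otherwise}}")
        body = r" \\ ".join(lines)
        return rf"\begin{{cases}} {body} \end{{cases}}"
    parts = []
    for br in branches:
        rhs = sp.sstr(br.rhs_expr.tree)
        if br.condition_expr is not None:
            parts.append(f"{rhs} if {sp.sstr(br.condition_expr.tree)}")
        else:
            parts.append(f"{rhs} otherwise")
    return "; ".join(parts)


def branches_to_piecewise(branches: Sequence) -> sp.Expr:
    """Collapse conditional branches (declaration order wins) to a Piecewise.

    The first branch whose condition holds is taken; a final unconditioned
    branch is the default.  A single unconditional branch returns its tree
    unchanged.
    """
    if len(branches) == 1 and branches[0].condition_expr is None:
        return branches[0].rhs_expr.tree
    pieces = []
    for br in branches:
        cond = sp.true if br.condition_expr is None else br.condition_expr.tree
        pieces.append((br.rhs_expr.tree, cond))
    if pieces[-1][1] is not sp.true:
        pieces.append((pieces[-1][0], sp.true))  # fall back to last branch
    return sp.Piecewise(*pieces)


def order_derived(derived: Sequence) -> list:
    """Topologically order derived-variable definitions.

    Ties are broken by declaration order (stable).  Conditional branches of
    the same left-hand side stay adjacent and keep their declaration order.
    Raises :class:`CycleError` listing the cycle members.
    """
    # group branches by lhs, keeping first-appearance order
    order_of: dict[str, int] = {}
    groups: dict[str, list] = {}
    for eq in derived:
        if eq.lhs not in groups:
            order_of[eq.lhs] = len(order_of)
            groups[eq.lhs] = []
        groups[eq.lhs].append(eq)

    deps: dict[str, set] = {}
    for name, eqs in groups.items():
        used = set()
        for eq in eqs:
            used |= eq.rhs_expr.free_symbols
            if eq.condition_expr is not None:
                used |= eq.condition_expr.free_symbols
        deps[name] = used & set(groups)

    # Kahn's algorithm with a declaration-order priority queue
    remaining = dict(deps)
    ready = sorted((n for n, d in remaining.items() if not d), key=order_of.get)
    out_names: list[str] = []
    while ready:
        n = ready.pop(0)
        out_names.append(n)
        del remaining[n]
        newly = []
        for m, d in remaining.items():
            d.discard(n)
            if not d and m not in ready and m not in newly:
                newly.append(m)
        ready = sorted(ready + newly, key=order_of.get)
    if remaining:
        raise CycleError(remaining.keys())
    out = []
    for name in out_names:
        out.extend(groups[name])
    return out


def derived_substitutions(model) -> list[tuple[sp.Symbol, sp.Expr]]:
    """Ordered (symbol, expression) pairs with earlier derived values inlined."""
    ordered = order_derived(model.derived)
    groups: dict[str, list] = {}
    names: list[str] = []
    for eq in ordered:
        if eq.lhs not in groups:
            groups[eq.lhs] = []
            names.append(eq.lhs)
        groups[eq.lhs].append(eq)
    subs: list[tuple[sp.Symbol, sp.Expr]] = []
    for name in names:
        tree = branches_to_piecewise(groups[name])
        for s, e in subs:
            tree = tree.xreplace({s: e})
        subs.append((sp.Symbol(name), tree))
    return subs


def inline_derivatives(model) -> list[sp.Expr]:
    """Per-state derivative trees with all derived variables inlined."""
    subs = derived_substitutions(model)
    rep = dict(subs)
    out = []
    for sv in model.states:
        eq = model.derivative_for(sv.name)
        tree = branches_to_piecewise(eq if isinstance(eq, list) else [eq])
        out.append(tree.xreplace(rep))
    return out


def jacobian(model, simplify: bool = False) -> list[list[Expression]]:
    """Symbolic Jacobian of the vector field: entry (i, j) = d(dS_i/dt)/dS_j.

    Derived variables are inlined first.  Non-smooth constructs (Heaviside
    steps whose derivative introduces a DiracDelta) raise
    :class:`NonDifferentiableError` naming the offending state equation.
    """
    if model.system_type != "continuous":
        raise ValueError("Jacobian requires a continuous system")
    rhs = inline_derivatives(model)
    state_syms = [sp.Symbol(sv.name) for sv in model.states]
    J: list[list[Expression]] = []
    for i, f in enumerate(rhs):
        row = []
        for s in state_syms:
            d = sp.diff(f, s)
            if d.has(sp.DiracDelta):
                raise NonDifferentiableError(model.states[i].name, "heaviside")
            if simplify:
                d = sp.simplify(d)
            row.append(Expression(d))
        J.append(row)
    return J


@dataclass
class DependencyGraph:
    """Directed graph: symbol -> equation (lhs) that uses it."""

    graph: nx.DiGraph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def dependency_graph(model) -> DependencyGraph:
    """Build the state/parameter/derived dependency graph of a model.

    One node per state, parameter and derived variable (attributes ``kind``
    and ``character``); an edge ``symbol -> lhs`` wherever the symbol appears
    in the equation defining ``lhs``.
    """
    g = nx.DiGraph()
    for sv in model.states:
        g.add_node(sv.name, kind="state", character="neutral")
    for p in model.parameters:
        g.add_node(p.name, kind="parameter", character=p.character)
    for eq in model.derived:
        if eq.lhs not in g:
            g.add_node(eq.lhs, kind="derived", character="neutral")
    declared = set(g.nodes)

    def add_edges(eq, target):
        used = set(eq.rhs_expr.free_symbols)
        if eq.condition_expr is not None:
            used |= eq.condition_expr.free_symbols
        for s in used & declared:
            g.add_edge(s, target)

    for eq in model.derived:
        add_edges(eq, eq.lhs)
    for eq in model.derivatives:
        add_edges(eq, eq.lhs)
    return DependencyGraph(g)


def lambdify_exprs(arg_names: Sequence[str], exprs: Sequence[sp.Expr]):
    """Compile expressions to a numpy-backed function of the named arguments."""
    args = [sp.Symbol(n) for n in arg_names]
    return sp.lambdify(args, list(exprs), modules=["numpy"])
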