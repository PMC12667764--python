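"""Symbolic layer: parsing, ordering, Jacobians, rendering, dependencies."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromass import symbolic
from neuromass.errors import (
    CycleError,
    ExpressionSyntaxError,
    NonDifferentiableError,
    UnknownSymbolError,
)
from neuromass.schema import EquationDef

from conftest import build_model


class TestParse:
    def test_free_symbols_of_polynomial_coupling_expression(self):
        known = {"d", "tau", "alpha", "W", "e", "V", "f"}
        ex = symbolic.parse_expression("d*tau*(alpha*W + e*V**2 - f*V**3)", known)
        assert ex.free_symbols == frozenset(known)

    def test_syntax_error_carries_position(self):
        with pytest.raises(ExpressionSyntaxError) as ei:
            symbolic.parse_expression("V + ", {"V"})
        assert isinstance(ei.value.position, int)
        assert 2 <= ei.value.position <= 4
        assert "position" in str(ei.value)

    def test_constants_are_folded(self):
        a = symbolic.parse_expression("2*3 + x", {"x"})
        b = symbolic.parse_expression("6 + x", {"x"})
        assert a == b

    def test_unknown_symbol_is_named(self):
        with pytest.raises(UnknownSymbolError) as ei:
            symbolic.parse_expression("x + Q", {"x"})
        assert ei.value.symbols == ["Q"]

    def test_unknown_function_rejected(self):
        with pytest.raises(UnknownSymbolError):
            symbolic.parse_expression("foo(x)", {"x"})

    def test_time_symbol_is_reserved(self):
        ex = symbolic.parse_expression("sin(t) + x", {"x"})
        assert "t" in ex.free_symbols

    def test_parsing_is_side_effect_free(self):
        # names that would be dangerous under unrestricted evaluation parse
        # as inert symbols (and are then rejected as unknown)
        with pytest.raises(UnknownSymbolError):
            symbolic.parse_expression("__import__ + x", {"x"})

    def test_declared_name_shadows_function(self):
        # a model may declare a parameter named like a function (e.g. 'e')
        ex = symbolic.parse_expression("e*x", {"e", "x"})
        assert ex.free_symbols == frozenset({"e", "x"})

    @given(st.integers(-50, 50), st.integers(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_constant_folding_matches_arithmetic(self, a, b):
        ex = symbolic.parse_expression(f"({a}) + ({b}) + x", {"x"})
        expected = symbolic.parse_expression(f"{a + b} + x", {"x"})
        assert ex == expected


class TestOrderDerived:
    @staticmethod
    def eq(lhs, rhs, known):
        e = EquationDef(lhs=lhs, rhs=rhs)
        e.rhs_expr = symbolic.parse_expression(rhs, known)
        return e

    def test_dependency_puts_definition_first(self):
        known = {"a", "b"}
        out = symbolic.order_derived(
            [self.eq("b", "a + 1", known), self.eq("a", "2", known)])
        assert [e.lhs for e in out] == ["a", "b"]

    def test_cycle_lists_members(self):
        known = {"a", "b"}
        with pytest.raises(CycleError) as ei:
            symbolic.order_derived(
                [self.eq("a", "b", known), self.eq("b", "a", known)])
        assert set(ei.value.members) == {"a", "b"}

    def test_independent_definitions_keep_declaration_order(self):
        known = {"p", "q"}
        out = symbolic.order_derived(
            [self.eq("p", "1", known), self.eq("q", "2", known)])
        assert [e.lhs for e in out] == ["p", "q"]


class TestJacobian:
    def test_linear_decay(self, decay_model):
        J = symbolic.jacobian(decay_model)
        assert J[0][0].tree == sp.Integer(-1)

    def test_polynomial_rule(self):
        m = build_model([("V", "e*V**2 - f*V**3")], states=("V",),
                        params=(("e", 3.0), ("f", 1.0)))
        J = symbolic.jacobian(m)
        V, e, f = sp.symbols("V e f")
        assert sp.simplify(J[0][0].tree - (2 * e * V - 3 * f * V**2)) == 0

    def test_heaviside_raises_named_error(self):
        m = build_model([("x", "heaviside(x)")])
        with pytest.raises(NonDifferentiableError) as ei:
            symbolic.jacobian(m)
        assert ei.value.equation == "x"

    def test_g2d_jacobian_matches_finite_differences(self, generic2d):
        # independent oracle: central finite differences of the compiled rhs
        from neuromass.engine import compile_dynamics

        J = symbolic.jacobian(generic2d)
        compiled = compile_dynamics(generic2d)
        pvec = compiled.param_vector()
        pnames = generic2d.parameter_names
        bind = dict(zip(pnames, pvec))
        x0 = np.array([0.0, 0.0])
        eps = 1e-6

        def f(x):
            return compiled(x[:, None], np.zeros(1), np.zeros(1), 0.0, pvec)[:, 0]

        for i in range(2):
            for j in range(2):
                xp, xm = x0.copy(), x0.copy()
                xp[j] += eps
                xm[j] -= eps
                fd = (f(xp)[i] - f(xm)[i]) / (2 * eps)
                sym = J[i][j].evaluate(
                    {**bind, "V": x0[0], "W": x0[1]})
                assert abs(fd - sym) <= 1e-6

    @pytest.mark.parametrize("model_name", [
        "generic2d", "jansen_rit", "reduced_wong_wang", "kuramoto"])
    def test_jacobian_matches_finite_differences_at_random_points(self, model_name):
        from neuromass import get_model
        from neuromass.analysis import _NodeSystem

        model = get_model(model_name)
        sys_ = _NodeSystem(model)
        pvec = sys_.pvec()
        rng = np.random.default_rng(0)
        n = sys_.n
        for _ in range(20):
            x = rng.uniform(-0.3, 0.3, size=n)
            J = sys_.jac(x, pvec)
            eps = 1e-6
            for j in range(n):
                xp, xm = x.copy(), x.copy()
                xp[j] += eps
                xm[j] -= eps
                fd = (sys_.f(xp, pvec) - sys_.f(xm, pvec)) / (2 * eps)
                assert np.allclose(J[:, j], fd, atol=1e-5), (model_name, x)


class TestRender:
    def test_plain_round_trip(self):
        ex = symbolic.parse_expression("a*x**2", {"a", "x"})
        text = symbolic.render(ex, "plain")
        assert symbolic.parse_expression(text, {"a", "x"}) == ex

    def test_plain_render_is_idempotent(self):
        ex = symbolic.parse_expression("(x + y)*(x - y)/z", {"x", "y", "z"})
        once = symbolic.render(ex, "plain")
        twice = symbolic.render(
            symbolic.parse_expression(once, {"x", "y", "z"}), "plain")
        assert once == twice

    def test_latex_power(self):
        ex = symbolic.parse_expression("x**2", {"x"})
        assert "^{2}" in symbolic.render(ex, "latex")

    def test_conditional_equation_renders_cases(self):
        known = {"x"}
        b1 = EquationDef(lhs="y", rhs="x", condition="x > 0")
        b1.rhs_expr = symbolic.parse_expression("x", known)
        b1.condition_expr = symbolic.parse_expression("x > 0", known)
        b2 = EquationDef(lhs="y", rhs="0")
        b2.rhs_expr = symbolic.parse_expression("0", known)
        tex = symbolic.render_cases([b1, b2], "latex")
        assert r"\begin{cases}" in tex and tex.count("&") == 2

    @given(st.sampled_from(["x + y", "x*y - 2", "x**3/(1 + y**2)", "exp(-x)*y"]))
    @settings(max_examples=8, deadline=None)
    def test_render_parse_round_trip_property(self, text):
        known = {"x", "y"}
        ex = symbolic.parse_expression(text, known)
        assert symbolic.parse_expression(symbolic.render(ex, "plain"), known) == ex


class TestDependencyGraph:
    def test_g2d_node_counts(self, generic2d):
        g = symbolic.dependency_graph(generic2d)
        kinds = [d["kind"] for _, d in g.graph.nodes(data=True)]
        assert kinds.count("state") == 2
        assert kinds.count("parameter") == 12

    def test_single_state_self_edge(self, decay_model):
        g = symbolic.dependency_graph(decay_model)
        assert list(g.graph.nodes) == ["x"]
        assert g.graph.has_edge("x", "x")

    def test_jansen_rit_characters(self, jansen_rit):
        g = symbolic.dependency_graph(jansen_rit)
        assert g.graph.nodes["A"]["character"] == "excitatory"
        assert g.graph.nodes["B"]["character"] == "inhibitory"


# hand-coded reference implementations (independent of the symbolic layer)

def _ref_generic2d(x, p):
    V, W = x
    return np.array([
        p["d"] * p["tau"] * (-p["f"] * V**3 + p["e"] * V**2 + p["g"] * V
                             + p["alpha"] * W + p["gamma"] * p["I"]),
        p["d"] * (p["a"] + p["b"] * V + p["c"] * V**2 - p["beta"] * W) / p["tau"],
    ])


def _ref_jansen_rit(x, p):
    y0, y1, y2, y3, y4, y5 = x
    C1, C2, C3, C4 = p["C"], 0.8 * p["C"], 0.25 * p["C"], 0.25 * p["C"]

    def S(v):
        return 2 * p["e0"] / (1 + np.exp(p["r"] * (p["v0"] - v)))

    A, B, a, b = p["A"], p["B"], p["a"], p["b"]
    return np.array([
        y3, y4, y5,
        A * a * S(y1 - y2) - 2 * a * y3 - a**2 * y0,
        A * a * (p["mu"] + C2 * S(C1 * y0)) - 2 * a * y4 - a**2 * y1,
        B * b * C4 * S(C3 * y0) - 2 * b * y5 - b**2 * y2,
    ])


def _ref_reduced_wong_wang(x, p):
    Se, Si = x

    def H(v, aa, bb, dd):
        u = aa * v - bb
        return u / (1 - np.exp(-dd * u))

    xe = p["W_e"] * p["I_o"] + p["w_p"] * p["J_N"] * Se - p["J_i"] * Si + p["I_ext"]
    xi = p["W_i"] * p["I_o"] + p["J_N"] * Se - Si
    re = H(xe, p["a_e"], p["b_e"], p["d_e"])
    ri = H(xi, p["a_i"], p["b_i"], p["d_i"])
    return np.array([
        -Se / p["tau_e"] + (1 - Se) * p["gamma_e"] * re,
        -Si / p["tau_i"] + p["gamma_i"] * ri,
    ])


def _ref_kuramoto(x, p):
    return np.array([p["omega"]])


_REFERENCES = {
    "generic2d": _ref_generic2d,
    "jansen_rit": _ref_jansen_rit,
    "reduced_wong_wang": _ref_reduced_wong_wang,
    "kuramoto": _ref_kuramoto,
}


@pytest.mark.parametrize("model_name", sorted(_REFERENCES))
def test_bundled_rhs_matches_hand_coded_reference(model_name):
    """Every bundled model's symbolic rhs agrees with an independently
    hand-coded reference function at 100 random state bindings."""
    from neuromass import get_model
    from neuromass.analysis import _NodeSystem

    model = get_model(model_name)
    sys_ = _NodeSystem(model)
    pvec = sys_.pvec()
    p = dict(zip(model.parameter_names, pvec))
    rng = np.random.default_rng(42)
    for _ in range(100):
        x = rng.uniform(-0.8, 0.8, size=sys_.n)
        got = sys_.f(x, pvec)
        ref = _REFERENCES[model_name](x, p)
        denom = np.maximum(np.abs(ref), 1e-12)
        assert np.max(np.abs(got - ref) / denom) <= 1e-12
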