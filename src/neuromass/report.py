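"""Human-readable model reports rendered from the specification itself.

Parameter tables and equation summaries are generated solely from the
:class:`~neuromass.schema.DynamicsSpec` — the same object that drives
simulation, analysis and code generation — so documentation cannot drift
from execution.  Markdown and LaTeX are supported.
"""

from __future__ import annotations

from . import symbolic
from .schema import DynamicsSpec


def _group_branches(eqs):
    groups, order = {}, []
    for eq in eqs:
        if eq.lhs not in groups:
            groups[eq.lhs] = []
            order.append(eq.lhs)
        groups[eq.lhs].append(eq)
    return [(lhs, groups[lhs]) for lhs in order]


def _equation_latex(lhs: str, branches, derivative: bool) -> str:
    left = rf"\frac{{d\,{lhs}}}{{dt}}" if derivative else lhs
    if len(branches) == 1 and branches[0].condition_expr is None:
        eq = branches[0]
        rhs = eq.latex if eq.latex else symbolic.render(eq.rhs_expr, "latex")
    else:
        rhs = symbolic.render_cases(branches, "latex")
    return f"{left} = {rhs}"


def _fmt_value(p):
    return "not reported" if p.value is None else f"{p.value:g}"


def model_report(model: DynamicsSpec, format: str = "markdown") -> str:
    """Render a model sheet: parameter table, equations, references."""
    if format not in ("markdown", "latex"):
        raise ValueError(f"unknown format {format!r}")
    deriv_eqs = [_equation_latex(lhs, br, True)
                 for lhs, br in _group_branches(model.derivatives)]
    derived_eqs = [_equation_latex(lhs, br, False)
                   for lhs, br in _group_branches(model.derived)]

    if format == "markdown":
        lines = [f"# Model report: {model.name}", ""]
        if model.notes:
            lines += [model.notes.strip(), ""]
        lines += [f"System type: {model.system_type}; "
                  f"{len(model.states)} state variable(s), "
                  f"{len(model.parameters)} parameter(s).", ""]
        lines += ["## Parameters", ""]
        lines += ["| symbol | value | unit | description |",
                  "|---|---|---|---|"]
        for p in model.parameters:
            lines.append(
                f"| {p.symbol} | {_fmt_value(p)} | {p.unit or '—'} | "
                f"{p.description or '—'} |")
        lines += ["", "## State variables", ""]
        lines += ["| name | symbol | unit | initial |", "|---|---|---|---|"]
        for s in model.states:
            lines.append(f"| {s.name} | {s.symbol} | {s.unit or '—'} | {s.initial:g} |")
        if derived_eqs:
            lines += ["", "## Derived variables", ""]
            lines += [f"$${eq}$$" for eq in derived_eqs]
        lines += ["", "## Equations of motion", ""]
        lines += [f"$${eq}$$" for eq in deriv_eqs]
        if model.output_expr:
            lines += ["", f"Output expression: `{model.output_expr}`"]
        if model.stimulation_variable:
            lines += ["", f"Designated stimulation variable: `{model.stimulation_variable}`"]
        if model.references:
            lines += ["", "## References", ""]
            lines += [f"- {k}" for k in model.references]
        return "\n".join(lines) + "\n"

    # LaTeX
    lines = [rf"\section*{{Model report: {model.name}}}", ""]
    lines += [r"\begin{tabular}{llll}",
              r"symbol & value & unit & description \\ \hline"]
    for p in model.parameters:
        lines.append(rf"${p.symbol}$ & {_fmt_value(p)} & {p.unit or '--'} & "
                     rf"{p.description or '--'} \\")
    lines += [r"\end{tabular}", ""]
    lines += [r"\begin{align*}"]
    for eq in derived_eqs + deriv_eqs:
        lines.append(eq + r" \\")
    lines += [r"\end{align*}", ""]
    if model.references:
        lines += [r"\noindent References: " + ", ".join(model.references)]
    return "\n".join(lines) + "\n"
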