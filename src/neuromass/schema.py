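"""Declarative model / experiment specification: types, YAML I/O, validation.

A specification is a human-readable YAML document with top-level keys
``dynamics``, ``connectome``, ``coupling``, ``integrator``, ``stimuli``,
``monitors``, ``duration_ms``, ``transient_ms`` (plus ``conduction_speed``).
Loading parses every expression into the symbolic layer and resolves every
cross-reference; validation returns machine-readable violation records
rather than raising per defect, so a malformed file reports all of its
problems at once.

Unknown keys are preserved on round trip (forward compatibility) but are
ignored computationally, with a logged warning.  A parameter may mark its
value as ``not_reported``; such a spec validates but refuses to execute
until a value is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import symbolic
from .errors import (
    CycleError,
    ExpressionSyntaxError,
    SpecValidationError,
    UnknownSymbolError,
)
from .network import Connectome, ConnectomeError, read_connectome

log = logging.getLogger(__name__)

SYSTEM_TYPES = ("continuous", "discrete")
PARAMETER_CHARACTERS = ("excitatory", "inhibitory", "neutral")
INTEGRATOR_METHODS = ("euler", "heun", "euler_maruyama")
STOCHASTIC_METHODS = ("euler_maruyama",)
MONITOR_KINDS = ("raw", "temporal_average")
STIMULUS_KINDS = ("pulse_train", "sampled")

# Closed enumerations carried by the metadata format.  Only SystemType
# affects computation (discrete systems step as maps, not ODEs); the rest
# keep entries comparable across specs.
IMAGING_MODALITIES = ("fmri", "eeg", "meg", "none")
BOUNDARY_CONDITION_TYPES = ("none", "periodic", "dirichlet", "neumann")
DISCRETIZATION_METHODS = ("none", "finite_difference", "finite_element")
OPERATOR_TYPES = ("function", "convolution", "derivative")
ELEMENT_TYPES = ("region", "vertex")


@dataclass(frozen=True)
class Violation:
    """One validation defect: a machine-readable code and the field path."""

    code: str
    path: str
    message: str


@dataclass
class Domain:
    lo: Optional[float] = None
    hi: Optional[float] = None
    step: Optional[float] = None

    @classmethod
    def from_dict(cls, d):
        if d is None:
            return None
        return cls(lo=d.get("lo"), hi=d.get("hi"), step=d.get("step"))

    def to_dict(self):
        out = {}
        if self.lo is not None:
            out["lo"] = self.lo
        if self.hi is not None:
            out["hi"] = self.hi
        if self.step is not None:
            out["step"] = self.step
        return out


@dataclass
class StateVariable:
    name: str
    symbol: str = ""
    unit: str = ""
    domain: Optional[Domain] = None
    initial: float = 0.0

    def __post_init__(self):
        if not self.symbol:
            self.symbol = self.name

    @classmethod
    def from_dict(cls, d):
        return cls(
            name=d["name"],
            symbol=d.get("symbol", d["name"]),
            unit=d.get("unit", ""),
            domain=Domain.from_dict(d.get("domain")),
            initial=float(d.get("initial", 0.0)),
        )

    def to_dict(self):
        out = {"name": self.name, "symbol": self.symbol}
        if self.unit:
            out["unit"] = self.unit
        if self.domain is not None:
            out["domain"] = self.domain.to_dict()
        out["initial"] = self.initial
        return out


@dataclass
class Parameter:
    name: str
    value: Optional[float]
    symbol: str = ""
    unit: str = ""
    domain: Optional[Domain] = None
    description: str = ""
    character: str = "neutral"
    not_reported: bool = False

    def __post_init__(self):
        if not self.symbol:
            self.symbol = self.name

    @classmethod
    def from_dict(cls, d):
        raw = d.get("value")
        not_reported = raw == "not_reported" or d.get("not_reported", False)
        value = None if not_reported or raw is None else float(raw)
        return cls(
            name=d["name"],
            value=value,
            symbol=d.get("symbol", d["name"]),
            unit=d.get("unit", ""),
            domain=Domain.from_dict(d.get("domain")),
            description=d.get("description", ""),
            character=d.get("character", "neutral"),
            not_reported=not_reported,
        )

    def to_dict(self):
        out = {"name": self.name, "symbol": self.symbol}
        out["value"] = "not_reported" if self.not_reported else self.value
        if self.unit:
            out["unit"] = self.unit
        if self.domain is not None:
            out["domain"] = self.domain.to_dict()
        if self.description:
            out["description"] = self.description
        if self.character != "neutral":
            out["character"] = self.character
        return out


@dataclass
class EquationDef:
    """One equation: lhs identifier, rhs text, optional condition and LaTeX.

    Conditional branches for one lhs are dispatched in declaration order;
    the first satisfied condition wins and a final unconditioned branch is
    the default.  ``rhs_expr`` / ``condition_expr`` hold the parsed symbolic
    form once the spec is resolved.
    """

    lhs: str
    rhs: str
    condition: Optional[str] = None
    latex: Optional[str] = None
    rhs_expr: Optional[symbolic.Expression] = field(default=None, compare=False, repr=False)
    condition_expr: Optional[symbolic.Expression] = field(default=None, compare=False, repr=False)

    @classmethod
    def from_dict(cls, d):
        return cls(
            lhs=d["lhs"],
            rhs=str(d["rhs"]),
            condition=d.get("condition"),
            latex=d.get("latex"),
        )

    def to_dict(self):
        out = {"lhs": self.lhs, "rhs": self.rhs}
        if self.condition is not None:
            out["condition"] = self.condition
        if self.latex is not None:
            out["latex"] = self.latex
        return out


@dataclass
class DynamicsSpec:
    """A neural mass model: states, parameters, derived variables, derivatives."""

    name: str
    states: list
    parameters: list
    derivatives: list
    derived: list = field(default_factory=list)
    system_type: str = "continuous"
    output_expr: Optional[str] = None
    stimulation_variable: Optional[str] = None
    coupling_variable: Optional[str] = None
    references: list = field(default_factory=list)
    notes: str = ""
    extra: dict = field(default_factory=dict, compare=False)
    output_expression: Optional[symbolic.Expression] = field(
        default=None, compare=False, repr=False
    )

    # -- symbol bookkeeping -------------------------------------------------
    @property
    def state_names(self):
        return [s.name for s in self.states]

    @property
    def parameter_names(self):
        return [p.name for p in self.parameters]

    @property
    def derived_names(self):
        seen = []
        for eq in self.derived:
            if eq.lhs not in seen:
                seen.append(eq.lhs)
        return seen

    def known_symbols(self):
        return set(self.state_names) | set(self.parameter_names) | set(self.derived_names)

    def derivative_for(self, state_name):
        eqs = [eq for eq in self.derivatives if eq.lhs == state_name]
        if not eqs:
            raise KeyError(f"no derivative equation for state {state_name!r}")
        return eqs if len(eqs) > 1 else eqs[0]

    def parameter(self, name):
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def parameter_values(self):
        from .errors import NotReportedError

        missing = [p.name for p in self.parameters if p.value is None]
        if missing:
            raise NotReportedError(missing)
        return {p.name: p.value for p in self.parameters}

    def initial_state(self):
        return np.array([s.initial for s in self.states], dtype=float)

    # -- serialization ------------------------------------------------------
    @classmethod
    def from_dict(cls, d):
        known_keys = {
            "name", "system_type", "states", "parameters", "derived",
            "derivatives", "output_expr", "stimulation_variable",
            "coupling_variable", "references", "notes",
        }
        extra = {k: v for k, v in d.items() if k not in known_keys}
        if extra:
            log.warning("ignoring unknown dynamics keys: %s", sorted(extra))
        spec = cls(
            name=d.get("name", "unnamed"),
            system_type=d.get("system_type", "continuous"),
            states=[StateVariable.from_dict(s) for s in d.get("states", [])],
            parameters=[Parameter.from_dict(p) for p in d.get("parameters", [])],
            derived=[EquationDef.from_dict(e) for e in d.get("derived", [])],
            derivatives=[EquationDef.from_dict(e) for e in d.get("derivatives", [])],
            output_expr=d.get("output_expr"),
            stimulation_variable=d.get("stimulation_variable"),
            coupling_variable=d.get("coupling_variable"),
            references=list(d.get("references", [])),
            notes=d.get("notes", ""),
            extra=extra,
        )
        return spec

    def to_dict(self):
        out = {
            "name": self.name,
            "system_type": self.system_type,
            "states": [s.to_dict() for s in self.states],
            "parameters": [p.to_dict() for p in self.parameters],
        }
        if self.derived:
            out["derived"] = [e.to_dict() for e in self.derived]
        out["derivatives"] = [e.to_dict() for e in self.derivatives]
        if self.output_expr is not None:
            out["output_expr"] = self.output_expr
        if self.stimulation_variable is not None:
            out["stimulation_variable"] = self.stimulation_variable
        if self.coupling_variable is not None:
            out["coupling_variable"] = self.coupling_variable
        if self.references:
            out["references"] = list(self.references)
        if self.notes:
            out["notes"] = self.notes
        out.update(self.extra)
        return out


@dataclass
class CouplingSpec:
    """Pre/sum/post decomposition of inter-regional coupling.

    ``pre`` transforms each delayed afferent signal (symbols ``x_j``:
    delayed source state, ``x_i``: local state); the engine forms the
    weighted sum over afferents; ``post`` transforms the aggregate
    (symbol ``agg``).  Parameters (e.g. the global gain) may appear in
    either expression.
    """

    name: str
    pre: str
    post: str
    parameters: list = field(default_factory=list)
    pre_expr: Optional[symbolic.Expression] = field(default=None, compare=False, repr=False)
    post_expr: Optional[symbolic.Expression] = field(default=None, compare=False, repr=False)

    @classmethod
    def from_dict(cls, d):
        return cls(
            name=d.get("name", "coupling"),
            pre=str(d.get("pre", "x_j")),
            post=str(d.get("post", "agg")),
            parameters=[Parameter.from_dict(p) for p in d.get("parameters", [])],
        )

    def to_dict(self):
        out = {"name": self.name, "pre": self.pre, "post": self.post}
        if self.parameters:
            out["parameters"] = [p.to_dict() for p in self.parameters]
        return out

    def parameter_values(self):
        return {p.name: p.value for p in self.parameters}


@dataclass
class IntegratorSpec:
    method: str = "heun"
    dt: float = 0.1
    noise_sigma: Union[float, Sequence[float]] = 0.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d):
        return cls(
            method=d.get("method", "heun"),
            dt=float(d.get("dt", 0.1)),
            noise_sigma=d.get("noise_sigma", 0.0),
            seed=int(d.get("seed", 0)),
        )

    def to_dict(self):
        out = {"method": self.method, "dt": self.dt}
        if np.any(np.asarray(self.noise_sigma) != 0):
            out["noise_sigma"] = (
                list(self.noise_sigma)
                if isinstance(self.noise_sigma, (list, tuple))
                else self.noise_sigma
            )
        out["seed"] = self.seed
        return out

    def sigma_vector(self, n_states):
        sig = np.asarray(self.noise_sigma, dtype=float)
        if sig.ndim == 0:
            sig = np.full(n_states, float(sig))
        return sig


@dataclass
class PulseTrain:
    onset: float
    period: float
    width: float
    amplitude: float

    @classmethod
    def from_dict(cls, d):
        return cls(
            onset=float(d["onset"]),
            period=float(d["period"]),
            width=float(d["width"]),
            amplitude=float(d["amplitude"]),
        )

    def to_dict(self):
        return {
            "onset": self.onset,
            "period": self.period,
            "width": self.width,
            "amplitude": self.amplitude,
        }


@dataclass
class SampledWaveform:
    values: list
    sample_rate: float  # samples per ms
    amplitude: float = 1.0

    @classmethod
    def from_dict(cls, d):
        return cls(
            values=[float(v) for v in d["values"]],
            sample_rate=float(d["sample_rate"]),
            amplitude=float(d.get("amplitude", 1.0)),
        )

    def to_dict(self):
        return {
            "values": list(self.values),
            "sample_rate": self.sample_rate,
            "amplitude": self.amplitude,
        }


@dataclass
class StimulusSpec:
    """A targeted external input: pulse train or sampled waveform.

    Exactly one of ``pulse`` / ``sampled`` is populated.  ``region_weights``
    spatially weights the input per region (a scalar applies everywhere);
    ``target_state`` names the state whose derivative receives the input.
    """

    kind: str
    target_state: str
    pulse: Optional[PulseTrain] = None
    sampled: Optional[SampledWaveform] = None
    region_weights: Union[float, list] = 1.0

    @classmethod
    def from_dict(cls, d):
        return cls(
            kind=d.get("kind", "pulse_train"),
            target_state=d.get("target_state", ""),
            pulse=PulseTrain.from_dict(d["pulse"]) if "pulse" in d else None,
            sampled=SampledWaveform.from_dict(d["sampled"]) if "sampled" in d else None,
            region_weights=d.get("region_weights", 1.0),
        )

    def to_dict(self):
        out = {"kind": self.kind, "target_state": self.target_state}
        if self.pulse is not None:
            out["pulse"] = self.pulse.to_dict()
        if self.sampled is not None:
            out["sampled"] = self.sampled.to_dict()
        if not (isinstance(self.region_weights, float) and self.region_weights == 1.0):
            out["region_weights"] = (
                list(self.region_weights)
                if isinstance(self.region_weights, (list, tuple, np.ndarray))
                else self.region_weights
            )
        return out


@dataclass
class MonitorSpec:
    name: str = "raw"
    kind: str = "raw"
    period: Optional[float] = None  # ms; defaults to integrator dt

    @classmethod
    def from_dict(cls, d):
        if isinstance(d, str):
            return cls(name=d, kind=d)
        return cls(
            name=d.get("name", d.get("kind", "raw")),
            kind=d.get("kind", "raw"),
            period=float(d["period"]) if d.get("period") is not None else None,
        )

    def to_dict(self):
        out = {"name": self.name, "kind": self.kind}
        if self.period is not None:
            out["period"] = self.period
        return out


@dataclass
class SimulationExperiment:
    """The complete run contract for one simulation."""

    dynamics: DynamicsSpec
    connectome: Connectome
    coupling: CouplingSpec
    integrator: IntegratorSpec
    monitors: list
    duration: float
    transient: float = 0.0
    conduction_speed: float = 10.0
    stimuli: list = field(default_factory=list)
    software_requirements: list = field(default_factory=list)
    citation: Optional[str] = None
    extra: dict = field(default_factory=dict, compare=False)

    def to_dict(self):
        out = {
            "dynamics": self.dynamics.to_dict(),
            "connectome": {
                "labels": list(self.connectome.labels),
                "weights": self.connectome.weights.tolist(),
                "tract_lengths": self.connectome.tract_lengths.tolist(),
            },
            "coupling": self.coupling.to_dict(),
            "conduction_speed": self.conduction_speed,
            "integrator": self.integrator.to_dict(),
            "stimuli": [s.to_dict() for s in self.stimuli],
            "monitors": [m.to_dict() for m in self.monitors],
            "duration_ms": self.duration,
            "transient_ms": self.transient,
        }
        if self.connectome.parcellation:
            out["connectome"]["parcellation"] = self.connectome.parcellation
        if self.software_requirements:
            out["software_requirements"] = list(self.software_requirements)
        if self.citation:
            out["citation"] = self.citation
        out.update(self.extra)
        return out

    def __eq__(self, other):
        if not isinstance(other, SimulationExperiment):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# resolution: parse every expression against the declared symbol sets
# ---------------------------------------------------------------------------

def _parse_into(eq: EquationDef, known, path: str, violations: list) -> None:
    try:
        eq.rhs_expr = symbolic.parse_expression(eq.rhs, known)
    except UnknownSymbolError as exc:
        violations.append(Violation(
            "unresolved_symbol", path,
            f"equation for {eq.lhs!r}: unknown symbol(s) {', '.join(exc.symbols)}",
        ))
    except ExpressionSyntaxError as exc:
        violations.append(Violation(
            "syntax_error", path,
            f"equation for {eq.lhs!r}: {exc}",
        ))
    if eq.condition is not None:
        try:
            eq.condition_expr = symbolic.parse_expression(eq.condition, known)
        except (UnknownSymbolError, ExpressionSyntaxError) as exc:
            violations.append(Violation(
                "syntax_error" if isinstance(exc, ExpressionSyntaxError) else "unresolved_symbol",
                path, f"condition for {eq.lhs!r}: {exc}",
            ))


def resolve_dynamics(spec: DynamicsSpec) -> list:
    """Parse all equations of a model; returns violation records."""
    violations: list = []
    known = spec.known_symbols()
    if not known:
        return [Violation("missing_role", "dynamics", "model declares no symbols")]
    for i, eq in enumerate(spec.derived):
        _parse_into(eq, known, f"dynamics.derived[{i}]", violations)
    for i, eq in enumerate(spec.derivatives):
        _parse_into(eq, known, f"dynamics.derivatives[{i}]", violations)
    if spec.output_expr is not None:
        try:
            spec.output_expression = symbolic.parse_expression(spec.output_expr, known)
        except (UnknownSymbolError, ExpressionSyntaxError) as exc:
            violations.append(Violation(
                "unresolved_symbol", "dynamics.output_expr", str(exc)))
    return violations


def resolve_coupling(c: CouplingSpec) -> list:
    violations: list = []
    pnames = {p.name for p in c.parameters}
    try:
        c.pre_expr = symbolic.parse_expression(c.pre, {"x_j", "x_i"} | pnames)
        bad = c.pre_expr.free_symbols - {"x_j", "x_i"} - pnames
        if bad:
            raise UnknownSymbolError(bad, c.pre)
    except (UnknownSymbolError, ExpressionSyntaxError) as exc:
        violations.append(Violation("coupling_symbol", "coupling.pre", str(exc)))
    try:
        c.post_expr = symbolic.parse_expression(c.post, {"agg"} | pnames)
        bad = c.post_expr.free_symbols - {"agg"} - pnames
        if bad:
            raise UnknownSymbolError(bad, c.post)
    except (UnknownSymbolError, ExpressionSyntaxError) as exc:
        violations.append(Violation("coupling_symbol", "coupling.post", str(exc)))
    return violations


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _validate_names(items, path, violations):
    seen = set()
    for it in items:
        if it.name in seen:
            violations.append(Violation(
                "duplicate_name", path, f"name {it.name!r} declared more than once"))
        seen.add(it.name)


def validate_dynamics(spec: DynamicsSpec) -> list:
    violations: list = []
    if spec.system_type not in SYSTEM_TYPES:
        violations.append(Violation(
            "invalid_enum", "dynamics.system_type",
            f"{spec.system_type!r} not in {SYSTEM_TYPES}"))
    if not spec.states:
        violations.append(Violation("missing_role", "dynamics.states", "no state variables"))
    _validate_names(spec.states, "dynamics.states", violations)
    _validate_names(spec.parameters, "dynamics.parameters", violations)
    for sv in spec.states:
        if sv.name in symbolic.RESERVED_SYMBOLS:
            violations.append(Violation(
                "reserved_symbol", "dynamics.states",
                f"state {sv.name!r} shadows a reserved symbol"))
    for p in spec.parameters:
        if p.name in symbolic.RESERVED_SYMBOLS:
            violations.append(Violation(
                "reserved_symbol", "dynamics.parameters",
                f"parameter {p.name!r} shadows a reserved symbol"))
        if p.character not in PARAMETER_CHARACTERS:
            violations.append(Violation(
                "invalid_enum", f"dynamics.parameters.{p.name}.character",
                f"{p.character!r} not in {PARAMETER_CHARACTERS}"))
    # domains
    for coll, base in ((spec.states, "states"), (spec.parameters, "parameters")):
        for it in coll:
            d = it.domain
            if d and d.lo is not None and d.hi is not None and d.lo > d.hi:
                violations.append(Violation(
                    "domain_invalid", f"dynamics.{base}.{it.name}.domain",
                    f"lo {d.lo} > hi {d.hi}"))
    for p in spec.parameters:
        d = p.domain
        if d and p.value is not None:
            if (d.lo is not None and p.value < d.lo) or (d.hi is not None and p.value > d.hi):
                violations.append(Violation(
                    "value_out_of_domain", f"dynamics.parameters.{p.name}",
                    f"value {p.value} outside [{d.lo}, {d.hi}]"))
    # one derivative per state
    deriv_lhs = [eq.lhs for eq in spec.derivatives]
    for sv in spec.states:
        k = deriv_lhs.count(sv.name)
        if k == 0:
            violations.append(Violation(
                "missing_derivative", "dynamics.derivatives",
                f"no derivative equation for state {sv.name!r}"))
    for lhs in deriv_lhs:
        if lhs not in spec.state_names:
            violations.append(Violation(
                "unknown_state", "dynamics.derivatives",
                f"derivative declared for unknown state {lhs!r}"))
    # derived acyclicity (only meaningful once expressions resolved)
    if all(eq.rhs_expr is not None for eq in spec.derived):
        try:
            symbolic.order_derived(spec.derived)
        except CycleError as exc:
            violations.append(Violation(
                "derived_cycle", "dynamics.derived",
                f"cycle among {{{', '.join(exc.members)}}}"))
    # cross-references
    for attr, role in (("stimulation_variable", "stimulation_variable"),
                       ("coupling_variable", "coupling_variable")):
        val = getattr(spec, attr)
        if val is not None and val not in spec.state_names:
            violations.append(Violation(
                "unknown_state", f"dynamics.{attr}",
                f"{role} {val!r} is not a declared state"))
    return violations


def validate(exp: SimulationExperiment) -> list:
    """Check every invariant; returns a (possibly empty) list of violations."""
    violations: list = []
    violations += validate_dynamics(exp.dynamics)
    # connectome is validated on construction; re-check shape vs labels defensively
    try:
        from .network import validate_connectome

        validate_connectome(exp.connectome)
    except ConnectomeError as exc:
        violations.append(Violation("connectome_invalid", "connectome", str(exc)))
    if exp.coupling.pre_expr is None or exp.coupling.post_expr is None:
        violations += resolve_coupling(exp.coupling)
    if exp.integrator.method not in INTEGRATOR_METHODS:
        violations.append(Violation(
            "invalid_enum", "integrator.method",
            f"{exp.integrator.method!r} not in {INTEGRATOR_METHODS}"))
    if exp.integrator.dt <= 0:
        violations.append(Violation(
            "dt_not_positive", "integrator.dt", f"dt = {exp.integrator.dt}"))
    sig = np.asarray(exp.integrator.noise_sigma, dtype=float)
    if np.any(sig < 0):
        violations.append(Violation(
            "noise_negative", "integrator.noise_sigma", "negative noise amplitude"))
    if np.any(sig != 0) and exp.integrator.method not in STOCHASTIC_METHODS:
        violations.append(Violation(
            "noise_without_stochastic_method", "integrator.noise_sigma",
            f"noise_sigma nonzero but method is {exp.integrator.method!r}"))
    if not exp.monitors:
        violations.append(Violation("missing_role", "monitors", "no monitors declared"))
    for i, m in enumerate(exp.monitors):
        if m.kind not in MONITOR_KINDS:
            violations.append(Violation(
                "invalid_enum", f"monitors[{i}].kind",
                f"{m.kind!r} not in {MONITOR_KINDS}"))
        if m.period is not None and m.period < exp.integrator.dt:
            violations.append(Violation(
                "monitor_period_lt_dt", f"monitors[{i}].period",
                f"period {m.period} < dt {exp.integrator.dt}"))
    if not exp.transient < exp.duration:
        violations.append(Violation(
            "transient_not_lt_duration", "transient_ms",
            f"transient {exp.transient} must be < duration {exp.duration}"))
    if exp.duration <= 0:
        violations.append(Violation(
            "duration_not_positive", "duration_ms", f"duration = {exp.duration}"))
    if exp.conduction_speed <= 0:
        violations.append(Violation(
            "conduction_speed_not_positive", "conduction_speed",
            f"conduction_speed = {exp.conduction_speed}"))
    for i, st in enumerate(exp.stimuli):
        if st.kind not in STIMULUS_KINDS:
            violations.append(Violation(
                "invalid_enum", f"stimuli[{i}].kind",
                f"{st.kind!r} not in {STIMULUS_KINDS}"))
        has_pulse, has_sampled = st.pulse is not None, st.sampled is not None
        if has_pulse == has_sampled:
            violations.append(Violation(
                "stimulus_kind_ambiguous", f"stimuli[{i}]",
                "exactly one of pulse/sampled must be populated"))
        if has_pulse and st.pulse.width > st.pulse.period:
            violations.append(Violation(
                "pulse_width_exceeds_period", f"stimuli[{i}].pulse",
                f"width {st.pulse.width} > period {st.pulse.period}"))
        if st.target_state not in exp.dynamics.state_names:
            violations.append(Violation(
                "unknown_target_state", f"stimuli[{i}].target_state",
                f"{st.target_state!r} is not a state of {exp.dynamics.name!r}"))
        rw = st.region_weights
        if isinstance(rw, (list, tuple)) and len(rw) != exp.connectome.n:
            violations.append(Violation(
                "region_weights_mismatch", f"stimuli[{i}].region_weights",
                f"{len(rw)} weights for {exp.connectome.n} regions"))
    return violations


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

REQUIRED_ROLES = ("dynamics", "connectome", "coupling", "integrator", "monitors")


def load_dynamics(source) -> DynamicsSpec:
    """Load and resolve a DynamicsSpec from a YAML path, mapping or name.

    Raises :class:`SpecValidationError` if the model has defects.
    """
    if isinstance(source, (str, Path)) and str(source).endswith((".yaml", ".yml")):
        data = yaml.safe_load(Path(source).read_text())
        if "dynamics" in data and "states" not in data:
            data = data["dynamics"]
    elif isinstance(source, dict):
        data = source
    else:
        from .library import get_model

        return get_model(str(source))
    spec = DynamicsSpec.from_dict(data)
    violations = resolve_dynamics(spec) + validate_dynamics(spec)
    if violations:
        raise SpecValidationError(violations)
    return spec


def _build_connectome(d, base_dir: Path, violations: list):
    if d is None:
        return None
    try:
        if "weights_path" in d:
            return read_connectome(
                base_dir / d["weights_path"],
                base_dir / d["lengths_path"],
                base_dir / d["labels_path"],
                parcellation=d.get("parcellation"),
            )
        return Connectome(
            labels=d["labels"],
            weights=d["weights"],
            tract_lengths=d["tract_lengths"],
            parcellation=d.get("parcellation"),
        )
    except (KeyError, ConnectomeError, OSError) as exc:
        violations.append(Violation("connectome_invalid", "connectome", str(exc)))
        return None


EXPERIMENT_KEYS = {
    "dynamics", "connectome", "coupling", "integrator", "stimuli", "monitors",
    "duration_ms", "transient_ms", "conduction_speed",
    "software_requirements", "citation",
}


def build_experiment(data: dict, base_dir: Path = Path(".")) -> SimulationExperiment:
    """Assemble and fully validate an experiment from a parsed mapping."""
    violations: list = []
    if not isinstance(data, dict):
        raise SpecValidationError(
            [Violation("parse_error", "", "experiment file is not a mapping")])
    for role in REQUIRED_ROLES:
        if role not in data or data[role] in (None, [], {}):
            violations.append(Violation(
                "missing_role", role, f"required role {role!r} is absent"))
    if "duration_ms" not in data:
        violations.append(Violation(
            "missing_role", "duration_ms", "required role 'duration_ms' is absent"))
    if violations:
        raise SpecValidationError(violations)

    extra = {k: v for k, v in data.items() if k not in EXPERIMENT_KEYS}
    if extra:
        log.warning("ignoring unknown experiment keys: %s", sorted(extra))

    dyn_src = data["dynamics"]
    if isinstance(dyn_src, str):
        if dyn_src.endswith((".yaml", ".yml")):
            dynamics = DynamicsSpec.from_dict(
                yaml.safe_load((base_dir / dyn_src).read_text()))
        else:
            from .library import get_model

            dynamics = get_model(dyn_src)
    else:
        dynamics = DynamicsSpec.from_dict(dyn_src)
    violations += resolve_dynamics(dynamics)

    connectome = _build_connectome(data.get("connectome"), base_dir, violations)
    coupling = CouplingSpec.from_dict(data["coupling"])
    violations += resolve_coupling(coupling)
    integrator = IntegratorSpec.from_dict(data["integrator"])
    stimuli = [StimulusSpec.from_dict(s) for s in data.get("stimuli", [])]
    monitors = [MonitorSpec.from_dict(m) for m in data.get("monitors", [])]

    if connectome is None:
        raise SpecValidationError(violations)

    exp = SimulationExperiment(
        dynamics=dynamics,
        connectome=connectome,
        coupling=coupling,
        integrator=integrator,
        stimuli=stimuli,
        monitors=monitors,
        duration=float(data["duration_ms"]),
        transient=float(data.get("transient_ms", 0.0)),
        conduction_speed=float(data.get("conduction_speed", 10.0)),
        software_requirements=list(data.get("software_requirements", [])),
        citation=data.get("citation"),
        extra=extra,
    )
    violations += validate(exp)
    if violations:
        raise SpecValidationError(violations)
    return exp


def load_experiment(path) -> SimulationExperiment:
    """Load, parse, resolve and validate an experiment YAML file."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SpecValidationError(
            [Violation("parse_error", str(path), str(exc))]) from None
    return build_experiment(data, base_dir=path.parent)


def write_experiment(exp: SimulationExperiment, path) -> None:
    """Write an experiment so that :func:`load_experiment` round-trips it."""
    violations = validate(exp)
    if violations:
        raise SpecValidationError(violations)
    text = yaml.safe_dump(exp.to_dict(), allow_unicode=True, sort_keys=False)
    Path(path).write_text(text)
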