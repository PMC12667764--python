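"""Shared fixtures: small models, connectomes and experiment builders."""

import numpy as np
import pytest

from neuromass import (
    IntegratorSpec,
    MonitorSpec,
    SimulationExperiment,
    get_model,
    make_coupling,
    synthetic_connectome,
)
from neuromass.schema import DynamicsSpec, resolve_dynamics, validate_dynamics


def build_model(derivatives, states=("x",), params=(), derived=(), **kw):
    """Assemble and resolve a small DynamicsSpec from terse tuples."""
    d = {
        "name": kw.pop("name", "testmodel"),
        "states": [
            {"name": s, "initial": kw.get("initial", {}).get(s, 0.0),
             "domain": {"lo": -3.0, "hi": 3.0}}
            for s in states
        ],
        "parameters": [
            {"name": n, "value": v, "domain": {"lo": -100.0, "hi": 100.0}}
            for n, v in params
        ],
        "derived": [{"lhs": l, "rhs": r} for l, r in derived],
        "derivatives": [{"lhs": l, "rhs": r} for l, r in derivatives],
    }
    d.update({k: v for k, v in kw.items() if k != "initial"})
    spec = DynamicsSpec.from_dict(d)
    violations = resolve_dynamics(spec) + validate_dynamics(spec)
    assert not violations, violations
    return spec


@pytest.fixture
def linear_model():
    """dx/dt = -k*x + c + c_glob: closed-form steady state c/k."""
    return build_model(
        [("x", "-k*x + c + c_glob")],
        params=(("k", 1.0), ("c", 0.0)),
        initial={"x": 1.0},
    )


@pytest.fixture
def decay_model():
    """dx/dt = -x from x(0) = 1: trajectory e^{-t}."""
    return build_model([("x", "-x")], initial={"x": 1.0})


@pytest.fixture
def generic2d():
    return get_model("generic2d")


@pytest.fixture
def jansen_rit():
    return get_model("jansen_rit")


@pytest.fixture
def small_connectome():
    return synthetic_connectome(4, density=1.0, length_scale=50.0, seed=7)


def make_experiment(model, connectome, *, gain=0.1, dt=0.5, duration=500.0,
                    transient=0.0, method="heun", seed=0, stimuli=(),
                    conduction_speed=10.0, coupling=None):
    return SimulationExperiment(
        dynamics=model,
        connectome=connectome,
        coupling=coupling if coupling is not None
        else make_coupling("linear", {"a": gain}),
        integrator=IntegratorSpec(method=method, dt=dt, seed=seed),
        monitors=[MonitorSpec(name="raw", kind="raw")],
        stimuli=list(stimuli),
        duration=duration,
        transient=transient,
        conduction_speed=conduction_speed,
    )


MINIMAL_EXPERIMENT_YAML = """\
dynamics:
  name: tiny
  states:
    - {name: x, initial: 1.0}
  parameters:
    - {name: k, value: 0.5, symbol: κ}
    - {name: tau, value: 2.0, symbol: τ}
  derivatives:
    - {lhs: x, rhs: -k*x/tau + c_glob}
connectome:
  labels: [left, right]
  weights: [[0.0, 1.0], [1.0, 0.0]]
  tract_lengths: [[0.0, 30.0], [30.0, 0.0]]
coupling:
  name: linear
  pre: x_j
  post: a*agg
  parameters:
    - {name: a, value: 0.5}
conduction_speed: 10.0
integrator: {method: euler, dt: 0.5, seed: 3}
stimuli:
  - kind: pulse_train
    target_state: x
    pulse: {onset: 10.0, period: 100.0, width: 5.0, amplitude: 0.2}
monitors:
  - {name: raw, kind: raw}
duration_ms: 200.0
transient_ms: 50.0
"""


@pytest.fixture
def experiment_file(tmp_path):
    p = tmp_path / "experiment.yaml"
    p.write_text(MINIMAL_EXPERIMENT_YAML)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
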