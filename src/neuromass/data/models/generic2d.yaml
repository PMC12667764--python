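name: generic2d
system_type: continuous
references: [FitzHugh1961, SanzLeon2015]
notes: >
  Generic two-dimensional phenomenological oscillator generalizing the
  FitzHugh-Nagumo system: fast excitatory variable V, slow recovery
  variable W.  Encoded in the canonical two-state form, including the
  c*V**2 parabolic term in the W equation (published renderings of this
  model occasionally print e*V**2 there; with the default c = 0 the two
  disagree, and the canonical form is used here).  c_local is 0 for
  region-based simulation.
states:
  - name: V
    symbol: V
    unit: dimensionless
    initial: 0.0
    domain: {lo: -4.0, hi: 4.0}
  - name: W
    symbol: W
    unit: dimensionless
    initial: 0.0
    domain: {lo: -20.0, hi: 20.0}
parameters:
  - name: a
    symbol: a
    value: 0.001
    description: vertical shift of the configurable nullcline (baseline)
    character: neutral
  - name: b
    symbol: b
    value: -10.0
    description: linear slope of the configurable nullcline
    character: neutral
  - name: c
    symbol: c
    value: 0.0
    description: parabolic term of the configurable nullcline
    character: neutral
  - name: d
    symbol: d
    value: 0.02
    description: overall temporal scale factor
    character: neutral
  - name: e
    symbol: e
    value: 3.0
    description: coefficient of the quadratic term of the cubic nullcline
    character: excitatory
  - name: f
    symbol: f
    value: 1.0
    description: coefficient of the cubic term of the cubic nullcline
    character: inhibitory
  - name: g
    symbol: g
    value: 0.0
    description: coefficient of the linear term of the cubic nullcline
    character: neutral
  - name: alpha
    symbol: α
    value: 1.0
    description: feedback scaling from W onto V
    character: neutral
  - name: beta
    symbol: β
    value: 1.0
    description: self-feedback of the recovery variable W
    character: inhibitory
  - name: gamma
    symbol: γ
    value: 1.0
    description: scaling of input currents (baseline and network coupling)
    character: neutral
  - name: tau
    symbol: τ
    value: 1.0
    description: time-scale hierarchy between V and W
    character: neutral
  - name: I
    symbol: I
    value: 0.0
    unit: dimensionless
    description: baseline external input current
    character: excitatory
derivatives:
  - lhs: V
    rhs: d*tau*(-f*V**3 + e*V**2 + g*V + alpha*W + gamma*I + gamma*c_glob + c_local)
  - lhs: W
    rhs: d*(a + b*V + c*V**2 - beta*W)/tau
output_expr: V
stimulation_variable: W
coupling_variable: V
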