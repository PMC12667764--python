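name: jansen_rit
system_type: continuous
references: [JansenRit1995, Grimbert2006]
notes: >
  Three-population cortical column model (pyramidal cells, excitatory and
  inhibitory interneurons).  y0/y1/y2 are postsynaptic potentials, y3/y4/y5
  their time derivatives.  Time is in ms, potentials in mV; the mean input
  firing rate mu is in /ms (multiply by 1000 for the /s values common in
  the literature: the Hopf onset near mu = 0.0898 /ms corresponds to
  89.8 /s).  Network input and stimuli enter the excitatory-interneuron
  feedback equation (state y4).
states:
  - name: y0
    symbol: y_0
    unit: mV
    initial: 0.0
    domain: {lo: -1.0, hi: 1.0}
  - name: y1
    symbol: y_1
    unit: mV
    initial: 0.0
    domain: {lo: -20.0, hi: 50.0}
  - name: y2
    symbol: y_2
    unit: mV
    initial: 0.0
    domain: {lo: -20.0, hi: 50.0}
  - name: y3
    symbol: y_3
    unit: mV/ms
    initial: 0.0
    domain: {lo: -5.0, hi: 5.0}
  - name: y4
    symbol: y_4
    unit: mV/ms
    initial: 0.0
    domain: {lo: -5.0, hi: 5.0}
  - name: y5
    symbol: y_5
    unit: mV/ms
    initial: 0.0
    domain: {lo: -5.0, hi: 5.0}
parameters:
  - name: A
    symbol: A
    value: 3.25
    unit: mV
    description: maximum amplitude of the excitatory postsynaptic potential
    character: excitatory
  - name: B
    symbol: B
    value: 22.0
    unit: mV
    description: maximum amplitude of the inhibitory postsynaptic potential
    character: inhibitory
  - name: a
    symbol: a
    value: 0.1
    unit: 1/ms
    description: inverse time constant of the excitatory postsynaptic kernel
    character: excitatory
  - name: b
    symbol: b
    value: 0.05
    unit: 1/ms
    description: inverse time constant of the inhibitory postsynaptic kernel
    character: inhibitory
  - name: v0
    symbol: v_0
    value: 6.0
    unit: mV
    description: potential at half of the maximum firing rate
    character: neutral
  - name: e0
    symbol: e_0
    value: 0.0025
    unit: 1/ms
    description: half of the maximum population firing rate
    character: neutral
  - name: r
    symbol: r
    value: 0.56
    unit: 1/mV
    description: steepness of the sigmoidal potential-to-rate transform
    character: neutral
  - name: C
    symbol: C
    value: 135.0
    description: average number of synapses between the populations
    character: neutral
    domain: {lo: 0.0, hi: 1350.0}
  - name: mu
    symbol: μ
    value: 0.22
    unit: 1/ms
    description: mean input firing rate to the excitatory interneurons (excitability)
    character: excitatory
    domain: {lo: -0.5, hi: 0.5}
derived:
  - lhs: C1
    rhs: C
  - lhs: C2
    rhs: 0.8*C
  - lhs: C3
    rhs: 0.25*C
  - lhs: C4
    rhs: 0.25*C
  - lhs: S_pyr
    rhs: 2*e0 / (1 + exp(r*(v0 - (y1 - y2))))
  - lhs: S_exc
    rhs: 2*e0 / (1 + exp(r*(v0 - C1*y0)))
  - lhs: S_inh
    rhs: 2*e0 / (1 + exp(r*(v0 - C3*y0)))
derivatives:
  - lhs: y0
    rhs: y3
  - lhs: y1
    rhs: y4
  - lhs: y2
    rhs: y5
  - lhs: y3
    rhs: A*a*S_pyr - 2*a*y3 - a**2*y0
  - lhs: y4
    rhs: A*a*(mu + C2*S_exc + c_glob) - 2*a*y4 - a**2*y1
  - lhs: y5
    rhs: B*b*C4*S_inh - 2*b*y5 - b**2*y2
output_expr: y1 - y2
stimulation_variable: y4
coupling_variable: y1
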