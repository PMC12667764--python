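name: reduced_wong_wang
system_type: continuous
references: [WongWang2006, Deco2014]
notes: >
  Reduced Wong-Wang mean-field model with one excitatory (NMDA) and one
  inhibitory (GABA) population per region; S_e and S_i are synaptic gating
  fractions.  Time is in ms, currents in nA, firing rates in Hz.  The
  excitatory gating variable is sometimes abbreviated Sc in the
  literature; it is the same quantity as S_e/Se here.  Network input
  enters the excitatory input current scaled by J_N.
states:
  - name: S_e
    symbol: S_E
    unit: dimensionless
    initial: 0.0
    domain: {lo: 0.0, hi: 1.0}
  - name: S_i
    symbol: S_I
    unit: dimensionless
    initial: 0.0
    domain: {lo: 0.0, hi: 1.0}
parameters:
  - name: a_e
    symbol: a_E
    value: 310.0
    unit: 1/nC
    description: slope of the excitatory input-output transfer function
    character: excitatory
  - name: b_e
    symbol: b_E
    value: 125.0
    unit: Hz
    description: offset of the excitatory transfer function
    character: excitatory
  - name: d_e
    symbol: d_E
    value: 0.16
    unit: s
    description: curvature of the excitatory transfer function
    character: excitatory
  - name: gamma_e
    symbol: γ_E
    value: 0.000641
    unit: ms
    description: kinetic rate of excitatory (NMDA) gating
    character: excitatory
  - name: tau_e
    symbol: τ_E
    value: 100.0
    unit: ms
    description: decay time of the excitatory (NMDA) gating variable
    character: excitatory
  - name: a_i
    symbol: a_I
    value: 615.0
    unit: 1/nC
    description: slope of the inhibitory transfer function
    character: inhibitory
  - name: b_i
    symbol: b_I
    value: 177.0
    unit: Hz
    description: offset of the inhibitory transfer function
    character: inhibitory
  - name: d_i
    symbol: d_I
    value: 0.087
    unit: s
    description: curvature of the inhibitory transfer function
    character: inhibitory
  - name: gamma_i
    symbol: γ_I
    value: 0.001
    unit: ms
    description: kinetic rate of inhibitory (GABA) gating
    character: inhibitory
  - name: tau_i
    symbol: τ_I
    value: 10.0
    unit: ms
    description: decay time of the inhibitory (GABA) gating variable
    character: inhibitory
  - name: J_N
    symbol: J_N
    value: 0.15
    unit: nA
    description: excitatory (NMDA) synaptic coupling strength
    character: excitatory
    domain: {lo: 0.0, hi: 1.0}
  - name: J_i
    symbol: J_I
    value: 1.0
    unit: nA
    description: local inhibitory (GABA) synaptic coupling strength
    character: inhibitory
  - name: w_p
    symbol: w_+
    value: 1.4
    description: local excitatory recurrence weight
    character: excitatory
  - name: W_e
    symbol: W_E
    value: 1.0
    description: external input scaling to the excitatory population
    character: excitatory
  - name: W_i
    symbol: W_I
    value: 0.7
    description: external input scaling to the inhibitory population
    character: inhibitory
  - name: I_o
    symbol: I_0
    value: 0.382
    unit: nA
    description: overall effective external input current
    character: excitatory
  - name: I_ext
    symbol: I_ext
    value: 0.0
    unit: nA
    description: additional external (task or excitability) input current
    character: excitatory
    domain: {lo: -0.5, hi: 0.5}
derived:
  - lhs: x_e
    rhs: W_e*I_o + w_p*J_N*S_e - J_i*S_i + I_ext + J_N*c_glob
  - lhs: r_e
    rhs: (a_e*x_e - b_e) / (1 - exp(-d_e*(a_e*x_e - b_e)))
  - lhs: x_i
    rhs: W_i*I_o + J_N*S_e - S_i
  - lhs: r_i
    rhs: (a_i*x_i - b_i) / (1 - exp(-d_i*(a_i*x_i - b_i)))
derivatives:
  - lhs: S_e
    rhs: -S_e/tau_e + (1 - S_e)*gamma_e*r_e
  - lhs: S_i
    rhs: -S_i/tau_i + gamma_i*r_i
output_expr: S_e
stimulation_variable: S_e
coupling_variable: S_e
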