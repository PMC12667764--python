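name: kuramoto
system_type: continuous
references: [Kuramoto1975]
notes: >
  Phase oscillator: each region is reduced to a single phase theta
  advancing at intrinsic frequency omega (rad/ms) plus network input.
  Use with a sine-difference pre-synaptic coupling transform for the
  classical Kuramoto network.
states:
  - name: theta
    symbol: θ
    unit: rad
    initial: 0.0
parameters:
  - name: omega
    symbol: ω
    value: 0.0628
    unit: rad/ms
    description: intrinsic angular frequency (default 10 Hz)
    character: neutral
derivatives:
  - lhs: theta
    rhs: omega + c_glob
output_expr: sin(theta)
stimulation_variable: theta
coupling_variable: theta
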