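# neuromass

Declarative specification, simulation, analysis and documentation of
whole-brain neural mass network models.

Whole-brain network models describe each brain region by a low-dimensional
neural mass model (Jansen-Rit, reduced Wong-Wang, generic oscillators, ...)
and couple the regions through a structural connectome. Results in this
field are notoriously hard to reproduce: equations, parameters, networks
and solver settings are scattered across prose, code and figures.
`neuromass` addresses this by making a single, validated, human-readable
specification the source of *everything*: the simulator, the bifurcation
analysis, the BOLD/functional-connectivity observation pipeline, generated
standalone code, provenance records and the model report.

## The model

Each region i evolves by delay-coupled differential equations

```
dS_i/dt = f_θ(S_i) + G Σ_j g_ij · pre(S_j(t − τ_ij), S_i(t)) + I_i(t) + η_i(t)
```

with local dynamics `f_θ` given symbolically in the spec, coupling weights
`g_ij` and conduction delays `τ_ij = D_ij / v` derived from tract lengths
`D_ij` (mm) and a conduction velocity `v` (mm/ms), an explicit
pre-transform / weighted-afferent-sum / post-transform coupling
decomposition, targeted stimuli `I_i`, and optional additive white noise
`η_i` (Euler–Maruyama). Observation models map hidden states to signals:
HRF convolution (unit-area difference-of-gammas or damped-sine kernels) to
BOLD-like series, and z-scored pairwise Pearson correlations to functional
connectivity (FC).

## Worked example

Classify the excitability regimes of the Jansen-Rit cortical column
(`examples/bifurcation_regimes.py`):

```python
from neuromass import get_model, continue_branch, classify_regimes

model = get_model("jansen_rit")
result = continue_branch(model, "mu", (-0.1, 0.4), var_of_interest="y2",
                         detect_periodic=True)
intervals, count = classify_regimes(result)
```

prints

```
special points (bifurcations):
  fold  at mu = -0.0413 /ms (-41.3 /s)
  hopf  at mu = -0.0121 /ms (-12.1 /s)
  hopf  at mu = +0.0898 /ms (+89.8 /s)
  fold  at mu = +0.1136 /ms (+113.6 /s)
  hopf  at mu = +0.3157 /ms (+315.7 /s)

3 dynamical regimes:
  mu in [-0.100, -0.010] : monostable-quiescent
  mu in [-0.010, +0.120] : bistable
  mu in [+0.120, +0.400] : oscillatory/overexcited
```

`mu` is the mean input firing rate in /ms. At low drive the column rests
at a quiescent fixed point; at intermediate drive a large-amplitude state
coexists with rest (bistability — a pulse can switch the column on); past
the Hopf point near 0.09 /ms the model oscillates at its characteristic
alpha-band rhythm, saturating at high drive. The same three-regime
structure appears in the reduced Wong-Wang model as its external input
varies — the toolkit makes such cross-model comparisons a two-line change.

Other example scripts (`examples/`): a delay-coupled network simulation,
the BOLD/FC observation DAG with provenance export, a
complex-stimulus perturbation run, and single-source code
generation + model reports. A thin CLI covers the same ground:
`neuromass simulate|analyze|report|codegen|validate|models`.

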