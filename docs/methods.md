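# Methods

This note records the scientific and numerical choices behind
`neuromass`: what the models and procedures assume, which parameters
matter, what the synthetic data generator does and does not emulate, and
where the design was genuinely open.

## Specification and symbolic layer

A model is a set of state variables, parameters (value, unit, domain,
excitatory/inhibitory character), ordered derived-variable definitions and
one time-derivative equation per state, all in a small infix grammar
(arithmetic with `**`; `exp`, `log`, trig/hyperbolic, `sqrt`, `abs`,
`min`, `max`, `heaviside`). Every expression is parsed once into a
normalized sympy tree that then drives numerical evaluation, Jacobians,
LaTeX rendering, code generation and dependency graphs, so these artifacts
cannot drift apart. Equality of expressions is structural (canonical
ordering of commutative operands), not algebraic: `2*3 + x` equals
`6 + x`, but `(x+1)**2` does not equal `x**2 + 2*x + 1`. Conditional
equations dispatch in declaration order — the first satisfied condition
wins, a final unconditioned branch is the default. The symbols `t`,
`c_glob`, `c_local` and `stim` are reserved for time, network input, local
(surface) input and stimulus; region-based simulation fixes `c_local = 0`.
Parsing is side-effect free: expressions are compiled in eval-mode against
a closed symbol table, and unknown names or calls are rejected, never
executed. Units are carried as annotations only; unit *algebra* (checking
dimensional consistency through the equations) is deliberately out of
scope in this version.

A parameter whose source never reported a value may be marked
`not_reported`; the spec validates and round-trips, but any attempt to
execute raises until a value is supplied. Unknown keys in spec files are
preserved on round trip and ignored computationally (with a warning), so
files from newer versions degrade gracefully.

## Model catalogue

Four models ship as ordinary YAML specs (so curation errors are visible to
the test suite, which checks every equation against independently
hand-coded reference implementations):

- **generic2d** — the two-variable phenomenological oscillator
  (FitzHugh–Nagumo generalization), canonical form
  `dV/dt = d·τ·(−f·V³ + e·V² + g·V + α·W + γ·I + γ·c_glob + c_local)`,
  `dW/dt = d·(a + b·V + c·V² − β·W)/τ`, defaults a=0.001, b=−10, c=0,
  d=0.02, e=3, f=1, g=0, α=β=γ=τ=1, I=0. Published renderings sometimes
  show `e·V²` in the W equation where the canonical form has `c·V²`; with
  c=0 these differ, and the canonical form is used (noted in the model
  file).
- **jansen_rit** — the three-population cortical column in ms/mV units
  (A=3.25 mV, B=22 mV, a=0.1 /ms, b=0.05 /ms, C=135, v₀=6 mV,
  e₀=0.0025 /ms, r=0.56 /mV). The excitability parameter `mu` is the mean
  input firing rate entering the excitatory-interneuron equation as
  `A·a·(mu + ...)`, i.e. the canonical input of the original formulation,
  in /ms. This interpretation was chosen (over a raw additive term on the
  derivative) because it reproduces the model's known bifurcation
  skeleton on the literature's scale: Hopf onset at mu ≈ 0.0898 /ms
  (89.8 /s) and the fold of the low-activity branch at 0.1136 /ms
  (113.6 /s), matching published analyses of this model to three decimals.
- **reduced_wong_wang** — the excitatory/inhibitory reduced mean-field
  model (gating variables S_e, S_i; sigmoidal-ramp transfer functions;
  τ_E=100 ms, τ_I=10 ms, γ_E=0.641/1000, J_N default 0.15 nA, w₊=1.4,
  I₀=0.382 nA). Its transfer function u/(1−exp(−d·u)) has a removable
  singularity at u=0; the raw form is kept (as in common reference
  implementations) and root-finding simply never lands on the exact point.
  The excitatory gating variable appears in parts of the literature
  abbreviated `Sc`; it is the same quantity as `S_e`.
- **kuramoto** — one phase per region, included to exercise the
  map/ODE and coupling machinery with a one-state model.

Equations for Jansen-Rit and reduced Wong-Wang follow their canonical
sources (Jansen & Rit 1995; Wong & Wang 2006 / Deco et al. 2014), as cited
in the bundled bibliography.

## Engine

Per step the engine (1) reads delayed coupling-variable values from a ring
buffer of length `max(delay steps)+1`, (2) applies the coupling
pre-transform per edge, sums over afferents weighted by `W[i, j]` (source
j → target i), applies the post-transform, (3) evaluates derived variables
and derivatives (derived definitions are inlined at compile time —
mathematically identical to sequential evaluation), adding the stimulus to
the derivative of its target state, and (4) advances by Euler, Heun or
Euler–Maruyama. Design choices where conventions differ:

- **History initialization**: constant at the initial state (the standard
  delay-equation convention).
- **Within-step ordering**: coupling reads only history written at
  previous steps (and the current pre-update state for zero-delay edges);
  Heun's corrector reuses the predictor-stage coupling aggregate rather
  than re-reading history at t+dt, keeping the delayed term explicit.
- **Delay discretization**: nearest-integer rounding of τ/dt, minimum 0.
- **Noise**: additive white Gaussian increments N(0, σ²·dt), one generator
  per run seeded from the integrator spec, drawn in fixed (state, region)
  order; with σ=0 the stochastic scheme is bitwise identical to Euler.
  Whether biological fluctuations are additive or multiplicative is an
  open modeling question; additive is implemented.
- **Stimulus entry**: an additive term inside the derivative evaluation of
  the designated target state (or substituted for the `stim` symbol where
  a model references it explicitly).
- **Overflow guard**: any |state| > 1e10 (or non-finite) aborts with the
  step index — uncoupled-sigmoid models driven by raw linear coupling at
  large gain hit this guard by design.
- **Discrete systems** step as maps: the "derivative" is the next state.

The coupling variable (which state enters the afferent sum) is part of the
model spec (`coupling_variable`, defaulting to the first state); the
engine contract `pre(x_j, x_i)` requires one to be designated.

## Observation pipelines

Observation models are DAGs of function nodes executed memoized in
topological order; inputs below rank 4 are expanded to
(time × state × region × mode). The BOLD path: an HRF kernel sampled at
the series' period (hemodynamic constants in seconds), normalized to unit
discrete area so convolution preserves signal scale; FFT convolution
(scipy's zero-padded `fftconvolve`, trimmed to [0, T)) keeps length and
causality; optional downsampling keeps one sample per completed repetition
interval (floor(T/tr) samples) while retaining the time base. Two kernels
are provided: *canonical* — difference of two gamma densities, peak 6 s,
undershoot 16 s, undershoot ratio 1/6 (the conventional default); and
*volterra* — a first-order exponentially damped sine
`exp(−t/2τ_s)·sin(ωt)`, ω² = 1/τ_f − 1/(4τ_s²), defaults τ_s = 0.8 s,
τ_f = 0.4 s. The damped-sine time constants are implementation-chosen
defaults (no authoritative values exist for this parameterization); both
kernels extend until the truncated tail mass is below 1e-6. Functional
connectivity z-scores regional traces along time and reports pairwise
Pearson correlations (upper triangle conventionally reported);
zero-variance regions — detected against the trace's own floating-point
scale — yield NaN with a warning.

## Bifurcation analysis

Fixed points: Newton (scipy `hybr` with the symbolic Jacobian) from
multi-start guesses over the declared state domains (≥25 random starts,
fixed seed — continuation from one branch can miss coexisting attractors),
accepted at residual < 1e-10, merged within 1e-6, stability from Jacobian
eigenvalues. One-parameter continuation scans the range (spacing at most
the `ds_max` step control), links fixed points across neighboring values,
and refines events by marching with natural-parameter continuation at
adaptive steps within [ds_min, ds_max]: a step collapse below `ds_min`
brackets a fold, located by bisection on root existence to parameter
tolerance 1e-6; stability changes are bisected likewise and labeled Hopf
when the critical eigenvalues are complex. Limit cycles are detected by
simulation (stiff-safe Runge–Kutta from a 1e-3 perturbation off an
unstable focus; sustained non-decaying post-transient peak-to-peak
> 1e-6 of the variable of interest), not by collocation — robust, and
directly testable against the Hopf normal form, whose cycle amplitude the
implementation reproduces within 0.03%.

Regime classification per sampled parameter value: ≥2 coexisting stable
attractors (fixed points and/or a cycle) → *bistable*; a stable cycle
alone → *oscillatory/overexcited*; a single stable fixed point is split
into *quiescent* vs *overexcited* only when the distribution of stable
levels across the scan is genuinely bimodal (largest inter-level gap
> 25% of the spread) — a lone attractor drifting continuously with the
parameter is one quiescent regime, not two. Contiguous equal labels merge
into regimes. Classification is invariant to the direction of the scan.

2-D parameter sweeps simulate each grid cell (default 8000 ms, first
2000 ms discarded) and store mean/max/variance of the output expression,
memoized in-process keyed by model name, parameter names, values rounded
to three decimals, the output expression and the durations.

## Provenance and reports

Each run yields a typed PROV-style DAG: the simulation Activity `used` the
model, connectome, coupling, integrator, initial conditions and stimuli
(qualified usages carry a fixed role vocabulary to distinguish them);
generated time series are Entities `wasGeneratedBy` the activity;
observation steps add activities whose outputs are `wasDerivedFrom` their
inputs, giving chains like FC ← BOLD ← raw. Identifiers are content-free
UUIDs with human labels; no resolvable IRIs are minted. Graphs are
append-only: re-derivation adds entities. Export is JSON-LD with a context
mapping relation names onto the PROV vocabulary; import is verified
isomorphic. Model reports (Markdown/LaTeX) render the parameter table and
equations from the same spec object the engine compiles — the single
source property is tested by checking that editing one value changes
exactly one table cell.

## Code generation

One target: a standalone numpy function. Derived variables are emitted in
topological order; conditional equations become declaration-order
`numpy.where` chains, matching the evaluator's first-true dispatch.
Verification samples random in-domain states (plus random coupling and
stimulus inputs) and compares against the symbolic path; the pass
criterion is relative deviation ≤ 1e-10 (measured: ≤ 2e-14 across the
catalogue, the residue of floating-point operation reordering).
Whole-trajectory agreement over 1000 ms is ≤ 1e-9 for every bundled model.

## Synthetic data

The synthetic connectome generator emulates the gross statistics of
tractography-derived networks: symmetric weights, zero diagonal, tunable
density, heavy-tailed (lognormal) weight distribution, tract lengths
positive exactly where weights are (drawn uniformly in 0.2–1.8 × a
100 mm length scale), deterministic under a seed. It does **not** emulate
spatial embedding (distance-dependent connection probability), hemispheric
symmetry, hubs/rich-club structure, or realistic streamline-count
magnitudes — so tests passing on it demonstrate the *mechanics* of
delay-coupled simulation and FC derivation, not fidelity to any empirical
connectome. Likewise the "audio" stimulus in the examples is a seeded sum
of drifting sines: broadband and time-varying like audio, but not speech
or music. Default study conditions follow the catalogue sources: 8 s
single-node runs with 2 s transient for sweeps and representative traces;
pulse stimuli of onset 4000 ms, period 8000 ms, width 1000 ms, amplitude
0.05; 4000 ms / dt = 1 ms / linear gain 0.5 for the 17-region stimulated
network reconstruction.

## Problem sizes and tolerances

The acceptance script and test suite run at desk scale: continuation scans
of 41–101 parameter values with 25 random starts each, cycle-detection
simulations of 0.4–6 s of model time, networks of 4–17 regions, and
1000 ms codegen-equivalence trajectories. Key tolerances: fixed-point
residual 1e-10; duplicate merge 1e-6; bifurcation parameter bisection
1e-6; cycle peak-to-peak threshold 1e-6; codegen relative deviation
1e-10; FC oracle agreement 1e-10. These were chosen from the numerics
(double precision, Newton convergence) rather than tuned to any outcome.

## Known limitations

No surface/PDE simulation or local coupling kernels; no two-parameter
continuation, branch switching or Floquet analysis; no
Balloon–Windkessel nonlinear hemodynamics or EEG/MEG lead fields; no unit
algebra; the stochastic scheme is Euler–Maruyama only (no stochastic
Heun). The limit-cycle detector can misread an extremely slowly decaying
focus as sustained near a Hopf point; in the regime classifier this is
benign because such points sit inside intervals that are already bistable
or oscillatory.
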