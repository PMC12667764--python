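"""Inject a complex sampled waveform into one region of a 17-node network.

A broadband waveform (standing in for an audio stimulus) is resampled to
the 1 ms simulation grid and fed into the slow variable W of region 3.
Two runs with identical parameters and seeds — stimulated and resting —
are compared: they agree exactly before stimulus onset, and the
functional connectivity afterwards shifts, quantified by the maximum
absolute off-diagonal FC difference.
"""

import numpy as np

from neuromass import (
    IntegratorSpec,
    MonitorSpec,
    SimulationExperiment,
    StimulusSpec,
    functional_connectivity,
    get_model,
    make_coupling,
    run,
    synthetic_connectome,
)
from neuromass.network import minmax_normalize
from neuromass.observation import compare_fc
from neuromass.schema import SampledWaveform

conn = synthetic_connectome(17, density=0.3, length_scale=100.0, seed=42)
conn.weights = minmax_normalize(conn.weights)

onset, duration, rate = 500.0, 4000.0, 8.0  # ms, ms, samples per ms
rng = np.random.default_rng(0)
t = np.arange(int((duration - onset) * rate)) / rate
wave = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
           for f in rng.uniform(0.001, 0.02, size=6))
wave = wave / np.max(np.abs(wave))

stimulus = StimulusSpec(
    kind="sampled", target_state="W",
    sampled=SampledWaveform(values=[0.0] * int(onset * rate) + list(wave),
                            sample_rate=rate, amplitude=0.5),
    region_weights=[1.0 if i == 3 else 0.0 for i in range(17)])


def simulate(stimuli):
    exp = SimulationExperiment(
        dynamics=get_model("generic2d"), connectome=conn,
        coupling=make_coupling("linear", {"a": 0.5}),
        integrator=IntegratorSpec(method="heun", dt=1.0, seed=0),
        monitors=[MonitorSpec(name="raw", kind="raw")],
        stimuli=stimuli, duration=duration, transient=onset,
        conduction_speed=10.0)
    return run(exp)["raw"]


rest = simulate([])
stim = simulate([stimulus])

pre = rest.time < onset
print(f"pre-onset max |difference| : "
      f"{np.max(np.abs(stim.data[pre] - rest.data[pre])):.1e} "
      "(identical by construction)")
fc_rest = functional_connectivity(rest, state="V")
fc_stim = functional_connectivity(stim, state="V")
composite, diff = compare_fc(fc_stim, fc_rest)
print(f"max |FC difference| stimulated vs rest: {diff:.3f}")
print("The composite matrix holds the stimulated condition in its upper "
      "triangle and rest in the lower; a nonzero difference shows the "
      "stimulus reorganized inter-regional coordination, not just the "
      "driven node.")
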