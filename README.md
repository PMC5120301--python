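# thalcort

A thalamocortical neural-field simulator and dynamical-analysis toolkit for
epileptic spike-wave discharges (SWD).

Absence epilepsy is marked by generalized 2–4 Hz spike-wave discharges that
arise from pathological interactions in the cortico-thalamic loop. `thalcort`
implements a five-population neural mass model of that loop — cortical
pyramidal cells (PY), a fast GABA_A-like interneuron population (IN1), a slow
GABA_B-like interneuron population (IN2), thalamocortical relay cells (TC)
and the thalamic reticular nucleus (RE) — and the analysis machinery needed
to study how seizures start, stop, and can be controlled: stimulation
protocols, firing-regime classification, parameter sweeps and state maps,
and numerical bifurcation analysis. It is aimed at computational
neuroscientists studying seizure dynamics, bistability and stimulation-based
seizure abatement.

## Model

The population activities obey

```
PY'  = τ₁ (ε₁ − PY + k₁ f(PY) − k₂ f(IN1) − k₃ f(IN2) + k₄ f(TC))
IN1' = τ₂ (ε₂ − IN1 + k₅ f(PY) − k₆ f(IN2))
IN2' = τ₃ (ε₃ − IN2 + k₇ f(PY) − k₈ f(IN1))
TC'  = τ₄ (ε₄ − TC − k₉ s(RE) + k₁₀ f(PY))
RE'  = τ₅ (ε₅ − RE − k₁₁ s(RE) + k₁₂ s(TC) + k₁₃ f(PY))
```

with the steep sigmoid `f(x) = 1/(1 + ν^(−x))` (ν = 2.5·10⁵) for cortical
outputs and the linear activation `s(x) = αx + β` for the simplified
thalamic subsystem. Excitatory projections (PY, TC) enter positively,
inhibitory ones (IN1, IN2, RE) negatively. IN2 is made slow (τ₃ ≪ τ₂); the
competition between the two inhibitory timescales is what lets the cortex
produce the spike-plus-wave waveform. The reference parameter set ships as
the preset `taylor2016-default`.

Integration is fixed-step classical RK4 at dt = 1 ms. There is no random
number generation anywhere: every run is reproducible bit for bit.

Stimulation is modelled as a single-point perturbation of the cortical
variables: a state jump of magnitude *m* (negative direction) applied to PY
and IN1. At the reference operating point (k₄, k₁₀) = (1, 3) the background
state and the SWD limit cycle coexist, so one pulse can initiate a seizure
and a later, weaker pulse can abate it.

## Worked example

```python
import numpy as np
from thalcort import (
    SimulationConfig, StimulusProtocol, classify_state, load_preset, simulate,
)
from thalcort.continuation import locate_hopf, bistable_intervals

params, config = load_preset("taylor2016-default")

# 1. the background state is not oscillating ...
quiet = simulate(params, config)
print("unstimulated:", classify_state(quiet.window(5.0), config.dt))

# 2. ... but a single -0.3 perturbation of the cortical populations
#    switches it into a sustained ~3 Hz spike-wave discharge
protocol = StimulusProtocol.single(time=20.0, magnitude=0.3)
seizure = simulate(params, config.replace(duration=50.0), protocol)
label, s = classify_state(seizure.window(25.0), config.dt, return_summary=True)
print(f"after the pulse: {label}, {s.dominant_frequency_hz:.2f} Hz, "
      f"{s.maxima_per_cycle} maxima/cycle")

# 3. the switch works because background and seizure attractors coexist:
iv = bistable_intervals(params, "k4", np.arange(0.9, 1.3, 0.02))[0]
print(f"bistable for k4 in [{iv.lower:.2f}, {iv.upper:.2f}]: {iv.attractors}")

# 4. the window opens at a subcritical Hopf bifurcation of the equilibrium
hb = locate_hopf(params, "k4", (1.0, 1.3))
print(f"{hb.kind} at k4 = {hb.value:.3f}")
```

This prints:

```
unstimulated: SATURATED_LOW
after the pulse: SWD, 2.96 Hz, 2 maxima/cycle
bistable for k4 in [1.00, 1.14]: ('SATURATED_LOW', 'SWD')
HOPF_SUB at k4 = 1.142
```

The unstimulated system rests in the low saturated background state; the
0.3-magnitude pulse switches it onto a spike-wave cycle at ~3 Hz whose
waveform carries two local maxima per period (the spike and the wave); the
two attractors coexist over a window of the thalamus-to-cortex coupling k₄
that closes at a subcritical Hopf bifurcation near k₄ ≈ 1.14.

A command-line interface exposes the same machinery
(`thalcort simulate|scan1d|map2d|pulseplane|ramp|threshold`, each with
`--preset`, `--set key=value` overrides and `--out`); results are written
as delimited tables with a config sidecar and checksummed manifest.

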