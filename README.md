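# thalaswitch

Conductance-based modelling of **robust switches between tonic firing and
bursting in thalamic neurons**, and of why those switches survive
neuromodulation, synaptic plasticity and cellular heterogeneity only when
the T-type calcium channel activates *slowly* — about an order of magnitude
slower than the sodium channel, and well faster than its own inactivation.

## The scientific problem

Thalamocortical relay and reticular neurons fire single spikes when
depolarized and rhythmic bursts when hyperpolarized (hyperpolarization-
induced bursting, HIB).  At the population level this cellular switch turns
the mean-field activity of an excitatory–inhibitory network from a
desynchronized active state into a low-frequency oscillation — the
signature of sleep-like brain states.  The burst generator is the T-type
calcium current

&nbsp;&nbsp;&nbsp;&nbsp;I<sub>CaT</sub> = ḡ<sub>CaT</sub> · m<sup>p</sup> h · (V − E<sub>Ca</sub>),

whose *inactivation* h is ultraslow and de-inactivates at hyperpolarized
potentials.  A widespread modelling simplification replaces the activation
gate m by its steady state m<sub>∞</sub>(V) ("instantaneous activation").
This package quantifies what that simplification costs: models with slow,
voltage-dependent activation kinetics τ<sub>m,CaT</sub>(V) keep their
tonic→burst switch under membrane-capacitance scaling, random conductance
variability (±10–30 %), random synaptic weights (±1/8) and population
heterogeneity, while instantaneous-activation models lose it — and
restoring a slow activation gate alone restores the robustness.

The package ships declarative single-compartment Hodgkin–Huxley models
(`C_m dV/dt = −ΣI_i + I_app`, first-order gating), kinetic
AMPA/GABA<sub>A</sub>/GABA<sub>B</sub> synapses, an explicit-Euler engine
(numba-compiled) for cells, 2-cell E-I circuits and all-to-all E-I
populations, LFP analysis (Butterworth low-pass + spectrogram + band-power
switch detection), Monte-Carlo robustness screens, and a systematic
three-timescale reduction (V, V_s, V_u) with nullcline / fixed-point /
saddle-node analysis of the slow–fast phase portrait.

Shipped model files (`src/thalaswitch/models/`): a slow-CaT archetype
("model 1": Na, K, CaT, H, KCa, CaL, leak + calcium pool) and two
instantaneous-activation archetypes ("model 5", "model 6": instantaneous
Na and CaT activation).  `load_builtin("5p")` / `"6p"` build their
restored-slow-activation variants on the fly.

## Worked example

```python
import thalaswitch as ts
from thalaswitch.sim_engine import (SINGLE_CELL_CLASSIFIER, StepProtocol,
                                    epoch_patterns, integrate,
                                    single_cell_system)

m = ts.load_builtin("1")                       # slow-CaT relay cell
p = m.presets["single_cell"]                   # I_dep=6, I_hyp=-1.5 uA/cm2
proto = StepProtocol(p["i_depol"], p["i_hyper"], 1500.0, 5500.0)
res = integrate(single_cell_system(m), proto, m.recommended_dt,
                spike_threshold=SINGLE_CELL_CLASSIFIER.spike_threshold)
print(epoch_patterns(res, 0, SINGLE_CELL_CLASSIFIER))

m5 = ts.load_builtin("5")                      # instantaneous activation
m5.c_m /= 10                                   # shrink the cell 10x
m5.recommended_dt /= 10
res5 = integrate(single_cell_system(m5),
                 StepProtocol(2.5, -1.0, 1500.0, 5500.0),
                 m5.recommended_dt, spike_threshold=-10.0)
print(epoch_patterns(res5, 0, SINGLE_CELL_CLASSIFIER))
```

prints

```
('tonic', 'burst')
('tonic', 'tonic')
```

i.e. the slow-activation model shows the depolarized-tonic /
hyperpolarized-burst switch, while the instantaneous-activation model at a
tenth of its capacitance fires tonically in both epochs — the switch is
lost.  Restoring a slow activation gate
(`ts.make_restored_variant(ts.load_builtin("5"))`) recovers `('tonic',
'burst')` under the same capacitance scaling.

A thin CLI wraps the named experiments:

```bash
thalaswitch run --experiment fig2b --model 1 --scale desk --out results/
thalaswitch list-models
```

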