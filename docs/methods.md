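# Methods

## Conductance-based models

All neurons are single-compartment Hodgkin–Huxley models,

    C_m dV/dt = -Σ_i ḡ_i m_i^{p_i} h_i^{q_i} (V - E_i) + I_app,
    dX/dt     = (X_∞(V) - X) / τ_X(V)          for every dynamic gate X,

with units fixed repo-wide: mV, ms, µA/cm², mS/cm², µF/cm², µM.  Gates
declared *instantaneous* are substituted algebraically by X_∞(V) at every
right-hand-side evaluation and never integrated.  Calcium-gated channels
(KCa) read a first-order intracellular calcium pool
d[Ca]/dt = −k·I_Ca − r·([Ca] − [Ca]_rest), clamped non-negative.

Model description files (`models/*.yml`) declare each current's gates as
members of a small, versioned set of parametric curve families (Boltzmann
steady states; constant / Gaussian-bell / double-exponential-bell /
sigmoid / two-bell time constants; Hill functions of calcium), so a model
is data, not code, and any model written in this format can be simulated,
screened and reduced.

### Shipped models

The parameters of the three shipped archetypes were authored for this
package (standard thalamic-literature functional forms; e.g. the T-current
activation time constant uses the classic double-exponential bell peaking
near −80 mV at ~10 ms, and the activation/inactivation windows overlap
near −70 mV as in relay-cell recordings).  They were tuned, before any
robustness screen was treated as a result, to exhibit the qualitative
repertoire the study requires:

- **model 1** (slow CaT): Na, K, CaT (dynamic m², τ ≈ 7 ms at threshold),
  H, KCa, CaL, leak, calcium pool.  Depolarized (+6 µA/cm²) it fires
  tonically at ~60 Hz; hyperpolarized (−1.5 µA/cm²) it bursts rhythmically
  at ~3 Hz through the T-window / h-recovery loop, with the H-current
  assisting the pacemaker.  Its sodium-activation time constant carries a
  second, hyperpolarized bell (τ ≈ 0.5 ms near −84 mV): sub-millisecond at
  spike threshold, it matters only for the timescale bookkeeping of the
  reduction (below).
- **models 5 and 6** (instantaneous CaT and Na activation): Na(h), K(n),
  CaT(h), leak only.  Burst clusters arise from the same window mechanism,
  but with m_CaT = m_∞(V) the plateau must survive each spike's
  afterhyperpolarization, which holds only on a narrow manifold of
  parameters — these models switch at nominal parameters and lose the
  switch when the capacitance is scaled down or parameters are perturbed.
  Model 6 differs from 5 by a steeper deinactivation curve and a ~2×
  slower inactivation (τ_h ≈ 600 ms at −75 mV), making it the more fragile
  of the two.
- **models 5p / 6p**: built by `make_restored_variant`, which attaches a
  dynamic activation gate to the unchanged steady-state curve.  The
  restored τ_mCaT(V) is a Gaussian bell whose value at the calcium
  threshold is the geometric mean of the model's fast and ultraslow
  anchors, i.e. squarely inside the slow band; no other parameter changes.

Applied-current amplitudes and nominal synaptic weights are per-model
presets stored in the model files (chosen, as in the experimental
protocols, so that the nominal cell and the nominal circuit perform the
rhythmic transition).

## Integration

Explicit forward Euler, all state variables advanced from the same
pre-step state.  dt defaults: 0.05 ms (model 1), 0.01 ms (models 5/6 and
variants; instantaneous gates stiffen the system).  dt is shrunk
proportionally when the capacitance is scaled down or the CaT activation
is accelerated.  Gates and synaptic gating are clipped to [0, 1] (the
exact flow preserves the interval; clipping removes Euler overshoot),
calcium to ≥ 0.  |V| > 200 mV or a non-finite state aborts with the
offending cell and time.  The numba kernel is the single code path for
cells, circuits and networks; its semantics are pinned to the pure-Python
reference (`membrane_rhs`, `synapse_rhs`) by step-for-step equality tests.

## Synapses, circuits, networks

Receptor gating follows ds/dt = α·T(V_pre)(1−s) − β·s with
T(V) = 1/(1+exp(−(V−2)/5)) and (α, β) = (1.1, 0.19) AMPA,
(0.53, 0.18) GABA_A, (0.016, 0.0047) GABA_B (1/ms); reversals 0, −70,
−85 mV.  Gating is stored once per (presynaptic cell, receptor) — exactly
equivalent to per-pair gating, keeping network state linear in cell count.

The 2-cell circuit connects E→I by AMPA and I→E by GABA_A+GABA_B; the
step current drives the I cell (depolarizing then hyperpolarizing epochs).
Networks are all-to-all E→I / I→E with no intra-population edges; nominal
weights are divided by the presynaptic count so a homogeneous population
of any size receives circuit-scale drive (a 1+1 "network" reproduces the
circuit trajectory exactly).

Classification: spikes are upward threshold crossings (−10 mV single
cell, −20 mV circuits/networks) after a transient skip (0.5 s / 1 s per
epoch).  A cell with <2 interspike intervals is silent; else bursting iff
max(ISI) > r·min(ISI) (r = 3 single cell, 4 circuits).  A circuit is
rhythmic iff the depolarized epoch is (E silent, I tonic) and the
hyperpolarized epoch has both cells bursting *synchronously*: bursts are
decomposed with the classifier's own gap statistic (ISI > r·min ISI ends
a burst), and the mean of the two burst-overlap fractions must reach 1/2.
The mean (rather than a per-cell floor) deliberately counts n:1
phase-locked rhythms — every burst of the sparser cell coinciding with a
burst of the denser one — as synchronous, while antiphase bursting fails.

## LFP and mean-field switch detection

LFP = population mean over postsynaptic cells of each cell's mean received
synaptic current (sign convention −g·s·(V−E)), low-pass filtered at
100 Hz with a 4th-order Butterworth (zero-phase by default; the package
also offers causal filtering), then a Hann short-time Fourier transform
(1 s window, 90 % overlap).  The network *switches* when the maximal
1–15 Hz band power after the hyperpolarizing step is ≥ 10× the
depolarized-epoch maximum and above an absolute floor (0 by default;
calibrated to 1 % of the homogeneous network's band power in the
heterogeneity × τ table, so the detector is anchored to its own positive
control).  Spectrogram windows straddling the step are excluded from the
depolarized epoch (a guard of half a window).

## Variability screens

Neuromodulation: every maximal conductance drawn uniformly in ±w % of
nominal (w = 10/20/30).  Synaptic plasticity: every weight uniform in
[g−g/8, g+g/8].  The two cells of a circuit are sampled independently
(config flag).  Each circuit's RNG derives from a master seed by a
counter scheme, so screens are reproducible and any single circuit can be
replayed.  The timescale screen draws one fixed set of circuits and
re-simulates it with the CaT activation τ scaled by η (full grid 1/100 …
100); the normalized logarithmic position of η·τ_mCaT between the sodium
anchor and the inactivation anchor (0 = fast, 1 = ultraslow) aligns
models with different absolute kinetics.  For instantaneous-sodium models
the missing fast anchor is substituted by τ_mCaT/100 (configurable; the
substituted boundary is taken to be the fast one).

The capacitance scan tests factors 0.01–5×; at each factor a small grid
of applied-current amplitudes is tried and the factor counts as supported
if any pair yields tonic→burst (1.5 s + 5.5 s protocol).

## Three-timescale reduction

Pacing: τ_s = τ_mK, τ_u = τ_hCaT, τ_f = τ_mNa (or τ_mK/10 when sodium
activation is instantaneous).  Every gate is replaced by
w_fs·X_∞(V) + (w_su−w_fs)·X_∞(V_s) + (1−w_su)·X_∞(V_u) with the
four-branch logarithmic-distance weights; V_s and V_u relax to V with
τ_s(V), τ_u(V).  The calcium pool is held at the quasi-equilibrium implied
by V_u.  Nullclines are traced by marching squares on a 600×600 grid over
[−100, 20] mV² with bisection polishing to 10⁻³ mV; components are the
marching-squares contours.  Fixed points are the diagonal roots with
central-finite-difference Jacobian eigenvalues.  The saddle-node of the
fast-slow subsystem is the fold of the equilibrium curve over V_u
(bisection on the root count, polished on {dV/dt = 0, det J₂ = 0});
the search window for V_u is restricted to hyperpolarized values
(≤ −40 mV), the regime the burst-onset knee lives in, and among multiple
folds the most hyperpolarized V is reported.  A *lower branch* is a
nullcline component disjoint from the spiking upper branch that reaches
below the saddle voltage; in the shipped slow-CaT model it is a C-shaped
fold whose lower arm carries the silent rest (hence "reaches below"
rather than "lies entirely below").

## Desk-scale study conditions

Full-scale conditions are 1000 circuits × 82 s (41 s per epoch), 400
circuits for the τ screen, and 100+100-cell networks × 42 s.  The test
suite and acceptance script use desk-scale conditions chosen once: 6 s +
8 s circuit epochs (4 s + 5 s in the τ screen), 20–200 circuits per
screen, 3-point η grids {1/100, 1, 100}, and 16+16- or 20+20-cell networks
with 10 s epochs — transients, integration steps, classifier thresholds
and variability widths identical to full scale.  What desk scale shows is
the qualitative contrast and ordering between kinetic classes; percentages
at n = 20 carry ±10-point binomial noise and are not precision estimates
of the full-scale fractions.

## Known limitations

- At the population scale, the all-to-all inhibitory loop (sized so the
  2-cell circuit's E cell gets a synaptically reachable rebound)
  synchronizes heterogeneous populations of either kinetic class: the
  instantaneous-activation networks keep most of their oscillation power up
  to 50 % heterogeneity.  The kinetic-class robustness contrast in this
  package is therefore expressed at the single-cell level (capacitance
  scaling, switch survival under conductance draws) and in the
  activation-timescale screens, not as a mean-field switch threshold.
- The shipped parameters are this package's own archetypes of the two
  kinetic classes, not transcriptions of the six published model sets; the
  description format accepts any model expressed in it.
- The C_m-fragility of the instantaneous archetype lives in its fast spike
  machinery; after reduction to (V, V_s, V_u) its hyperpolarized rhythm is
  carried by the window fold and survives capacitance scaling, so the
  reduced-level capacitance contrast between model classes is not
  reproduced (the full-model contrast is).
- The generator emulates neuromodulation and plasticity as static uniform
  parameter draws; real modulation is dynamic, correlated across channels
  and activity-dependent.  Passing screens show robustness of the rhythm
  to parameter dispersion, not to time-varying modulation.
- Single compartments, no temperature corrections, no stochastic gating,
  no conduction delays, no extracellular forward model beyond the
  synaptic-sum LFP.
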