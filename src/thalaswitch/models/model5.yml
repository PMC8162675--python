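# Instantaneous-CaT archetype "5": minimal relay-cell model in which both
# the sodium activation and the T-type calcium activation are replaced by
# their steady-state functions (only h_Na, m_K and h_CaT are integrated).
# Bursting under hyperpolarization arises from the T-current window and the
# slow inactivation variable.
format: thalaswitch-model/1
model_id: "5"
c_m: 1.0
recommended_dt: 0.01
thresholds:
  v_th_na: -45.0
  v_th_act: -60.0
  v_th_inact: -75.0
currents:
  - name: Na
    g_max: 50.0
    reversal: 50.0
    gates:
      - name: m_Na
        kind: activation
        exponent: 3
        steady_state: {family: boltzmann, params: [-37.0, -7.0]}
        time_constant: instantaneous
      - name: h_Na
        kind: inactivation
        exponent: 1
        steady_state: {family: boltzmann, params: [-58.0, 6.0]}
        time_constant: {family: gaussian, params: [0.5, 8.0, -60.0, 25.0]}
  - name: K
    g_max: 7.0
    reversal: -80.0
    gates:
      - name: m_K
        kind: activation
        exponent: 4
        steady_state: {family: boltzmann, params: [-30.0, -10.0]}
        time_constant: {family: gaussian, params: [0.5, 4.0, -40.0, 40.0]}
  - name: CaT
    g_max: 2.0
    reversal: 120.0
    gates:
      - name: m_CaT
        kind: activation
        exponent: 2
        steady_state: {family: boltzmann, params: [-65.0, -7.8]}
        time_constant: instantaneous
      - name: h_CaT
        kind: inactivation
        exponent: 1
        steady_state: {family: boltzmann, params: [-82.0, 3.0]}
        time_constant: {family: sigmoid, params: [30.0, 600.0, -75.0, 6.0]}
  - name: leak
    g_max: 0.05
    reversal: -70.0
    gates: []
presets:
  single_cell:
    i_depol: 2.5
    i_hyper: -1.0
  circuit:
    i_depol: 2.5
    i_hyper: -1.0
    weights: {ampa: 0.3, gabaa: 0.5, gabab: 1.0}
  network:
    heterogeneity: 5.0
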