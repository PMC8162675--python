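# Slow-CaT archetype: thalamocortical relay cell with Na, K, CaT (slow,
# voltage-dependent activation kinetics), H, KCa, CaL, leak and a first-order
# intracellular calcium pool.  T-current kinetics follow the standard
# relay-cell functional forms (Boltzmann steady states, double-exponential
# bell activation time constant).
format: thalaswitch-model/1
model_id: "1"
c_m: 1.0
recommended_dt: 0.05
thresholds:
  v_th_na: -45.0
  v_th_act: -60.0
  v_th_inact: -75.0
calcium_pool:
  influx_coupling: 0.1
  removal_rate: 0.01
  resting_level: 0.05
  external_level: 2000.0
  nernst_factor: 12.84
currents:
  - name: Na
    g_max: 90.0
    reversal: 50.0
    gates:
      - name: m_Na
        kind: activation
        exponent: 3
        steady_state: {family: boltzmann, params: [-38.0, -7.0]}
        time_constant: {family: gauss2, params: [0.1, 0.4, -40.0, 30.0, 0.35, -84.0, 10.0]}
      - name: h_Na
        kind: inactivation
        exponent: 1
        steady_state: {family: boltzmann, params: [-62.0, 6.0]}
        time_constant: {family: gaussian, params: [0.5, 7.0, -60.0, 25.0]}
  - name: K
    g_max: 10.0
    reversal: -90.0
    gates:
      - name: m_K
        kind: activation
        exponent: 4
        steady_state: {family: boltzmann, params: [-30.0, -10.0]}
        time_constant: {family: gaussian, params: [0.5, 4.0, -40.0, 40.0]}
  - name: CaT
    g_max: 1.0
    reversal: 120.0
    calcium_source: true
    gates:
      - name: m_CaT
        kind: activation
        exponent: 2
        steady_state: {family: boltzmann, params: [-65.0, -7.8]}
        time_constant: {family: biexp, params: [0.43, 0.7, -16.8, 18.2, -131.6, 16.7]}
      - name: h_CaT
        kind: inactivation
        exponent: 1
        steady_state: {family: boltzmann, params: [-82.0, 4.0]}
        time_constant: {family: sigmoid, params: [25.0, 400.0, -60.0, 8.0]}
  - name: H
    g_max: 0.05
    reversal: -43.0
    gates:
      - name: m_H
        kind: activation
        exponent: 1
        steady_state: {family: boltzmann, params: [-75.0, 5.5]}
        time_constant: {family: gaussian, params: [200.0, 800.0, -85.0, 20.0]}
  - name: KCa
    g_max: 0.3
    reversal: -90.0
    gates:
      - name: m_KCa
        kind: activation
        exponent: 1
        ca_dependent: true
        steady_state: {family: hill, params: [20.0, 2.0]}
        time_constant: instantaneous
  - name: CaL
    g_max: 0.05
    reversal: 120.0
    calcium_source: true
    gates:
      - name: m_CaL
        kind: activation
        exponent: 2
        steady_state: {family: boltzmann, params: [-30.0, -6.0]}
        time_constant: {family: gaussian, params: [1.0, 5.0, -30.0, 25.0]}
  - name: leak
    g_max: 0.05
    reversal: -70.0
    gates: []
presets:
  single_cell:
    i_depol: 6.0
    i_hyper: -1.5
  circuit:
    i_depol: 6.0
    i_hyper: -1.5
    weights: {ampa: 0.3, gabaa: 0.5, gabab: 1.2}
  network:
    heterogeneity: 20.0
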