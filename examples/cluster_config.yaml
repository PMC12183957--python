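# Fully-commented simulation configuration.  Every key is optional; an
# empty file gives the implemented-chip defaults (16 axons x 16 dendrites,
# threshold 5 alpha units, reference code value 2).  JSON files load too.

device:                 # MTJ array electrical parameters
  R_P: 10000.0          # parallel (low) resistance, ohms
  R_AP: 20000.0         # anti-parallel (high) resistance, ohms
  V_READ_AMP: 0.050     # clamped bit-line voltage, volts (warn above 50 mV)

array:                  # synapse crossbar, in user-facing signed alpha units
  K: 2                  # axon (input) rows
  N: 3                  # dendrite (output) columns
  weights:              # K x N table; range -ref_value .. total-ref_value
    - [4, 5, 4]
    - [-2, 0, 1]
  ref_value: 2          # PSP reference code value (two P, five AP cells)
  shape: thermometer    # thermometer (unit ratios) or binary (ratios 1,2,4)
  # n_cells: 7          # cells per code; auto-sized when omitted

threshold:              # shared per-cluster threshold block
  theta_units: 5        # net threshold in alpha units (>= 1)
  ref_value: 2          # use 0 (all-AP reference) for theta_units > 5
  shape: thermometer

analog:                 # integrator voltages (V), capacitance (F), leakage
  C_int: 1.0e-12        # integration capacitor
  V_TH: 0.850           # comparator threshold / time-window stop level
  V_CM_COL: 0.600       # integrator reset common-mode
  # V_CM_TWG: 0.582     # window-generator start; default V_CM_COL - delta
  V_REST: 0.600         # resting baseline
  # V_GEN: 0.600        # subthreshold baseline; default V_REST
  V_RFR: 0.540          # relative-refractory baseline (< V_REST)
  V_LAT: 0.480          # lateral-inhibition baseline (< V_RFR)
  I_LEAKAGE: 1.0e-06    # leak current, amperes
  t_leak: 1.0e-08       # SW_LEAK pulse width, seconds
  theta_max: 7          # largest threshold the firing margin must protect

timing:
  f_GCLK: 10000.0       # global clock, Hz (warn outside 1-50 kHz)
  n_abs: 1              # absolute-refractory gate, GCLK cycles
  inhibition_radius: 1  # lateral inhibition reach on the dendrite line
  # adjacency: {0: [2], 2: [0]}   # explicit topology overriding the radius

variation:              # Monte-Carlo offset and chip-spread model
  autozero_enabled: true
  alpha_range: [0.7, 1.3]   # uniform chip-level alpha multiplier support
  # offset_pre:  {integrator_comparator: [2.42e-3, 3.26e-3], buffer: [0.58e-3, 3.37e-3]}
  # offset_post: {integrator_comparator: [8.03e-3, 0.97e-3], buffer: [-0.12e-3, 0.15e-3]}
  seed: 0

seed: 0                 # top-level RNG seed for stochastic experiments
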