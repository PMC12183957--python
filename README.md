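# mramsim

A behavioral simulator of an MRAM-based mixed-signal neuromorphic cluster:
a K-axon × N-dendrite spiking array whose synaptic weights live in
magnetic-tunnel-junction (MTJ) memory and whose neurons are analog leaky
integrate-and-fire (LIF) circuits.  The package models the system at the
level of currents, voltages and clock phases — not transistors — for
researchers who want to study or reproduce the architecture's neural
behaviors (EPSP/IPSP summation, refractory periods, lateral inhibition)
and its robustness to device variation without silicon.

## The model

An MTJ stores a bit as its resistance: parallel `P` (low, `R_P`) or
anti-parallel `AP` (high, `R_AP`).  With the bit line clamped at
`V_READ_AMP`, a cell sources `I_P = V_READ_AMP / R_P` or
`I_AP = V_READ_AMP / R_AP`.  Because the on/off contrast is low (down to
1:2), raw multi-cell currents are ambiguous — one P cell equals two AP
cells.  The architecture therefore stores every weight as a multi-bit code
paired with a matched-total reference code and uses only the difference,
which is an exact integer multiple of the weight quantum
`α = I_P − I_AP`:

    I(gen) − I(ref) = (code_value(gen) − code_value(ref)) · α

Positive net weights are excitatory (EPSP), negative inhibitory (IPSP);
simultaneously active axons sum on the dendrite column (spatial
summation).

Each stimulus-carrying global-clock (GCLK) cycle, a neuron resets its
integrator to a baseline voltage, integrates the net column current for a
time window set by the stored threshold `θ` (in α units),

    T_int = C_int (V_TH − V_CM_TWG) / (θ α),

and fires when the membrane reaches `V_TH`.  Substituting `T_int`, the
deflection of a weight-`w` stimulus is `(w/θ)(V_TH − V_CM_TWG)` —
independent of `α`, the capacitance and the clock frequency — so firing
depends only on the integer comparison `w ≥ θ`.  Biology-inspired states
are encoded in the baseline the next integration starts from:
`V_RFR` after the neuron's own spike (relative refractory), `V_LAT` after
a neighbor's (lateral inhibition), `V_GEN` after a subthreshold
deflection, `V_REST` otherwise, with `V_LAT < V_RFR < V_REST`.  An
absolute refractory gate blocks all input for `n_abs` cycles after a
spike.  A Monte-Carlo layer samples per-neuron comparator offsets (with or
without auto-zero cancelation) and a per-chip `α` multiplier to study
chip-to-chip invariance.

## Worked example

```python
from mramsim import (DeviceParams, WeightCode, net_alpha_units,
                     program_weights, column_current, preset, simulate)

params = DeviceParams()               # 10 kΩ : 20 kΩ at 50 mV
ref = WeightCode.from_value(2)        # two P + five AP reference
print(net_alpha_units(WeightCode.from_value(6), ref))   # -> 4   (EPSP +4α)
print(net_alpha_units(WeightCode.from_value(0), ref))   # -> -2  (IPSP −2α)

matrix = program_weights([[4], [-2]])
print(column_current({0, 1}, 0, matrix, params) / params.alpha)  # -> 2.0

sim, schedule = preset("linear_sweep", theta_units=5)   # weights −2..+5
raster, _ = simulate(sim, schedule)
print(raster.spikes)                                    # -> [(0, 7)]
```

The simultaneous +4α and −2α stimuli sum to +2α — below the 5α threshold,
so that dendrite stays silent — while in the linear sweep exactly one
spike appears, at tick 0 on dendrite 7, the column whose weight (+5)
equals the threshold.  The `examples/` directory contains one narrative
script per capability (synapse arithmetic, linear sweep, refractory and
lateral inhibition, time-window and leakage control, variation
Monte-Carlo); `examples/cluster_config.yaml` is a fully commented
configuration file.

A thin CLI wraps the library:

```sh
mramsim run --config cfg.yaml --stimulus stim.csv --out raster.csv
mramsim preset linear_sweep -o theta_units=7
mramsim sweep --kind time_window
mramsim montecarlo --n-chips 100
```

Stimulus files are CSV with header `tick,axon`; rasters `tick,dendrite`.

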