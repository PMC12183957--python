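# Methods

## Scope and level of abstraction

`mramsim` is a behavioral model of a mixed-signal neuromorphic cluster:
MTJ synapse codes, current-subtraction readout, window-normalized LIF
integration, refractory/lateral-inhibition baselines, and Monte-Carlo
variation.  It operates on currents, voltages and clock phases.  It does
not model transistors, layout, MRAM write physics (writes are
instantaneous, error-free state assignments), tunneling or temperature
effects, multi-cluster packet transport, or power.  Within each
global-clock (GCLK) cycle the analog evolution is resolved in closed form,
not by ODE integration: the integrator is linear in time, so the
end-of-window voltage is exact.

## Synapse arithmetic

A weight code is an ordered list of MTJ cells with integer mirror ratios.
Two shapes are built in and proven equivalent in tests: *thermometer*
(seven unit-ratio cells, as in the worked examples) and *binary* (ratios
1, 2, 4, as on the chip).  For a code with ratio-weighted P count `v` and
total ratio `T`, the raw current is `T·I_AP + v·α`; subtracting a
matched-total reference with count `r` leaves `(v − r)·α` exactly.  The
user-facing unit is the signed integer `w = v − r` ("alpha units"); with
the default reference value `r = 2` on 7-total codes the representable
range is −2…+5, eight levels.  Each axon row owns one PSP reference, so
simultaneous stimuli each subtract their own reference before the column
sums — this is what makes, e.g., a +4α and a −2α stimulus sum to +2α.
The reference-per-row topology and the default reference value 2 are
design choices consistent with every worked configuration.

Thresholds above 5α cannot be written against the reference value 2
within 7-total codes; the threshold block therefore accepts an all-AP
reference (value 0), and the linear-sweep scenario auto-sizes thermometer
codes to `max(7, ref + w_max)` cells when the requested weight range
requires it.

## Firing normalization and the margin δ

The time-window generator converts the stored threshold into the
integration time `T_int = C_int (V_TH − V_CM_TWG)/(θ α)`.  Substituting
`T_int` into the integrator gives a deflection of
`(w/θ)(V_TH − V_CM_TWG)` for a weight-`w` stimulus — independent of `α`,
`C_int` and the clock, which is the chip-invariance claim in closed form.
The window ramp starts a margin `δ = V_CM_COL − V_CM_TWG > 0` below the
integrator's reset level, so from rest a stimulus with `w = θ` overshoots
`V_TH` by exactly `δ` and fires; the validator requires
`δ(θ_max − 1) < V_TH − V_CM_COL` strictly so that `w = θ − 1` can never
reach `V_TH` (at equality it would land exactly on the comparator
threshold, which fires under the `≥` comparison).  The default is half
the center of that band, `δ = (V_TH − V_CM_COL)/(2 θ_max)` ≈ 17.9 mV at
the default levels.  Firing therefore occurs iff `w ≥ θ`, including
exactly at equality.

Voltage defaults: `V_REST = V_CM_COL = 600 mV`, `V_TH = 850 mV` (the top
of the 800–850 mV operating band used in the window sweeps),
`V_RFR = 540 mV`, `V_LAT = 480 mV`, `V_GEN = V_REST`.  All are
configurable; the loader enforces `V_LAT < V_RFR < V_REST < V_TH`.  A
baseline `B` blocks a threshold-equal stimulus iff `B < V_CM_TWG`;
`V_RFR` and `V_LAT` both satisfy this by a wide margin at the defaults,
and the configuration validator warns when a custom `V_RFR` does not.

## Per-cycle phase order and state encoding

On a stimulus-carrying tick each neuron runs: absolute-refractory gate →
reset to baseline → integrate over `T_int` → compare (fire, then
immediate repolarization to `V_REST`; the spike waveform is not traced) →
one discrete leak pulse (skipped on fire cycles, since the comparison
precedes the leak switch) → baseline selection for the next stimulus.
Ticks without any active axon are idle: no switches fire, baselines
persist, only the absolute-refractory counters advance.  Baseline
priority when events coincide is own-spike (`V_RFR`) over neighbor-spike
(`V_LAT`) over subthreshold (`V_GEN`), a cell-intrinsic-state-first rule;
each special baseline applies to exactly the next stimulus cycle and then
reverts through the selector.  The absolute gate length `n_abs` defaults
to one GCLK cycle and is configurable.  Lateral inhibition defaults to
radius-1 adjacency on the dendrite index line (non-wrapping); an explicit
adjacency map supports other topologies.

Leakage is one pulse of depth `I_LEAKAGE · t_leak / C_int` toward
`V_REST`, clamped so it never crosses it.  The defaults
(`1 µA × 10 ns / 1 pF = 10 mV` per pulse) are a package choice — large
enough to be visible in traces, smaller than the firing margin δ-related
quantities that determine rasters.  Because every integration starts from
a selected baseline, leakage shapes the traces but never the raster; this
matches the discrete "leak windows" the circuit produces, as opposed to
the continuous decay of biological membranes.

## Device parameters

The P:AP resistance envelope spans 10 kΩ:20 kΩ to 5 kΩ:30 kΩ; the default
pair is 10 kΩ/20 kΩ — deliberately the worst-contrast corner
(`I_P/I_AP = 2`), where the raw-current ambiguity (one P cell vs. two AP
cells) that motivates the subtraction architecture is exact.  The clamp
voltage default is 50 mV, the read-disturb guideline; exceeding it logs a
warning rather than failing, since the bound is an operating ideal.
Memory reads sense against the arithmetic mean of one P and one AP
reference cell (symmetric margin), with midpoint ties resolving to the
high-resistance state.

## Variation model

Comparator/integrator and buffer offsets use the quoted fabrication
Monte-Carlo statistics as *input* distributions — pre-cancelation
(2.42 mV, 3.26 mV) and post-auto-zero (8.03 mV, 0.97 mV) for the
integrator/comparator path — the simulator does not re-derive them from
device physics.  Offsets are applied additively to the comparator
threshold only; integrator-slope mismatch is folded into a chip-level `α`
multiplier, drawn uniformly from [0.7, 1.3] by default to emulate the
resistance-envelope spread.  This is the minimal model that reproduces
both the robustness claim (identical rasters across chips, since the
normalized deflection is offset-tolerant up to δ) and the failure mode
(boundary misfires when the margin shrinks below the offset spread).

The boundary-misfire experiment deliberately shrinks δ to 5 mV: a
threshold-equal stimulus then overshoots by only 5 mV, and a chip misses
the spike iff its comparator offset exceeds that.  The shrunken value is
chosen above the pre-cancelation offset *mean* (2.42 mV) so that the miss
probability is monotone increasing in the offset sd — with a margin below
the mean, tightening the spread would concentrate offsets above the
margin and the trend would invert.

## Determinism, problem sizes, and what the tests show

All experiments are deterministic given a configuration and a seed
(`numpy.random.Generator` throughout); rasters compare bit-for-bit via a
content hash.  Scenario sizes follow the documented protocols: the linear
sweep uses one axon and one column per weight level (8 columns at θ = 5,
10 at θ = 7, 6 at θ = 3), the refractory protocol 3 columns and two
stimuli two ticks apart, invariance populations 100 chips, misfire curves
200 chips per sd point.  Property tests (hypothesis, derandomized) cover
the subtraction identity, encoding round trips, column superposition,
leak convergence, refractory spacing and clock invariance.

The synthetic stimulus generator emulates GCLK-aligned Poisson-like
streams and adversarial edge cases (all-IPSP arrays, threshold-boundary
weights, full-row simultaneous activation).  It does not emulate
asynchronous biological timing (inputs are grid-aligned, as in the chip),
correlated mismatch within a code, electrical parasitics, or measured
absolute times — so passing tests demonstrate the architecture's logical
and arithmetic behavior, not silicon timing.  Printed silicon figures
(chip-to-chip nanosecond spreads, offset histograms) are treated as input
parameters, not as quantities this simulator can reproduce.

## Known limitations

- Analog waveforms within a phase are not traced; traces record the
  reset, post-integration and post-comparison values per cycle.
- The exact analog role of `V_GEN` is underdetermined in the source
  architecture; it is modeled as the baseline after a subthreshold
  deflection and defaults to `V_REST`.
- Whether leakage applies on fire cycles is ambiguous; the model skips it
  (comparison precedes the leak switch, and the fired integrator is
  repolarized immediately).
- Threshold storage is fully programmable (gen/ref code pair with
  `θ ≥ 1`); the physical 2 × 6-cell allocation is not decomposed.
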