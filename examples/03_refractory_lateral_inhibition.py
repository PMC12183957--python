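"""Relative refractory period and lateral inhibition protocol.

Three columns carry weights (theta-1, theta, theta-1).  The first stimulus
fires only the middle dendrite.  The second, identical stimulus two ticks
later finds the middle dendrite integrating from the refractory baseline
V_RFR and its neighbors from the inhibited baseline V_LAT — nobody fires.
"""

from mramsim import preset, simulate

for theta in (5, 7):
    sim, schedule = preset("refractory_lateral", theta_units=theta)
    raster, traces = simulate(sim, schedule, record_traces=True)
    print(f"\ntheta = {theta}, weights {sim.matrix.alpha_matrix()[0].tolist()}, "
          f"stimuli at ticks {[t for t, _ in schedule.events]}")
    print(f"  spikes: {raster.spikes}  (middle dendrite, first stimulus only)")
    starts = traces[traces["phase"] == "reset"]
    for tick in (0, 2):
        row = starts[starts["tick"] == tick].set_index("neuron")["volts"]
        levels = ", ".join(f"d{d}={v * 1e3:.0f} mV" for d, v in row.items())
        print(f"  tick {tick} integration baselines: {levels}")
    a = sim.analog
    print(f"  (V_REST={a.V_REST * 1e3:.0f}, V_RFR={a.V_RFR * 1e3:.0f}, "
          f"V_LAT={a.V_LAT * 1e3:.0f} mV)")
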