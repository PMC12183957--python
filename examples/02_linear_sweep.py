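"""Linear integration sweep: one axon, one column per weight level.

A single stimulus deflects each dendrite's membrane by (w/theta) of the
window span — IPSPs dip below rest, weight 0 stays flat, EPSPs climb
linearly, and the column whose weight equals the threshold fires.
"""

from mramsim import preset, simulate

for theta in (5, 7, 3):
    sim, schedule = preset("linear_sweep", theta_units=theta)
    raster, traces = simulate(sim, schedule, record_traces=True)
    W = sim.matrix.alpha_matrix()[0]
    peaks = traces[traces["phase"] == "integrate"].set_index("neuron")["volts"]
    fired = {d for _, d in raster.spikes}
    print(f"\ntheta = {theta}: weights {W.min():+d}..{W.max():+d}")
    for d, w in enumerate(W):
        mark = "  <- FIRE" if d in fired else ""
        print(f"  w = {w:+d}: V_integ peaks at {peaks[d] * 1e3:7.2f} mV{mark}")
    fired_w = sorted(int(W[d]) for d in fired)
    print(f"  spike exactly at w = {fired_w} (threshold {theta})")
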