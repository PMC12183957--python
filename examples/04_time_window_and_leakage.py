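"""Time-window generation and controllable discrete leakage.

The stored threshold sets the integration window: a higher theta ramps the
window generator faster (shorter T_int), a higher V_TH stops it later
(longer T_int).  Leakage is a per-cycle pulse whose depth scales with the
SW_LEAK width and with I_LEAKAGE.
"""

from mramsim import leakage_sweep, time_window_sweep

tw = time_window_sweep(thetas=(5, 7))
print("Integration window T_int (ns) over the V_TH grid:")
pivot = tw.assign(T_ns=tw["T_int_s"] * 1e9).pivot(
    index="V_TH", columns="theta", values="T_ns"
)
print(pivot.round(2).to_string())
print("-> T_int grows with V_TH; the theta=7 window is 5/7 of the theta=5 one.")

lk = leakage_sweep(t_leak_values=(5e-9, 10e-9, 20e-9),
                   I_leak_values=(1e-6, 2e-6))
print("\nPer-window leakage drop (mV) vs. pulse width and current:")
pivot = lk.assign(mV=lk["delta_V"] * 1e3).pivot(
    index="t_leak_s", columns="I_LEAKAGE_A", values="mV"
)
print(pivot.round(2).to_string())
print("-> doubling either the pulse width or the leak current doubles the drop.")
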