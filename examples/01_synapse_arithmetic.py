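"""Current-subtraction synapse arithmetic on the worked code examples.

Builds the canonical seven-cell codes, shows the raw-current ambiguity of
low-contrast MTJs, and how subtracting the PSP reference turns codes into
exact signed multiples of alpha = I_P - I_AP.
"""

from mramsim import (
    DeviceParams,
    ThresholdBlock,
    WeightCode,
    code_current,
    collision_report,
    column_current,
    net_alpha_units,
    program_weights,
    threshold_units,
)

params = DeviceParams()  # 10 kOhm : 20 kOhm at 50 mV
print(f"I_P  = {params.I_P * 1e6:.2f} uA   I_AP = {params.I_AP * 1e6:.2f} uA   "
      f"alpha = {params.alpha * 1e6:.2f} uA")

# Raw currents collide: one P cell equals two AP cells at I_P/I_AP = 2.
report = collision_report("thermometer", params)
pair = report[report["pattern"].isin(["1xP", "1xAP+1xAP"])]
print("\nRaw-current collision (the low-contrast ambiguity):")
print(pair.to_string(index=False))

# Subtraction against a matched-total reference resolves it exactly.
ref = WeightCode.from_value(2)          # two P, five AP
epsp = WeightCode.from_value(6)         # six P, one AP
ipsp = WeightCode.from_value(0)         # seven AP
print(f"\nEPSP row net weight: {net_alpha_units(epsp, ref):+d} alpha")
print(f"IPSP row net weight: {net_alpha_units(ipsp, ref):+d} alpha")
theta = threshold_units(ThresholdBlock(WeightCode.from_value(7), ref))
print(f"threshold block:     {theta:+d} alpha")

# Spatial summation: both rows active on one dendrite in the same tick.
matrix = program_weights([[4], [-2]])
net = column_current({0, 1}, 0, matrix, params) / params.alpha
print(f"simultaneous +4 and -2 stimuli sum to {net:+.1f} alpha "
      f"(below the threshold of {theta}: no spike)")
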