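"""Monte-Carlo device variation: weight-determined firing across chips.

Virtual chips differ in their alpha quantum (resistance-envelope spread)
and per-neuron comparator offsets.  With auto-zeroed offsets the window
normalization makes every chip produce the same raster; shrinking the
firing margin and widening the offset spread breaks the boundary case.
"""

from mramsim import boundary_misfire_rates, invariance_experiment

df = invariance_experiment(n_chips=100, scenario="linear_sweep", seed=1)
print(f"100 virtual chips, alpha multipliers "
      f"{df['alpha_multiplier'].min():.2f}-{df['alpha_multiplier'].max():.2f}:")
print(f"  identical rasters on every chip: {df['identical'].all()}")
print(f"  integration window spread: {df['T_int_s'].min() * 1e9:.1f}-"
      f"{df['T_int_s'].max() * 1e9:.1f} ns (adaptive, not a malfunction)")

rates = boundary_misfire_rates([3.26e-3, 2.0e-3, 0.97e-3, 0.3e-3],
                               n_chips=200, seed=3)
print("\nBoundary (w = theta) misfire rate with a 5 mV margin:")
for row in rates.itertuples():
    print(f"  offset sigma = {row.sigma * 1e3:.2f} mV -> "
          f"misfire rate {row.misfire_rate:.2f}")
print("-> the rate shrinks monotonically as offsets are canceled.")
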