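"""The four temperature-variation indices, including the two textbook
two-day cases: a 18->25 degC warm-up and a 16->10 degC cool-down, both
against a minimum-mortality temperature (MMT) of 20 degC.
"""

import tempmort as tm

inc, dec = tm.interday_indices([18.0, 25.0], mmt=20.0)
print(f"warm-up  18 -> 25 degC (MMT 20): increase {inc[1]:g} degC, "
      f"decrease {dec[1]:g} degC")
inc, dec = tm.interday_indices([16.0, 10.0], mmt=20.0)
print(f"cool-down 16 -> 10 degC (MMT 20): increase {inc[1]:g} degC, "
      f"decrease {dec[1]:g} degC")
print("Only the part of the change beyond the MMT counts, so a rise on a "
      "cold day or a drop on a hot day scores zero.\n")

# on a full series: distribution of active days per index
series = tm.simulate_city(tm.SynthConfig(n_years=5, seed=2))
indices = tm.compute_indices(series, mmt=19.0)
print(tm.summarize_indices(indices).round(2))
print("\nEach row: days with a nonzero index and the quartiles of those "
      "nonzero values (degC).")
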