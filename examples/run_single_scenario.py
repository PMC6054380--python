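"""Run one debt-economy scenario and inspect its indicator series.

Simulates a fractional-reserve economy with no government intervention on a
50 x 50 landscape for up to 250 ticks, then prints when (and whether) the
natural resource base collapsed, how much credit the bank created, and the
peak of the speculative episode.
"""

from ecocredit import preset_config, run

config = preset_config("fractional_no_gov")
result = run(config, seed=0)

ind = result.indicators
print(f"ticks simulated:        {result.halt_tick}")
print(f"halt reason:            {result.halt_reason}")
print(f"initial resource stock: {ind.natural_resource_stock.iloc[0]:,.0f}")
print(f"final resource stock:   {ind.natural_resource_stock.iloc[-1]:,.0f}")
print(f"cumulative credit:      {result.cumulative_credit:,.0f}")
boom = ind[ind.tick > 10]  # skip the start-up transient
print(f"peak speculation rate:  {boom.speculation_rate.max():,.1f} "
      f"(tick {int(boom.speculation_rate.idxmax()) + 1})")
print(f"peak debt growth rate:  {boom.debt_growth_rate.max():.2f}")

# A halt reason of "resource_collapse" means the total biomass stock fell
# below 1% of its initial value and the simulation ended early: the
# credit-fuelled extraction boom exhausted the landscape.
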