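"""Fractional-reserve vs full-reserve banking, as shared-seed ensembles.

Runs small ensembles (8 replicates each, same seeds) of the four canonical
scenarios and prints the collapse frequency, mean credit creation and mean
final stock for each.  Larger ensembles (the package default is 20, the
reference design is 100) tighten the standard-error bands but show the same
ordering.
"""

import numpy as np

from ecocredit import PRESETS, run_ensemble

REPLICATES = 8

print(f"{'scenario':20s} {'collapses':>9s} {'mean credit':>12s} {'final stock %':>14s}")
for name in PRESETS:
    ens = run_ensemble(name, REPLICATES, base_seed=0, keep_series=True)
    finals = [
        100 * r.indicators.natural_resource_stock.iloc[-1]
        / r.indicators.natural_resource_stock.iloc[0]
        for r in ens.runs
    ]
    print(
        f"{name:20s} {ens.n_collapsed:>4d}/{REPLICATES:<4d} "
        f"{np.mean(ens.cumulative_credit):>12,.0f} {np.mean(finals):>14.1f}"
    )

# Reading the table: the unregulated fractional-reserve economy collapses in
# most replicates; conservation policies triggered at 50% of the initial
# stock prevent every collapse while the 25% threshold comes too late in some
# runs; the full-reserve bank creates almost no credit (only its own interest
# surplus is lendable) and its economy never exhausts the resource base.
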