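"""Threshold-triggered conservation governance.

The government monitors the total natural resource stock.  Once it first
drops strictly below ``critical_biomass_fraction`` of the initial stock, a
package of four conservation policies activates permanently:

1. the precautionary principle — firms' technology-investment fraction is
   capped (default: frozen at zero);
2. speculation limits — the speculation rate is capped and new speculator
   borrowing is blocked;
3. protected-area expansion — the protected patch fraction is raised once by
   a fixed increment, patches drawn uniformly at random;
4. mandatory restoration — depleted, previously-harvested patches are flagged
   for restoration, funded per tick by the last harvester.

A ``critical_biomass_fraction`` of 0 means the trigger can never fire
(stock is never strictly below zero), which encodes the
no-government-intervention scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import Landscape, designate_protected

__all__ = ["Government", "check_trigger", "apply_policies"]


@dataclass
class Government:
    critical_biomass_fraction: float = 0.0
    intervention_active: bool = False
    tech_investment_cap: float = 0.0
    speculation_cap: float = 0.0
    protection_increment: float = 0.03
    restoration_mandate: bool = True
    trigger_tick: int | None = None
    protection_target: float | None = None  # fixed at activation

    def validate(self) -> None:
        for name in ("critical_biomass_fraction", "tech_investment_cap", "protection_increment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"governance.{name} must be in [0, 1]")
        if self.speculation_cap < 0:
            raise ValueError("governance.speculation_cap must be >= 0")


def check_trigger(total_stock: float, initial_stock: float, gov: Government) -> bool:
    """True iff the stock is strictly below the critical fraction of initial."""
    if initial_stock <= 0:
        raise ValueError("initial_stock must be positive")
    return total_stock < gov.critical_biomass_fraction * initial_stock


def apply_policies(state, gov: Government) -> None:
    """Apply the active policy package to the full simulation state.

    Idempotent within a run: the protected-area target is fixed once at
    activation, so repeated application never ratchets protection further
    (the protected count is still monotone non-decreasing).  Caps on
    technology investment and speculation are enforced every tick by the
    scheduler while the intervention is active.
    """
    if not gov.intervention_active:
        return
    landscape: Landscape = state.landscape
    # (ii) cap the speculation rate
    if state.market.speculation_rate > gov.speculation_cap:
        state.market.speculation_rate = gov.speculation_cap
    # (iii) enlarge the protected-area network (once)
    if gov.protection_target is None:
        gov.protection_target = min(
            landscape.protected_fraction() + gov.protection_increment, 1.0
        )
    designate_protected(landscape, gov.protection_target, state.rng)
    # (iv) mandate restoration of depleted, previously harvested patches
    if gov.restoration_mandate:
        depleted = (
            (landscape.stock <= 0.0)
            & (landscape.last_harvester >= 0)
            & ~landscape.under_restoration
            & ~landscape.protected
        )
        landscape.under_restoration |= depleted
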