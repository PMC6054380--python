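"""Spatial resource landscape.

A rectangular, non-toroidal grid of land parcels ("patches"), each carrying a
renewable biomass stock that regrows logistically toward a per-patch carrying
capacity.  Depletion to zero is absorbing: an exhausted patch only recovers
through active restoration (a paid, government-mandated process).  Patches can
be placed under protection, after which their stock can never be reduced by
extraction.

Biocapacity — the capacity of a parcel to produce useful biomass — is the
stock scaled by a yield factor and an equivalence factor, the two multipliers
used in ecological-footprint accounting to convert land-type productivity into
universal biologically-productive-area units.  Defaults correspond to
forest land and are placeholders in the absence of an empirical case study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnvironmentParams",
    "Patch",
    "Landscape",
    "logistic_increment",
    "grow_resource",
    "compute_biocapacity",
    "total_resource_stock",
    "designate_protected",
    "restore_patch",
]


@dataclass
class EnvironmentParams:
    """Landscape-level parameters.

    Parameters
    ----------
    grid_rows, grid_cols
        Grid dimensions (patch count = rows x cols).
    regrowth_rate
        Intrinsic per-tick logistic growth rate ``r``.
    carrying_capacity
        Per-patch maximum stock ``K`` (biomass units).
    initial_stock_per_patch
        Stock each patch starts with (defaults to ``K``: pristine landscape).
    yield_factor, equivalence_factor
        Footprint-accounting multipliers ``F_y``, ``F_eq`` (forest-land
        placeholder values).
    restoration_rate
        Biomass added per tick to a patch under (funded) restoration.
    reactivation_fraction
        Fraction of ``K`` at which a restored patch leaves restoration and
        resumes ordinary logistic growth.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    regrowth_rate: float = 0.12
    carrying_capacity: float = 100.0
    initial_stock_per_patch: float = 100.0
    yield_factor: float = 1.26
    equivalence_factor: float = 1.28
    restoration_rate: float = 1.0
    reactivation_fraction: float = 0.05

    def validate(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("environment.grid_rows/grid_cols must be positive")
        if self.carrying_capacity <= 0:
            raise ValueError("environment.carrying_capacity must be > 0")
        for name in (
            "regrowth_rate",
            "initial_stock_per_patch",
            "yield_factor",
            "equivalence_factor",
            "restoration_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"environment.{name} must be >= 0")
        if not 0.0 <= self.reactivation_fraction <= 1.0:
            raise ValueError("environment.reactivation_fraction must be in [0, 1]")


@dataclass
class Patch:
    """One land parcel."""

    patch_id: int
    row: int
    col: int
    resource_stock: float
    protected: bool = False
    under_restoration: bool = False

    def biocapacity(self, env: EnvironmentParams) -> float:
        return compute_biocapacity(self, env)


def logistic_increment(stock: float, rate: float, capacity: float):
    """One-step logistic growth increment ``r * R * (1 - R/K)``.

    Works element-wise on numpy arrays as well as scalars.
    """
    return rate * stock * (1.0 - stock / capacity)


def grow_resource(patch: Patch, env: EnvironmentParams) -> Patch:
    """Advance one patch by one growth tick (in place; the patch is returned).

    Extinction is absorbing: a stock of exactly zero does not regrow (the seed
    bank is gone); only restoration can revive such a patch.  The stock never
    exceeds the carrying capacity and never becomes negative.
    """
    if patch.resource_stock < 0:
        raise ValueError(f"patch {patch.patch_id} has negative stock (corrupted state)")
    inc = logistic_increment(
        patch.resource_stock, env.regrowth_rate, env.carrying_capacity
    )
    patch.resource_stock = float(
        np.clip(patch.resource_stock + inc, 0.0, env.carrying_capacity)
    )
    return patch


def compute_biocapacity(patch: Patch, env: EnvironmentParams) -> float:
    """Biocapacity ``B = R_s * F_y * F_eq`` of a single patch."""
    if patch.resource_stock < 0:
        raise ValueError("negative resource stock")
    return patch.resource_stock * env.yield_factor * env.equivalence_factor


def total_resource_stock(grid) -> float:
    """Total stock over a collection of patches or a :class:`Landscape`."""
    if isinstance(grid, Landscape):
        return float(grid.stock.sum())
    return float(sum(p.resource_stock for p in grid))


def restore_patch(patch: Patch, env: EnvironmentParams) -> Patch:
    """One tick of active restoration on a depleted patch.

    Adds ``restoration_rate`` biomass (capped at carrying capacity).  Once the
    stock reaches the re-activation fraction of capacity the restoration flag
    clears and the patch resumes ordinary logistic growth.
    """
    if not patch.under_restoration:
        raise ValueError(
            f"restore_patch called on patch {patch.patch_id} not under restoration"
        )
    patch.resource_stock = float(
        min(patch.resource_stock + env.restoration_rate, env.carrying_capacity)
    )
    if patch.resource_stock >= env.reactivation_fraction * env.carrying_capacity:
        patch.under_restoration = False
    return patch


class Landscape:
    """Vectorized patch grid.

    Stores per-patch state in flat numpy arrays indexed by patch id
    (row-major: ``patch_id = row * grid_cols + col``).  The scalar operations
    above define the semantics of a single patch; the array methods here apply
    the identical update rules to every patch at once.
    """

    def __init__(self, env: EnvironmentParams):
        env.validate()
        self.env = env
        n = env.grid_rows * env.grid_cols
        self.n_patches = n
        self.stock = np.full(
            n, min(env.initial_stock_per_patch, env.carrying_capacity), dtype=float
        )
        self.protected = np.zeros(n, dtype=bool)
        self.under_restoration = np.zeros(n, dtype=bool)
        # id of the firm that last extracted from each patch (-1 = never harvested)
        self.last_harvester = np.full(n, -1, dtype=int)
        self.initial_total_stock = float(self.stock.sum())

    # -- coordinate helpers -------------------------------------------------
    def coords(self, patch_id: int) -> tuple[int, int]:
        return divmod(int(patch_id), self.env.grid_cols)

    def patch_id(self, row: int, col: int) -> int:
        return int(row) * self.env.grid_cols + int(col)

    def patch(self, patch_id: int) -> Patch:
        """Materialize a :class:`Patch` record for one parcel (a copy)."""
        r, c = self.coords(patch_id)
        return Patch(
            patch_id=int(patch_id),
            row=r,
            col=c,
            resource_stock=float(self.stock[patch_id]),
            protected=bool(self.protected[patch_id]),
            under_restoration=bool(self.under_restoration[patch_id]),
        )

    def patches(self):
        return [self.patch(i) for i in range(self.n_patches)]

    # -- per-tick processes -------------------------------------------------
    def grow_all(self) -> float:
        """Logistic growth on every patch not under restoration.

        Returns the total biomass added (for mass-balance audit).
        """
        env = self.env
        growing = ~self.under_restoration
        inc = np.where(
            growing,
            logistic_increment(self.stock, env.regrowth_rate, env.carrying_capacity),
            0.0,
        )
        new = np.clip(self.stock + inc, 0.0, env.carrying_capacity)
        added = float((new - self.stock)[growing].sum())
        self.stock = new
        return added

    def restore_all(self, funded: np.ndarray | None = None) -> float:
        """One restoration tick on every flagged patch.

        ``funded`` optionally masks which restoring patches actually receive
        biomass this tick (restoration is a paid process; unfunded patches
        keep the flag but do not grow).  Returns total biomass added.
        """
        env = self.env
        active = self.under_restoration.copy()
        if funded is not None:
            active &= funded
        if not active.any():
            return 0.0
        new = np.minimum(
            self.stock + np.where(active, env.restoration_rate, 0.0),
            env.carrying_capacity,
        )
        added = float((new - self.stock)[active].sum())
        self.stock = new
        done = self.under_restoration & (
            self.stock >= env.reactivation_fraction * env.carrying_capacity
        )
        self.under_restoration[done] = False
        return added

    def extract(self, patch_id: int, amount: float) -> float:
        """Remove up to ``amount`` from one unprotected patch; returns taken."""
        if self.protected[patch_id]:
            raise ValueError(f"extraction attempted on protected patch {patch_id}")
        take = float(min(max(amount, 0.0), self.stock[patch_id]))
        self.stock[patch_id] -= take
        return take

    def protected_fraction(self) -> float:
        return float(self.protected.mean())

    def biocapacity_all(self) -> np.ndarray:
        return self.stock * self.env.yield_factor * self.env.equivalence_factor


def designate_protected(landscape: Landscape, target_fraction: float, rng) -> Landscape:
    """Expand the protected-area network to ``round(fraction * n)`` patches.

    Already-protected patches stay protected (monotone expansion); additional
    patches are drawn uniformly at random among the unprotected ones.  If the
    target is below the current protected count, nothing changes.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    n = landscape.n_patches
    target = int(round(target_fraction * n))
    current = int(landscape.protected.sum())
    extra = target - current
    if extra <= 0:
        return landscape
    candidates = np.flatnonzero(~landscape.protected)
    chosen = rng.choice(candidates, size=min(extra, candidates.size), replace=False)
    landscape.protected[chosen] = True
    return landscape
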