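"""Scenario presets, replicate ensembles, OFAT sweeps and regime labels.

The four canonical scenarios pair a banking regime with a conservation
threshold:

===================  ==================  =========================
name                 cash reserve ratio  critical biomass fraction
===================  ==================  =========================
fractional_no_gov    0.02                0    (never triggers)
fractional_gov25     0.02                0.25
fractional_gov50     0.02                0.50
full_reserve         1.00                0    (no intervention)
===================  ==================  =========================

Ensembles run a scenario over consecutive seeds and summarize each indicator
per tick as a mean with a standard-error band (sample standard deviation over
sqrt of the number of runs).  Runs that collapse early drop out of the band;
the summary is taken over the surviving runs at each tick and reports the
survivor count alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .simulation import INDICATOR_COLUMNS, RunResult, run

__all__ = [
    "ScenarioPreset",
    "PRESETS",
    "preset_config",
    "default_world",
    "small_world",
    "toy_world",
    "EnsembleSummary",
    "run_ensemble",
    "ofat_sweep",
    "classify_run",
]


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    cash_reserve_ratio: float
    critical_biomass_fraction: float

    def __post_init__(self):
        if self.cash_reserve_ratio >= 1.0 and self.critical_biomass_fraction != 0.0:
            raise ValueError(
                "full-reserve presets pair with critical_biomass_fraction 0 "
                "(no government intervention)"
            )


PRESETS: dict[str, ScenarioPreset] = {
    "fractional_no_gov": ScenarioPreset("fractional_no_gov", 0.02, 0.0),
    "fractional_gov25": ScenarioPreset("fractional_gov25", 0.02, 0.25),
    "fractional_gov50": ScenarioPreset("fractional_gov50", 0.02, 0.50),
    "full_reserve": ScenarioPreset("full_reserve", 1.0, 0.0),
}


def default_world() -> SimulationConfig:
    """Full-scale world: 100 x 100 grid, 30 firms, 300 households."""
    return SimulationConfig()


def small_world() -> SimulationConfig:
    """Half-linear-scale world (50 x 50 grid) for desk-speed ensembles.

    Agent counts are scaled with grid area so per-patch extraction pressure
    matches the full-scale world; dynamics are qualitatively identical.
    """
    cfg = SimulationConfig()
    cfg.environment.grid_rows = 50
    cfg.environment.grid_cols = 50
    cfg.economy.n_firms = 8
    cfg.economy.n_households = 80
    cfg.economy.n_speculators = 10
    cfg.economy.max_firms = 24
    return cfg


def toy_world() -> SimulationConfig:
    """Tiny deterministic fixture world (10 x 10, a handful of agents)."""
    cfg = SimulationConfig()
    cfg.environment.grid_rows = 10
    cfg.environment.grid_cols = 10
    cfg.economy.n_firms = 3
    cfg.economy.n_households = 12
    cfg.economy.n_speculators = 3
    cfg.economy.max_firms = 6
    cfg.simulation.horizon = 100
    return cfg


def preset_config(
    preset: ScenarioPreset | str, base: SimulationConfig | None = None
) -> SimulationConfig:
    """Apply a scenario preset to a base configuration (default: small world)."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    cfg = (base or small_world()).copy()
    cfg.economy.cash_reserve_ratio = preset.cash_reserve_ratio
    cfg.governance.critical_biomass_fraction = preset.critical_biomass_fraction
    return cfg.validate()


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------
@dataclass
class EnsembleSummary:
    """Per-tick cross-replicate summary of one scenario."""

    name: str
    replicates: int
    seeds: list[int]
    summary: pd.DataFrame  # tick, survivors, <ind>_mean, <ind>_se per indicator
    regimes: list[str]  # per-replicate regime label
    collapse_times: list[int | None]
    cumulative_credit: list[float]
    runs: list[RunResult] | None = None

    @property
    def n_collapsed(self) -> int:
        return sum(1 for r in self.regimes if r == "collapse")

    @property
    def collapse_frequency(self) -> float:
        return self.n_collapsed / self.replicates


def summarize_runs(name: str, runs: list[RunResult], keep_series: bool) -> EnsembleSummary:
    indicators = [c for c in INDICATOR_COLUMNS if c != "tick"]
    max_ticks = max((len(r.indicators) for r in runs), default=0)
    rows = []
    for t in range(1, max_ticks + 1):
        alive = [r.indicators for r in runs if len(r.indicators) >= t]
        row: dict = {"tick": t, "survivors": len(alive)}
        for ind in indicators:
            vals = np.array([df[ind].iloc[t - 1] for df in alive])
            row[f"{ind}_mean"] = float(vals.mean())
            row[f"{ind}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) >= 2 else np.nan
            )
        rows.append(row)
    summary = pd.DataFrame(rows)
    regimes = [classify_run(r.indicators, r.halt_reason) for r in runs]
    collapse_times = [
        r.halt_tick if r.halt_reason == "resource_collapse" else None for r in runs
    ]
    return EnsembleSummary(
        name=name,
        replicates=len(runs),
        seeds=[r.seed for r in runs],
        summary=summary,
        regimes=regimes,
        collapse_times=collapse_times,
        cumulative_credit=[r.cumulative_credit for r in runs],
        runs=runs if keep_series else None,
    )


def run_ensemble(
    preset: ScenarioPreset | str | SimulationConfig,
    replicates: int,
    base_seed: int = 0,
    base: SimulationConfig | None = None,
    keep_series: bool = False,
) -> EnsembleSummary:
    """Run ``replicates`` seeded copies of a scenario and summarize them.

    Seeds are ``base_seed .. base_seed + replicates - 1`` so that scenario
    comparisons can share seeds.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if isinstance(preset, SimulationConfig):
        cfg, name = preset, "custom"
    else:
        cfg = preset_config(preset, base=base)
        name = preset if isinstance(preset, str) else preset.name
    runs = [run(cfg, seed=base_seed + i) for i in range(replicates)]
    return summarize_runs(name, runs, keep_series)


def ofat_sweep(
    base: ScenarioPreset | str | SimulationConfig,
    parameter_name: str,
    values,
    replicates: int,
    base_seed: int = 0,
) -> dict:
    """One-factor-at-a-time sweep: one ensemble per parameter value.

    ``parameter_name`` is a dotted config field such as
    ``governance.critical_biomass_fraction``; all other parameters stay at
    the base scenario's values.  Returns ``{"summaries": {value: EnsembleSummary},
    "table": tidy DataFrame}`` keyed by (parameter value, tick, indicator).
    """
    if isinstance(base, SimulationConfig):
        cfg0 = base.copy()
    else:
        cfg0 = preset_config(base)
    cfg0.get(parameter_name)  # raises KeyError on unknown parameters
    summaries = {}
    frames = []
    for v in values:
        cfg = cfg0.with_value(parameter_name, v).validate()
        ens = run_ensemble(cfg, replicates, base_seed=base_seed)
        summaries[v] = ens
        frame = ens.summary.copy()
        frame.insert(0, parameter_name, v)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return {"summaries": summaries, "table": table}


# --------------------------------------------------------------------------
# regime classification
# --------------------------------------------------------------------------
def classify_run(
    series: pd.DataFrame,
    halt_reason: str,
    stability_fraction: float = 0.25,
) -> str:
    """Label a finished run ``collapse``, ``stable`` or ``decline``.

    ``collapse``: the run halted on resource collapse.  ``stable``: the final
    stock is at least ``stability_fraction`` of the initial recorded stock
    and the stock trend over the last quartile of ticks is non-negative.
    Anything else is ``decline``.
    """
    if len(series) == 0:
        raise ValueError("cannot classify an empty indicator series")
    if halt_reason == "resource_collapse":
        return "collapse"
    stock = series["natural_resource_stock"].to_numpy()
    initial = stock[0]
    if initial <= 0:
        return "stable"
    q = max(len(stock) // 4, 2)
    tail = stock[-q:]
    slope = np.polyfit(np.arange(len(tail)), tail, 1)[0] if len(tail) >= 2 else 0.0
    slope_tol = 1e-9 * max(1.0, float(np.abs(tail).max()))
    if stock[-1] >= stability_fraction * initial and slope >= -slope_tol:
        return "stable"
    return "decline"
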