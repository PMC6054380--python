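"""Per-tick scheduler, indicator recording and collapse detection.

Each tick executes eleven processes in a fixed order:

    (i)    patches compute biomass stock (growth + funded restoration)
    (ii)   firms extract resources (and pay the extraction investment)
    (iii)  households compute demand, movement and energy
    (iv)   firms compute prices and sales; market aggregates update
    (v)    firms compute labour and finance (wages, productivity, technology)
    (vi)   the bank computes finance (deposit partition, deposit interest)
    (vii)  firms borrow credits
    (viii) firms consider business expansion
    (ix)   speculators compute speculation
    (x)    firms and speculators compute credit repayment
    (xi)   the government computes conservation policies

after which an indicator row is recorded and collapse detection runs: the
run halts once the total resource stock falls strictly below a small
fraction (default 1%) of its initial value.

Within a process, agents act in an order re-randomized every tick from the
run's seed (standard ABM practice to avoid fixed-order artifacts); the
processes themselves are strictly ordered.  A double-entry ledger row is
recorded every tick so that money and biomass conservation can be audited
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import economy as econmod
from .config import SimulationConfig
from .economy import (
    Bank,
    Firm,
    Household,
    MarketState,
    Speculator,
    bank_accounting,
    compute_investment,
    compute_productivity,
    consider_expansion,
    firm_borrow,
    invest_in_technology,
    pay_deposit_interest,
    pay_wages,
    repay_credits,
    sell_goods,
    set_price,
    speculator_step,
    update_speculation,
)
from .environment import Landscape
from .governance import apply_policies, check_trigger

__all__ = [
    "SimulationState",
    "RunResult",
    "INDICATOR_COLUMNS",
    "initialize",
    "step",
    "detect_collapse",
    "run",
]

INDICATOR_COLUMNS = [
    "tick",
    "natural_resource_stock",
    "real_gdp_growth",
    "debt_growth_rate",
    "speculation_rate",
    "monetary_capital_firms",
    "monetary_capital_households",
    "monetary_capital_bank",
    "technology_efficiency",
    "mean_price",
    "employment",
    "active_speculators",
]

PROCESS_NAMES = [
    "patches_biomass",
    "firm_extraction",
    "household_demand",
    "firm_pricing_sales",
    "firm_labour_finance",
    "bank_finance",
    "firm_borrowing",
    "firm_expansion",
    "speculation",
    "credit_repayment",
    "government_policies",
]


@dataclass
class SimulationState:
    config: SimulationConfig
    landscape: Landscape
    firms: list[Firm]
    households: list[Household]
    speculators: list[Speculator]
    bank: Bank
    market: MarketState
    rng: np.random.Generator
    tick: int = 0
    halted: bool = False
    halt_reason: str = "none"  # none | resource_collapse | horizon_reached
    initial_total_stock: float = 0.0
    rng_seed: int = 0
    indicators: list = field(default_factory=list)
    ledger: list = field(default_factory=list)
    process_log: list = field(default_factory=list)
    _prev_debt: float = 0.0
    _next_firm_id: int = 0
    _household_pool: float = 0.0  # firm spending routed to the household sector

    @property
    def government(self):
        return self.config.governance

    # -- aggregates ---------------------------------------------------------
    def total_money(self) -> float:
        """Counted money aggregate: agent capitals plus bank equity."""
        return (
            sum(f.capital for f in self.firms)
            + sum(h.capital for h in self.households)
            + sum(s.capital for s in self.speculators)
            + self.bank.interest_surplus
        )

    def total_debt(self) -> float:
        return self.bank.outstanding_total()

    def active_firms(self) -> list[Firm]:
        return [f for f in self.firms if not f.bankrupt]


def initialize(config: SimulationConfig, seed: int | None = None) -> SimulationState:
    """Build a fresh world from a validated configuration and a seed."""
    config = config.copy().validate()
    if seed is None:
        seed = config.simulation.seed
    rng = np.random.default_rng(seed)
    env = config.environment
    econ = config.economy
    landscape = Landscape(env)

    n_patches = landscape.n_patches
    firm_patches = (
        rng.choice(n_patches, size=min(econ.n_firms, n_patches), replace=False)
        if econ.n_firms > 0
        else np.array([], dtype=int)
    )
    firms = [
        Firm(
            firm_id=i,
            patch_id=int(p),
            capital=econ.initial_firm_capital,
            capital_prev=econ.initial_firm_capital,
            biomass_reserve=econ.initial_biomass_reserve,
            price=econ.initial_price,
        )
        for i, p in enumerate(firm_patches)
    ]
    households = []
    for j in range(econ.n_households):
        row = int(rng.integers(env.grid_rows))
        col = int(rng.integers(env.grid_cols))
        employer = firms[j % len(firms)].firm_id if firms else None
        households.append(
            Household(
                household_id=j,
                row=row,
                col=col,
                capital=econ.initial_household_capital,
                employer=employer,
            )
        )
    for f in firms:
        f.labour = sum(1 for h in households if h.employer == f.firm_id)
    speculators = [
        Speculator(spec_id=k, capital=econ.initial_speculator_capital)
        for k in range(econ.n_speculators)
    ]
    bank = Bank(cash_reserve_ratio=econ.cash_reserve_ratio)
    bank.interest_surplus = econ.initial_bank_equity
    bank_accounting(bank, households)

    state = SimulationState(
        config=config,
        landscape=landscape,
        firms=firms,
        households=households,
        speculators=speculators,
        bank=bank,
        market=MarketState(mean_price=econ.initial_price, mean_price_prev=econ.initial_price),
        rng=rng,
        initial_total_stock=landscape.initial_total_stock,
        rng_seed=int(seed),
        _next_firm_id=len(firms),
    )
    return state


# --------------------------------------------------------------------------
# the eleven processes
# --------------------------------------------------------------------------
def _p1_patches(state: SimulationState) -> None:
    econ = state.config.economy
    land = state.landscape
    state._growth = land.grow_all()

    # funded restoration: the last harvester pays, within its budget
    restoration = 0.0
    restoring = np.flatnonzero(land.under_restoration)
    if restoring.size:
        funded = np.zeros(land.n_patches, dtype=bool)
        firms_by_id = {f.firm_id: f for f in state.firms}
        cost = econ.restoration_cost_rate
        by_firm: dict[int, list[int]] = {}
        for pid in restoring:
            by_firm.setdefault(int(land.last_harvester[pid]), []).append(int(pid))
        for fid, pids in sorted(by_firm.items()):
            firm = firms_by_id.get(fid)
            if firm is None or firm.bankrupt or firm.capital <= 0:
                continue
            budget = econ.restoration_budget_fraction * firm.capital
            n_afford = len(pids) if cost <= 0 else int(budget // cost)
            paid_for = pids[: max(n_afford, 0)]
            if not paid_for:
                continue
            payment = cost * len(paid_for)
            firm.capital -= payment
            state._household_pool += payment
            funded[paid_for] = True
        restoration = land.restore_all(funded)
    state._restoration = restoration


def _maybe_relocate(firm: Firm, state: SimulationState, need: float) -> None:
    """Move to the richest unprotected patch within the move radius when the
    local patch cannot meet the extraction target."""
    land = state.landscape
    ids = _window(land, firm.patch_id, state.config.economy.harvest_radius)
    ids = ids[~land.protected[ids]]
    if ids.size and land.stock[ids].sum() >= need:
        return
    env = land.env
    radius = state.config.economy.firm_move_radius
    row, col = land.coords(firm.patch_id)
    r0, r1 = max(row - radius, 0), min(row + radius + 1, env.grid_rows)
    c0, c1 = max(col - radius, 0), min(col + radius + 1, env.grid_cols)
    stock2d = land.stock.reshape(env.grid_rows, env.grid_cols)[r0:r1, c0:c1]
    prot2d = land.protected.reshape(env.grid_rows, env.grid_cols)[r0:r1, c0:c1]
    window = np.where(prot2d, -1.0, stock2d)
    flat_best = int(window.argmax())  # first occurrence = lowest patch id in window
    br, bc = divmod(flat_best, window.shape[1])
    best_id = land.patch_id(r0 + br, c0 + bc)
    here = -1.0 if land.protected[firm.patch_id] else land.stock[firm.patch_id]
    if window[br, bc] > here:
        firm.patch_id = best_id


def _window(land: Landscape, patch_id: int, radius: int):
    env = land.env
    row, col = land.coords(patch_id)
    r0, r1 = max(row - radius, 0), min(row + radius + 1, env.grid_rows)
    c0, c1 = max(col - radius, 0), min(col + radius + 1, env.grid_cols)
    rows = np.repeat(np.arange(r0, r1), c1 - c0)
    cols = np.tile(np.arange(c0, c1), r1 - r0)
    return rows * env.grid_cols + cols


def _harvest(firm: Firm, state: SimulationState, target: float) -> float:
    """Harvest up to ``target`` biomass from the firm's concession area.

    The concession is the window of ``harvest_radius`` around the firm's
    patch; patches are harvested richest-first, each bounded by its
    remaining stock, protected patches untouchable.
    """
    land = state.landscape
    ids = _window(land, firm.patch_id, state.config.economy.harvest_radius)
    ids = ids[~land.protected[ids]]
    if ids.size == 0 or target <= 0:
        return 0.0
    order = np.argsort(-land.stock[ids], kind="stable")
    taken_total = 0.0
    for pid in ids[order]:
        if target <= 1e-12:
            break
        taken = land.extract(int(pid), target)
        if taken > 0:
            land.last_harvester[pid] = firm.firm_id
            firm.biomass_reserve += taken
            target -= taken
            taken_total += taken
    return taken_total


def _p2_extraction(state: SimulationState) -> None:
    econ = state.config.economy
    extraction = 0.0
    reserve_inflow = 0.0
    investment = 0.0
    order = state.rng.permutation(len(state.firms))
    for idx in order:
        firm = state.firms[idx]
        if firm.bankrupt:
            continue
        target = max(
            0.0,
            firm.demand * firm.labour * econ.conversion_factor * firm.tech_efficiency
            - firm.biomass_reserve,
        )
        if target > 0:
            _maybe_relocate(firm, state, target)
            before = firm.biomass_reserve
            taken = _harvest(firm, state, target)
            extraction += taken
            reserve_inflow += firm.biomass_reserve - before
        k = compute_investment(firm, state.market, econ)
        if k > 0:
            firm.capital -= k
            state._household_pool += k
            investment += k
    state._extraction = extraction
    state._reserve_inflow = reserve_inflow
    state._investment = investment


def _p3_households(state: SimulationState) -> None:
    """Vectorized movement/demand for the whole household sector.

    Households do not interact within this process, so the vectorized update
    is exactly equivalent to sequential per-household steps (a property the
    test suite asserts against :func:`ecocredit.economy.household_step`).
    """
    econ = state.config.economy
    land = state.landscape
    for f in state.firms:
        f.demand = 0.0
    active = state.active_firms()
    agd = 0.0
    buyers: dict[int, list[tuple[Household, float]]] = {f.firm_id: [] for f in active}
    if active and state.households:
        cols = land.env.grid_cols
        f_pos = np.array([divmod(f.patch_id, cols) for f in active], dtype=float)
        f_price = np.array([f.price for f in active])
        h_row = np.array([h.row for h in state.households], dtype=float)
        h_col = np.array([h.col for h in state.households], dtype=float)
        h_cap = np.array([h.capital for h in state.households])
        dist = np.maximum(
            np.abs(h_row[:, None] - f_pos[None, :, 0]),
            np.abs(h_col[:, None] - f_pos[None, :, 1]),
        )
        # move one step toward the cheapest distance-discounted firm
        score = f_price[None, :] * np.exp(econ.distance_decay * dist)
        choice = score.argmin(axis=1)
        t_row = f_pos[choice, 0]
        t_col = f_pos[choice, 1]
        new_row = h_row + np.sign(t_row - h_row)
        new_col = h_col + np.sign(t_col - h_col)
        new_dist = np.maximum(
            np.abs(new_row[:, None] - f_pos[None, :, 0]),
            np.abs(new_col[:, None] - f_pos[None, :, 1]),
        )
        # per-pair demand, spending-capped per household
        base = h_cap[:, None] / (f_price[None, :] * econ.accelerator)
        demand = np.minimum(
            base * np.exp(-econ.distance_decay * new_dist), h_cap[:, None] / f_price[None, :]
        )
        demand = np.maximum(demand, 0.0)
        spend = demand @ f_price
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(spend > h_cap, h_cap / np.where(spend > 0, spend, 1.0), 1.0)
        demand *= scale[:, None]
        for i, h in enumerate(state.households):
            h.row = int(new_row[i])
            h.col = int(new_col[i])
            h.energy = max(h.energy - econ.energy_consumption, 0.0)
            h.demand = float(demand[i].sum())
            h.target_firm = active[choice[i]].firm_id
            agd += h.demand
        for j, firm in enumerate(active):
            col_d = demand[:, j]
            firm.demand = float(col_d.sum())
            bl = buyers[firm.firm_id]
            for i, h in enumerate(state.households):
                if col_d[i] > 0:
                    bl.append((h, float(col_d[i])))
    else:
        for h in state.households:
            h.energy = max(h.energy - econ.energy_consumption, 0.0)
            h.demand = 0.0
            h.target_firm = None
    state._buyers = buyers
    state.market.aggregate_demand = agd


def _p4_pricing_sales(state: SimulationState) -> None:
    econ = state.config.economy
    market = state.market
    # partial geometric adjustment toward the behavioural price target
    alpha = econ.price_adjustment_speed
    for f in state.active_firms():
        p_old = f.price
        target = set_price(f, market, econ)
        f.price = max(p_old * (target / p_old) ** alpha, econ.price_min)
    gdp = 0.0
    output = 0.0
    for f in state.active_firms():
        goods, revenue = sell_goods(f, state._buyers.get(f.firm_id, []), econ)
        gdp += revenue
        output += goods
    state._goods_sold = output
    market.gdp_prev = market.gdp
    market.output_prev = market.output
    market.mean_price_prev = market.mean_price
    market.gdp = gdp
    market.output = output
    if output > 0:
        market.mean_price = gdp / output
    # growth rates are taken on exponentially smoothed levels: the goods
    # market has a natural alternating (cobweb) micro-cycle, and growth-
    # sensitive behaviour responds to the trend, not tick-to-tick flicker
    beta = econ.trend_smoothing
    trend_prev = market.gdp_trend
    if trend_prev <= 0:
        # seed the trend at the first observed GDP level; no growth signal yet
        market.gdp_trend = market.gdp
        market.gdp_growth = 0.0
    else:
        market.gdp_trend = (1 - beta) * trend_prev + beta * market.gdp
        market.gdp_growth = (market.gdp_trend - trend_prev) / trend_prev
    market._mean_price_trend_prev = market.mean_price_trend
    market.mean_price_trend = (1 - beta) * market.mean_price_trend + beta * market.mean_price
    update_speculation(market)


def _p5_labour_finance(state: SimulationState) -> None:
    econ = state.config.economy
    gov = state.government
    workers: dict[int, list[Household]] = {}
    unemployed: list[Household] = []
    for h in state.households:
        if h.employer is not None:
            workers.setdefault(h.employer, []).append(h)
        else:
            unemployed.append(h)
    tech_spend_total = 0.0
    order = state.rng.permutation(len(state.firms))
    for idx in order:
        firm = state.firms[idx]
        if firm.bankrupt:
            continue
        staff = workers.get(firm.firm_id, [])
        if firm.capital <= 0 and staff:
            for h in staff:
                h.employer = None
            unemployed.extend(staff)
            staff = []
            workers[firm.firm_id] = []
        elif firm.capital > econ.hire_capital_min:
            while len(staff) < econ.target_labour and unemployed:
                h = unemployed.pop()
                h.employer = firm.firm_id
                staff.append(h)
        firm.labour = len(staff)
        pay_wages(firm, staff, econ)
        compute_productivity(firm)
        cap = gov.tech_investment_cap if gov.intervention_active else None
        tech_spend_total += invest_in_technology(firm, econ, cap_fraction=cap)
    state._household_pool += tech_spend_total
    state._tech_spend = tech_spend_total


def _p6_bank(state: SimulationState) -> None:
    econ = state.config.economy
    # distribute firm real-expenditure flows to the household sector
    pool = state._household_pool
    state._household_pool = 0.0
    if pool > 0:
        if state.households:
            share = pool / len(state.households)
            for h in state.households:
                h.capital += share
        else:
            state.bank.interest_surplus += pool
    state._deposit_interest = pay_deposit_interest(state.bank, state.households, econ)
    # the bank's net interest income is spent back into the economy as
    # dividends, closing the monetary circuit
    excess = state.bank.interest_surplus - econ.initial_bank_equity
    payout = econ.bank_dividend_rate * max(excess, 0.0)
    if payout > 0 and state.households:
        state.bank.interest_surplus -= payout
        share = payout / len(state.households)
        for h in state.households:
            h.capital += share
    bank_accounting(state.bank, state.households)


def _p7_borrowing(state: SimulationState) -> None:
    econ = state.config.economy
    new_credit = 0.0
    order = state.rng.permutation(len(state.firms))
    for idx in order:
        firm = state.firms[idx]
        if firm.bankrupt:
            continue
        new_credit += firm_borrow(firm, state.bank, state.market, econ)
    state._new_loans = new_credit


def _p8_expansion(state: SimulationState) -> None:
    econ = state.config.economy
    if len(state.firms) >= econ.max_firms:
        return
    spawned: list[Firm] = []
    order = state.rng.permutation(len(state.firms))
    for idx in order:
        if len(state.firms) + len(spawned) >= econ.max_firms:
            break
        firm = state.firms[idx]
        if firm.bankrupt:
            continue
        before = state.bank.cumulative_credit
        child = consider_expansion(
            firm, state.landscape, state.bank, econ, state._next_firm_id
        )
        state._new_loans += state.bank.cumulative_credit - before
        if child is not None:
            state._next_firm_id += 1
            spawned.append(child)
    state.firms.extend(spawned)


def _p9_speculation(state: SimulationState) -> None:
    econ = state.config.economy
    gov = state.government
    blocked = gov.intervention_active
    order = state.rng.permutation(len(state.speculators))
    for idx in order:
        spec = state.speculators[idx]
        before = state.bank.cumulative_credit
        rec = speculator_step(
            spec, state.market, state.bank, econ, borrowing_blocked=blocked
        )
        state._new_loans += state.bank.cumulative_credit - before
        state._written_off += rec["written_off"]


def _p10_repayment(state: SimulationState) -> None:
    econ = state.config.economy
    firms_by_id = {f.firm_id: f for f in state.firms}
    specs_by_id = {s.spec_id: s for s in state.speculators}
    principal = interest = written = 0.0
    for loan in sorted(state.bank.loans, key=lambda l: l.loan_id):
        if loan.balance <= 0:
            continue
        if loan.borrower_kind == "firm":
            borrower = firms_by_id.get(loan.borrower_id)
        else:
            borrower = specs_by_id.get(loan.borrower_id)
        if borrower is None:
            continue
        if getattr(borrower, "bankrupt", False) or not getattr(borrower, "active", True):
            written += econmod.write_off(state.bank, borrower, loan)
            continue
        rec = repay_credits(borrower, state.bank, loan, econ)
        principal += rec["principal"]
        interest += rec["interest"]
        written += rec["written_off"]
        if rec["defaulted"]:
            if isinstance(borrower, Firm):
                borrower.bankrupt = True
                for h in state.households:
                    if h.employer == borrower.firm_id:
                        h.employer = None
                borrower.labour = 0
            else:
                borrower.active = False
    state.bank.loans = [l for l in state.bank.loans if l.balance > 0]
    state._principal_repaid += principal
    state._interest_received += interest
    state._written_off += written


def _p11_government(state: SimulationState) -> None:
    gov = state.government
    total = float(state.landscape.stock.sum())
    if (
        not gov.intervention_active
        and state.initial_total_stock > 0
        and check_trigger(total, state.initial_total_stock, gov)
    ):
        gov.intervention_active = True
        gov.trigger_tick = state.tick
    apply_policies(state, gov)


_PROCESSES = [
    _p1_patches,
    _p2_extraction,
    _p3_households,
    _p4_pricing_sales,
    _p5_labour_finance,
    _p6_bank,
    _p7_borrowing,
    _p8_expansion,
    _p9_speculation,
    _p10_repayment,
    _p11_government,
]


def detect_collapse(state: SimulationState, epsilon_fraction: float | None = None) -> bool:
    """Natural-resource collapse: stock strictly below epsilon * initial.

    When detected the state halts with reason ``resource_collapse`` and is
    never stepped again.
    """
    if epsilon_fraction is None:
        epsilon_fraction = state.config.simulation.collapse_epsilon
    total = float(state.landscape.stock.sum())
    collapsed = total < epsilon_fraction * state.initial_total_stock
    if collapsed:
        state.halted = True
        state.halt_reason = "resource_collapse"
    return collapsed


def step(state: SimulationState) -> SimulationState:
    """Advance the world by exactly one tick (processes (i)-(xi))."""
    if state.halted:
        raise RuntimeError("cannot step a halted simulation state")
    record = state.config.simulation.record_processes
    # per-tick scratch accumulators
    state._growth = state._restoration = state._extraction = 0.0
    state._reserve_inflow = state._investment = state._goods_sold = 0.0
    state._new_loans = state._principal_repaid = 0.0
    state._interest_received = state._written_off = 0.0
    state._tech_spend = state._deposit_interest = 0.0

    for name, proc in zip(PROCESS_NAMES, _PROCESSES):
        proc(state)
        if record:
            state.process_log.append((state.tick, name))

    state.tick += 1
    _record(state)
    for f in state.firms:
        f.capital_prev = f.capital
    detect_collapse(state)
    return state


def _record(state: SimulationState) -> None:
    market = state.market
    debt = state.total_debt()
    debt_growth = (
        (debt - state._prev_debt) / state._prev_debt if state._prev_debt > 1e-12 else 0.0
    )
    state._prev_debt = debt
    real_growth = (
        (market.output - market.output_prev) / market.output_prev
        if market.output_prev > 0
        else 0.0
    )
    active = state.active_firms()
    tech = (
        float(np.mean([f.tech_efficiency for f in active]))
        if active
        else (float(np.mean([f.tech_efficiency for f in state.firms])) if state.firms else 1.0)
    )
    bank = state.bank
    state.indicators.append(
        {
            "tick": state.tick,
            "natural_resource_stock": float(state.landscape.stock.sum()),
            "real_gdp_growth": real_growth,
            "debt_growth_rate": debt_growth,
            "speculation_rate": market.speculation_rate,
            "monetary_capital_firms": sum(f.capital for f in state.firms),
            "monetary_capital_households": sum(h.capital for h in state.households),
            "monetary_capital_bank": bank.withdrawable_capital + bank.bank_reserves,
            "technology_efficiency": tech,
            "mean_price": market.mean_price,
            "employment": sum(f.labour for f in state.firms),
            "active_speculators": sum(1 for s in state.speculators if s.active),
        }
    )
    deposits = sum(h.capital for h in state.households)
    state.ledger.append(
        {
            "tick": state.tick,
            "money_total": state.total_money(),
            "new_loans": state._new_loans,
            "principal_repaid": state._principal_repaid,
            "interest_received": state._interest_received,
            "deposit_interest_paid": state._deposit_interest,
            "written_off": state._written_off,
            "growth": state._growth,
            "restoration": state._restoration,
            "extraction": state._extraction,
            "reserve_inflow": state._reserve_inflow,
            "goods_sold": state._goods_sold,
            "deposits": deposits,
            "withdrawable_capital": state.bank.withdrawable_capital,
            "bank_reserves": state.bank.bank_reserves,
            "outstanding_debt": debt,
            "cumulative_credit": state.bank.cumulative_credit,
        }
    )


@dataclass
class RunResult:
    """Full output of one simulation run."""

    indicators: pd.DataFrame
    ledger: pd.DataFrame
    halt_reason: str
    halt_tick: int
    seed: int
    config: SimulationConfig
    cumulative_credit: float

    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "halt_reason": self.halt_reason,
            "halt_tick": self.halt_tick,
            "ticks_run": int(len(self.indicators)),
            "cumulative_credit": self.cumulative_credit,
        }

    def write_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.indicators.to_csv(path, index=False)
        if sidecar:
            path.with_suffix(".json").write_text(json.dumps(self.metadata(), indent=2))

    def to_csv_bytes(self) -> bytes:
        return self.indicators.to_csv(index=False).encode()


def run(config: SimulationConfig, seed: int | None = None) -> RunResult:
    """Initialize from ``config`` and step until horizon or halt."""
    state = initialize(config, seed=seed)
    horizon = config.simulation.horizon
    while state.tick < horizon and not state.halted:
        step(state)
    if not state.halted:
        state.halted = True
        if state.halt_reason == "none":
            state.halt_reason = "horizon_reached"
    indicators = pd.DataFrame(state.indicators, columns=INDICATOR_COLUMNS)
    ledger = pd.DataFrame(state.ledger)
    return RunResult(
        indicators=indicators,
        ledger=ledger,
        halt_reason=state.halt_reason,
        halt_tick=state.tick,
        seed=state.rng_seed,
        config=config,
        cumulative_credit=state.bank.cumulative_credit,
    )
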