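"""Economic agents and the core behavioural functions.

The economy is a monetary circuit: firms extract biomass from the landscape,
convert it to a single consumption good and sell it to households; households
supply labour for a nominal wage and hold their money as bank deposits; a
single commercial bank lends credit to firms and speculators and pays deposit
interest; speculators borrow to bet on the direction of the goods price and
have no hand in production.

Eight small algebraic functions drive agent behaviour:

    biocapacity        B   = R_s * F_y * F_eq            (environment module)
    resource extraction R_e = D * L * c - B_r
    demand             D   = H_c / (P * v)   (distance-discounted)
    investment         K   = AGD(t-1) * L * F_c * M_c
    price              P   = D * P_k / B_r
    productivity       p   = (F_c(t) - F_c(t-1)) / L
    nominal wage       W_n = W_c * F_c / L
    speculation        P_k = k_g * Y

Money accounting convention (stock-flow consistent, endogenous money): the
counted money aggregate is firm + household + speculator capital plus the
bank's equity (``interest_surplus``).  Household capital *is* the deposit
stock; the bank's two monetary stocks — withdrawable capital and bank
reserves — are the reserve-ratio partition of those deposits plus lending
headroom, recomputed every accounting step.  Granting a loan creates money,
repaying principal destroys it, defaulted balances are written off against
bank equity (unpaid debt becomes the bank's debt), and every other operation
is a pure transfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "EconomyParams",
    "Firm",
    "Household",
    "Speculator",
    "Loan",
    "Bank",
    "MarketState",
    "compute_demand",
    "extract_resources",
    "compute_investment",
    "set_price",
    "sell_goods",
    "compute_productivity",
    "pay_wages",
    "bank_lend",
    "repay_credits",
    "update_speculation",
    "speculator_step",
    "consider_expansion",
    "invest_in_technology",
    "household_step",
    "bank_accounting",
]


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------
@dataclass
class EconomyParams:
    """Behavioural coefficients and agent-pool sizes.

    The coefficient values are configurable placeholders calibrated so the
    coupled system reproduces the qualitative regimes of a debt-based
    boom-bust economy; see docs/methods.md for the calibration rationale.
    """

    n_firms: int = 30
    n_households: int = 300
    n_speculators: int = 20

    cash_reserve_ratio: float = 0.02  # 0.02 fractional-reserve, 1.0 full-reserve
    conversion_factor: float = 0.3  # c: goods per biomass unit
    accelerator: float = 3.5  # v
    correction_factor: float = 2e-5  # M_c
    wage_coefficient: float = 0.4  # W_c, fraction of firm capital paid as wages
    credit_interest_rate: float = 0.05  # per tick
    deposit_interest_rate: float = 0.005  # per tick
    loan_term: int = 20  # ticks
    tech_investment_fraction: float = 0.1
    tech_efficiency_gain: float = 1e-4  # efficiency multiplier per money unit
    bank_dividend_rate: float = 0.2  # payout rate on bank equity above its endowment
    distance_decay: float = 0.05  # demand decay per grid cell

    # numerical guards
    reserve_floor: float = 1e-6  # denominator floor for B_r in the price rule
    speculation_price_floor: float = 25.0  # floor for P_k in the price rule
    price_min: float = 1e-3
    price_adjustment_speed: float = 0.2  # geometric adjustment toward the price target
    trend_smoothing: float = 0.3  # EMA weight for GDP/price trends driving k_g
    max_tech_efficiency: float = 1e6  # numerical ceiling, far above operating range

    # credit market
    debt_to_capital_cap: float = 8.0
    bankruptcy_floor: float = 1.0
    working_capital_target: float = 450.0
    growth_borrow_fraction: float = 0.5  # opportunistic borrowing per unit GDP growth
    speculator_borrow_fraction: float = 0.5

    # firm demography
    expansion_cost: float = 400.0
    expansion_trigger_multiple: float = 2.0
    max_firms: int = 90
    firm_move_radius: int = 8
    harvest_radius: int = 1  # concession area half-width around the firm's patch
    target_labour: int = 10
    hire_capital_min: float = 20.0

    # restoration funding
    restoration_cost_rate: float = 1.0  # money per patch-tick of restoration
    restoration_budget_fraction: float = 0.005  # capital share a firm will spend on it

    # initial endowments
    initial_firm_capital: float = 200.0
    initial_household_capital: float = 100.0
    initial_speculator_capital: float = 100.0
    initial_bank_equity: float = 100.0
    initial_biomass_reserve: float = 50.0
    initial_price: float = 1.0

    # household energy bookkeeping
    energy_consumption: float = 1.0
    energy_per_good: float = 1.0

    def validate(self) -> None:
        if self.credit_interest_rate < self.deposit_interest_rate:
            raise ValueError(
                "economy.credit_interest_rate must be >= deposit_interest_rate "
                "(the spread is the bank's income source)"
            )
        if self.conversion_factor <= 0:
            raise ValueError("economy.conversion_factor must be > 0")
        if self.accelerator <= 0:
            raise ValueError("economy.accelerator must be > 0")
        if not 0.0 < self.wage_coefficient < 1.0:
            raise ValueError("economy.wage_coefficient must be in (0, 1)")
        if self.loan_term <= 0:
            raise ValueError("economy.loan_term must be a positive integer")
        if not 0.0 < self.cash_reserve_ratio <= 1.0:
            raise ValueError("economy.cash_reserve_ratio must be in (0, 1]")
        if not 0.0 <= self.tech_investment_fraction <= 1.0:
            raise ValueError("economy.tech_investment_fraction must be in [0, 1]")
        for name in (
            "n_firms",
            "n_households",
            "correction_factor",
            "credit_interest_rate",
            "deposit_interest_rate",
            "tech_efficiency_gain",
            "distance_decay",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"economy.{name} must be >= 0")


# --------------------------------------------------------------------------
# agents
# --------------------------------------------------------------------------
@dataclass
class Firm:
    firm_id: int
    patch_id: int
    capital: float  # F_c
    capital_prev: float  # F_c(t-1)
    labour: int = 0  # L
    biomass_reserve: float = 0.0  # B_r
    price: float = 1.0  # P
    productivity: float = 0.0  # p
    nominal_wage: float = 0.0  # W_n
    tech_efficiency: float = 1.0
    outstanding_debt: float = 0.0
    bankrupt: bool = False
    demand: float = 0.0  # demand directed at this firm this tick (goods)

    @property
    def active(self) -> bool:
        return not self.bankrupt


@dataclass
class Household:
    household_id: int
    row: int
    col: int
    capital: float  # H_c, held as a bank deposit
    employer: int | None = None  # firm_id
    demand: float = 0.0  # D
    target_firm: int | None = None
    energy: float = 10.0


@dataclass
class Speculator:
    spec_id: int
    capital: float
    outstanding_debt: float = 0.0
    active: bool = True
    pending_stake: float = 0.0  # escrowed bet awaiting settlement


@dataclass
class Loan:
    loan_id: int
    borrower_kind: str  # "firm" | "speculator"
    borrower_id: int
    principal: float
    balance: float
    rate: float
    ticks_remaining: int


@dataclass
class Bank:
    """Single commercial bank with a dual-stock balance sheet.

    ``withdrawable_capital`` is the share of household deposits held for
    withdrawal; ``bank_reserves`` is the remaining lending headroom.  Both are
    recomputed by :func:`bank_accounting` from deposits, the cash reserve
    ratio and accumulated equity.  Under full reserve (ratio 1) only the
    bank's own interest surplus can fund lending.
    """

    cash_reserve_ratio: float = 0.02
    withdrawable_capital: float = 0.0
    bank_reserves: float = 0.0
    interest_surplus: float = 0.0  # bank equity; may go negative after defaults
    bad_debt: float = 0.0  # cumulative written-off principal
    loans: list[Loan] = field(default_factory=list)
    cumulative_credit: float = 0.0
    _next_loan_id: int = 0

    def outstanding_total(self) -> float:
        return sum(loan.balance for loan in self.loans)


@dataclass
class MarketState:
    speculation_rate: float = 0.0  # P_k
    gdp: float = 0.0  # nominal goods value sold per tick
    gdp_prev: float = 0.0
    gdp_trend: float = 0.0  # exponentially smoothed GDP level
    gdp_growth: float = 0.0  # k_g, relative change of the GDP trend
    output: float = 0.0  # Y, goods per tick
    output_prev: float = 0.0
    aggregate_demand: float = 0.0  # AGD
    aggregate_demand_prev: float = 0.0
    mean_price: float = 1.0
    mean_price_prev: float = 1.0
    mean_price_trend: float = 1.0
    _mean_price_trend_prev: float = 1.0

    @property
    def price_change(self) -> float:
        """Relative change of the smoothed mean goods price."""
        if self._mean_price_trend_prev <= 0:
            return 0.0
        return (self.mean_price_trend - self._mean_price_trend_prev) / self._mean_price_trend_prev


# --------------------------------------------------------------------------
# behavioural functions
# --------------------------------------------------------------------------
def grid_distance(row_a: int, col_a: int, row_b: int, col_b: int) -> float:
    """Chebyshev distance between two grid cells (one move = one step)."""
    return float(max(abs(row_a - row_b), abs(col_a - col_b)))


def compute_demand(
    household: Household,
    firm: Firm,
    econ: EconomyParams,
    distance: float | None = None,
) -> float:
    """Goods demand of one household directed at one firm.

    ``D = H_c / (P * v)`` discounted exponentially with grid distance and
    capped so the implied spending never exceeds the household's capital.
    """
    if firm.price <= 0:
        raise ValueError("firm price must be positive")
    if econ.accelerator <= 0:
        raise ValueError("accelerator v must be positive")
    if distance is None:
        distance = 0.0
    base = household.capital / (firm.price * econ.accelerator)
    d = base * math.exp(-econ.distance_decay * distance)
    return max(0.0, min(d, household.capital / firm.price))


def extract_resources(firm: Firm, landscape, econ: EconomyParams) -> float:
    """Extract biomass from the firm's patch into its reserve.

    Target ``R_e = max(0, D * L * c * tech_efficiency - B_r)``; the realized
    amount is limited by the patch's remaining stock.  Patch stock and firm
    reserve change by exactly the same amount.
    """
    if firm.bankrupt:
        raise ValueError("bankrupt firms do not extract")
    if landscape.protected[firm.patch_id]:
        raise ValueError("extraction attempted on a protected patch")
    target = max(
        0.0,
        firm.demand * firm.labour * econ.conversion_factor * firm.tech_efficiency
        - firm.biomass_reserve,
    )
    taken = landscape.extract(firm.patch_id, target)
    if taken > 0:
        landscape.last_harvester[firm.patch_id] = firm.firm_id
    firm.biomass_reserve += taken
    return taken


def compute_investment(firm: Firm, market: MarketState, econ: EconomyParams) -> float:
    """Extraction investment ``K = AGD(t-1) * L * F_c * M_c``.

    Floored at zero when the firm's capital is negative, and capped at the
    firm's capital (a firm cannot spend money it does not have).
    """
    if firm.capital < 0:
        return 0.0
    k = (
        market.aggregate_demand_prev
        * firm.labour
        * firm.capital
        * econ.correction_factor
    )
    return max(0.0, min(k, firm.capital))


def set_price(firm: Firm, market: MarketState, econ: EconomyParams) -> float:
    """Price rule ``P = D * P_k / B_r`` with numerical guards.

    The speculation rate enters multiplicatively (speculative bidding drives
    the goods/asset price), floored at ``speculation_price_floor`` so the
    goods market functions when speculation is absent; the biomass reserve in
    the denominator is floored to keep the price finite.
    """
    pk = max(market.speculation_rate, econ.speculation_price_floor)
    br = max(firm.biomass_reserve, econ.reserve_floor)
    price = (firm.demand * pk) / br
    firm.price = max(price, econ.price_min)
    return firm.price


def sell_goods(firm: Firm, buyers: list[tuple[Household, float]], econ: EconomyParams):
    """Deliver goods against the demand directed at one firm.

    Supply is the goods content of the biomass reserve,
    ``B_r * c * tech_efficiency``.  When demand exceeds supply buyers are
    rationed proportionally.  Money moves buyer -> firm at the posted price;
    the biomass reserve falls by goods delivered / (c * tech_efficiency).
    Returns ``(goods_sold, revenue)``.
    """
    total_demand = 0.0
    for _, d in buyers:
        if d < 0:
            raise ValueError("negative demand")
        total_demand += d
    if total_demand <= 0:
        return 0.0, 0.0
    conv = econ.conversion_factor * firm.tech_efficiency
    supply = firm.biomass_reserve * conv
    goods = min(total_demand, supply)
    if goods <= 0:
        return 0.0, 0.0
    ration = goods / total_demand
    revenue = 0.0
    delivered = 0.0
    for household, d in buyers:
        g = d * ration
        pay = min(g * firm.price, household.capital)
        g = pay / firm.price if firm.price > 0 else 0.0
        household.capital -= pay
        household.energy += g * econ.energy_per_good
        revenue += pay
        delivered += g
    firm.capital += revenue
    firm.biomass_reserve = max(firm.biomass_reserve - delivered / conv, 0.0)
    return delivered, revenue


def compute_productivity(firm: Firm) -> float:
    """Productivity ``p = (F_c(t) - F_c(t-1)) / L``; zero when L = 0."""
    if firm.labour <= 0:
        firm.productivity = 0.0
    else:
        firm.productivity = (firm.capital - firm.capital_prev) / firm.labour
    return firm.productivity


def pay_wages(firm: Firm, workers: list[Household], econ: EconomyParams):
    """Pay the wage bill ``W_c * F_c`` split equally among workers.

    Per-worker nominal wage ``W_n = W_c * F_c / L``.  A firm with
    non-positive capital pays nothing (and the scheduler may release its
    workers).  Returns ``(nominal_wage, payroll)``.
    """
    n = len(workers)
    if n == 0 or firm.capital <= 0:
        firm.nominal_wage = 0.0
        return 0.0, 0.0
    payroll = econ.wage_coefficient * firm.capital
    wage = payroll / n
    firm.capital -= payroll
    for w in workers:
        w.capital += wage
    firm.nominal_wage = wage
    return wage, payroll


# --------------------------------------------------------------------------
# credit market
# --------------------------------------------------------------------------
def bank_lend(bank: Bank, borrower, amount: float, econ: EconomyParams) -> Loan | None:
    """Grant a loan if capacity and creditworthiness allow; else ``None``.

    Creditworthiness: post-loan debt-to-capital must stay below the
    configured cap.  A grant credits the borrower's capital (money creation),
    reduces the bank's lending headroom, and opens a loan at the credit
    interest rate over the configured term.
    """
    if amount <= 0:
        return None
    if getattr(borrower, "bankrupt", False) or not getattr(borrower, "active", True):
        return None
    if amount > bank.bank_reserves:
        return None
    capital_base = max(borrower.capital, econ.bankruptcy_floor)
    if (borrower.outstanding_debt + amount) / capital_base > econ.debt_to_capital_cap:
        return None
    loan = Loan(
        loan_id=bank._next_loan_id,
        borrower_kind="speculator" if isinstance(borrower, Speculator) else "firm",
        borrower_id=getattr(borrower, "firm_id", None)
        if not isinstance(borrower, Speculator)
        else borrower.spec_id,
        principal=amount,
        balance=amount,
        rate=econ.credit_interest_rate,
        ticks_remaining=econ.loan_term,
    )
    bank._next_loan_id += 1
    bank.loans.append(loan)
    bank.bank_reserves -= amount
    bank.cumulative_credit += amount
    borrower.capital += amount
    borrower.outstanding_debt += amount
    return loan


def write_off(bank: Bank, borrower, loan: Loan) -> float:
    """Default path: the unpaid balance becomes the bank's debt."""
    lost = loan.balance
    bank.bad_debt += lost
    bank.interest_surplus -= lost
    borrower.outstanding_debt = max(borrower.outstanding_debt - lost, 0.0)
    loan.balance = 0.0
    loan.ticks_remaining = 0
    return lost


def repay_credits(borrower, bank: Bank, loan: Loan, econ: EconomyParams) -> dict:
    """One amortization tick: equal-principal installment plus interest.

    Due = balance / ticks_remaining + balance * rate.  A borrower whose
    capital is below the bankruptcy floor defaults: the remaining balance is
    written off against bank equity.  Otherwise the borrower pays what it
    can (principal and interest scaled proportionally); principal repayment
    destroys money, interest accrues to the bank's surplus.
    """
    record = {"principal": 0.0, "interest": 0.0, "written_off": 0.0, "defaulted": False}
    if loan.balance <= 0:
        return record
    if borrower.capital < econ.bankruptcy_floor:
        record["written_off"] = write_off(bank, borrower, loan)
        record["defaulted"] = True
        return record
    ticks = max(loan.ticks_remaining, 1)
    principal_due = loan.balance / ticks
    interest_due = loan.balance * loan.rate
    due = principal_due + interest_due
    pay = min(due, borrower.capital)
    frac = pay / due if due > 0 else 0.0
    p_paid = principal_due * frac
    i_paid = interest_due * frac
    borrower.capital -= pay
    borrower.outstanding_debt = max(borrower.outstanding_debt - p_paid, 0.0)
    loan.balance = max(loan.balance - p_paid, 0.0)
    loan.ticks_remaining = max(loan.ticks_remaining - 1, 0)
    bank.interest_surplus += i_paid
    record["principal"] = p_paid
    record["interest"] = i_paid
    return record


def bank_accounting(bank: Bank, households: list[Household]) -> dict:
    """Partition deposits and pay deposit interest.

    ``withdrawable_capital = ratio * deposits`` is held for withdrawal; the
    remainder, plus accumulated (positive) equity, less balances already on
    loan, is the lending headroom ``bank_reserves``.  Under full reserve
    (ratio 1) only the bank's own surplus can fund lending.  Deposit interest
    is paid out of bank equity.
    """
    deposits = sum(h.capital for h in households)
    if deposits < 0:
        raise ValueError("negative deposits")
    bank.withdrawable_capital = bank.cash_reserve_ratio * deposits
    lendable_base = max(
        (1.0 - bank.cash_reserve_ratio) * deposits + bank.interest_surplus, 0.0
    )
    bank.bank_reserves = max(lendable_base - bank.outstanding_total(), 0.0)
    return {"deposits": deposits, "lendable": bank.bank_reserves}


def pay_deposit_interest(bank: Bank, households: list[Household], econ: EconomyParams) -> float:
    """Pay deposit interest, limited by the bank's positive equity.

    The bank cannot conjure deposit interest out of a loss position: when
    accumulated equity is below the total due, payments are prorated.
    """
    rate = econ.deposit_interest_rate
    if rate <= 0 or not households:
        return 0.0
    due = rate * sum(h.capital for h in households)
    payable = min(due, max(bank.interest_surplus, 0.0))
    if payable <= 0:
        return 0.0
    scale = payable / due
    for h in households:
        h.capital += rate * h.capital * scale
    bank.interest_surplus -= payable
    return payable


# --------------------------------------------------------------------------
# speculation
# --------------------------------------------------------------------------
def update_speculation(market: MarketState) -> float:
    """Speculation rate ``P_k = max(0, k_g) * Y`` (no negative betting volume)."""
    market.speculation_rate = max(0.0, market.gdp_growth) * market.output
    return market.speculation_rate


def speculator_step(
    spec: Speculator,
    market: MarketState,
    bank: Bank,
    econ: EconomyParams,
    borrowing_blocked: bool = False,
) -> dict:
    """Settle last tick's bet, then possibly place a new credit-funded one.

    The bet is a directional derivative on the mean goods price, cleared by
    the bank: a stake ``s`` placed last tick returns ``s * (1 + q)`` where
    ``q`` is the realized relative price change.  New bets are placed only in
    rising markets (both mean price and GDP up), funded by borrowing a fixed
    fraction of the speculator's capital.  A speculator whose capital is
    below the bankruptcy floor at that decision point declines to borrow,
    goes inactive and defaults on its outstanding loans.
    """
    record = {"settled": 0.0, "staked": 0.0, "went_bankrupt": False, "written_off": 0.0}
    if not spec.active:
        return record
    # settle
    if spec.pending_stake > 0:
        q = market.price_change
        payout = spec.pending_stake * (1.0 + q)
        bank.interest_surplus -= payout
        spec.capital += payout
        record["settled"] = payout - spec.pending_stake
        spec.pending_stake = 0.0
    rising = market.price_change > 0 and market.gdp_growth > 0
    if not rising or borrowing_blocked:
        return record
    if spec.capital < econ.bankruptcy_floor:
        # unwilling/unable to borrow further: bankruptcy and default
        for loan in bank.loans:
            if loan.borrower_kind == "speculator" and loan.borrower_id == spec.spec_id:
                record["written_off"] += write_off(bank, spec, loan)
        spec.active = False
        record["went_bankrupt"] = True
        return record
    stake = econ.speculator_borrow_fraction * spec.capital
    loan = bank_lend(bank, spec, stake, econ)
    if loan is not None:
        # escrow the stake with the bank until settlement
        spec.capital -= stake
        bank.interest_surplus += stake
        spec.pending_stake = stake
        record["staked"] = stake
    return record


# --------------------------------------------------------------------------
# firm strategy
# --------------------------------------------------------------------------
def invest_in_technology(
    firm: Firm, econ: EconomyParams, cap_fraction: float | None = None
) -> float:
    """Spend surplus capital on extraction-technology efficiency.

    The invested amount is a fraction of the capital held above the firm's
    working-capital needs — so technology investment is fuelled by credit and
    boom profits, not by funds the firm needs to operate.  The efficiency
    multiplier compounds: ``tech_efficiency *= 1 + gain * spend``.  A
    government cap (precautionary principle) can shrink the invested
    fraction.  Returns the spend (routed by the scheduler to the household
    sector as equipment/services income).
    """
    fraction = econ.tech_investment_fraction
    if cap_fraction is not None:
        fraction = min(fraction, cap_fraction)
    spend = fraction * max(firm.capital - econ.working_capital_target, 0.0)
    if spend <= 0:
        return 0.0
    firm.tech_efficiency = min(
        firm.tech_efficiency * (1.0 + econ.tech_efficiency_gain * spend),
        econ.max_tech_efficiency,
    )
    firm.capital -= spend
    return spend


def consider_expansion(
    firm: Firm,
    landscape,
    bank: Bank,
    econ: EconomyParams,
    next_firm_id: int,
) -> Firm | None:
    """Open a branch firm on the best unprotected patch, if affordable.

    A solvent firm attempts expansion once its capital reaches
    ``expansion_trigger_multiple * expansion_cost``; any shortfall against
    the cost is requested as credit.  The branch is sited on the unprotected
    patch with maximal resource stock (ties broken by lowest patch id) and
    endowed with the expansion cost.
    """
    if firm.bankrupt:
        return None
    cost = econ.expansion_cost
    if firm.capital < econ.expansion_trigger_multiple * cost:
        return None
    if firm.capital < cost:
        # trigger multiples below 1 allow partially credit-funded expansion
        if bank_lend(bank, firm, cost - firm.capital, econ) is None:
            return None
    stocks = landscape.stock.copy()
    stocks[landscape.protected] = -1.0
    best = int(stocks.argmax())  # argmax takes the lowest index on ties
    if stocks[best] <= 0:
        return None
    firm.capital -= cost
    child = Firm(
        firm_id=next_firm_id,
        patch_id=best,
        capital=cost,
        capital_prev=cost,
        tech_efficiency=firm.tech_efficiency,
        price=firm.price,
        biomass_reserve=0.0,
    )
    return child


def firm_borrow(firm: Firm, bank: Bank, market: MarketState, econ: EconomyParams) -> float:
    """Working-capital and growth borrowing rule.

    A firm borrows its shortfall against a working-capital target, plus — in
    a growing economy — an opportunistic tranche proportional to GDP growth
    (borrowing rises with profit expectations).  Returns credit granted.
    """
    request = max(0.0, econ.working_capital_target - firm.capital)
    if market.gdp_growth > 0:
        boom = min(market.gdp_growth, 1.0)
        request += econ.growth_borrow_fraction * boom * max(firm.capital, 0.0)
    # take what the bank can extend when capacity is scarce (partial grants)
    request = min(request, bank.bank_reserves)
    if request <= 0:
        return 0.0
    loan = bank_lend(bank, firm, request, econ)
    return loan.principal if loan is not None else 0.0


# --------------------------------------------------------------------------
# households
# --------------------------------------------------------------------------
def household_step(
    household: Household,
    firms: list[Firm],
    landscape,
    econ: EconomyParams,
) -> dict[int, float]:
    """Movement, demand formation and energy bookkeeping for one household.

    The household moves one grid step toward the firm with the lowest
    distance-discounted price (``P * exp(decay * distance)``), then spreads
    its demand over all solvent firms using the per-pair demand function,
    scaled down uniformly if the implied total spending would exceed its
    capital.  Energy is consumed at a fixed per-tick rate and replenished by
    goods bought.  Returns the per-firm demand allocation.
    """
    household.energy = max(household.energy - econ.energy_consumption, 0.0)
    active = [f for f in firms if not f.bankrupt]
    if not active:
        household.demand = 0.0
        household.target_firm = None
        return {}
    cols = landscape.env.grid_cols

    def dist_to(f: Firm) -> float:
        frow, fcol = divmod(f.patch_id, cols)
        return grid_distance(household.row, household.col, frow, fcol)

    best = min(
        active, key=lambda f: (f.price * math.exp(econ.distance_decay * dist_to(f)), f.firm_id)
    )
    frow, fcol = divmod(best.patch_id, cols)
    household.row += int(math.copysign(1, frow - household.row)) if frow != household.row else 0
    household.col += int(math.copysign(1, fcol - household.col)) if fcol != household.col else 0
    household.target_firm = best.firm_id

    allocation = {
        f.firm_id: compute_demand(household, f, econ, distance=dist_to(f)) for f in active
    }
    spend = sum(d * f.price for f, d in zip(active, allocation.values()))
    if spend > household.capital and spend > 0:
        scale = household.capital / spend
        allocation = {fid: d * scale for fid, d in allocation.items()}
    household.demand = sum(allocation.values())
    return allocation
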