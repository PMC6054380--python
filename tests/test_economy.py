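"""Economic-agent unit tests: behavioural functions, credit market, markets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecocredit.economy import (
    Bank,
    EconomyParams,
    Firm,
    Household,
    Loan,
    MarketState,
    Speculator,
    bank_accounting,
    bank_lend,
    compute_demand,
    compute_investment,
    compute_productivity,
    consider_expansion,
    extract_resources,
    household_step,
    invest_in_technology,
    pay_wages,
    repay_credits,
    sell_goods,
    set_price,
    speculator_step,
    update_speculation,
)
from ecocredit.environment import EnvironmentParams, Landscape


def make_firm(**kw):
    defaults = dict(firm_id=0, patch_id=0, capital=100.0, capital_prev=100.0)
    defaults.update(kw)
    return Firm(**defaults)


def make_household(capital=100.0, row=0, col=0):
    return Household(household_id=0, row=row, col=col, capital=capital)


class TestDemand:
    def test_zero_capital_zero_demand(self, econ):
        h = make_household(capital=0.0)
        f = make_firm(price=2.0)
        assert compute_demand(h, f, econ, distance=0.0) == 0.0

    def test_hand_value(self):
        econ = EconomyParams(accelerator=1.0, distance_decay=0.0)
        h = make_household(capital=100.0)
        f = make_firm(price=2.0)
        assert compute_demand(h, f, econ, distance=0.0) == pytest.approx(50.0)

    def test_doubling_price_halves_demand(self, econ):
        h = make_household(capital=100.0)
        d1 = compute_demand(h, make_firm(price=2.0), econ, distance=3.0)
        d2 = compute_demand(h, make_firm(price=4.0), econ, distance=3.0)
        assert d1 == pytest.approx(2 * d2)

    def test_spending_never_exceeds_capital(self):
        econ = EconomyParams(accelerator=0.5, distance_decay=0.0)  # aggressive demand
        h = make_household(capital=100.0)
        f = make_firm(price=0.5)
        d = compute_demand(h, f, econ, distance=0.0)
        assert d * f.price <= h.capital + 1e-12

    def test_invalid_price(self, econ):
        with pytest.raises(ValueError):
            compute_demand(make_household(), make_firm(price=0.0), econ, distance=0)


class TestExtraction:
    def _landscape(self, stock=100.0):
        env = EnvironmentParams(grid_rows=3, grid_cols=3, initial_stock_per_patch=stock)
        return Landscape(env)

    def test_sufficient_reserve_extracts_nothing(self, econ):
        land = self._landscape()
        f = make_firm(demand=1.0, labour=1, biomass_reserve=1e9)
        assert extract_resources(f, land, econ) == 0.0

    def test_hand_target(self):
        econ = EconomyParams(conversion_factor=0.5)
        land = self._landscape(stock=100.0)
        f = make_firm(demand=10.0, labour=2, biomass_reserve=4.0, tech_efficiency=1.0)
        taken = extract_resources(f, land, econ)
        assert taken == pytest.approx(6.0)  # 10*2*0.5 - 4
        assert f.biomass_reserve == pytest.approx(10.0)

    def test_bounded_by_patch_stock(self):
        econ = EconomyParams(conversion_factor=0.5)
        land = self._landscape(stock=3.0)
        f = make_firm(demand=10.0, labour=2, biomass_reserve=4.0)
        taken = extract_resources(f, land, econ)
        assert taken == pytest.approx(3.0)
        assert land.stock[0] == 0.0

    def test_protected_patch_rejected(self, econ):
        land = self._landscape()
        land.protected[0] = True
        with pytest.raises(ValueError):
            extract_resources(make_firm(demand=1, labour=1), land, econ)

    def test_patch_outflow_equals_reserve_inflow(self, econ, rng):
        land = self._landscape()
        f = make_firm(demand=50.0, labour=5, biomass_reserve=0.0)
        before_land = land.stock.sum()
        before_res = f.biomass_reserve
        taken = extract_resources(f, land, econ)
        assert before_land - land.stock.sum() == pytest.approx(taken, abs=1e-9)
        assert f.biomass_reserve - before_res == pytest.approx(taken, abs=1e-9)


class TestInvestment:
    def test_zero_aggregate_demand(self, econ):
        market = MarketState(aggregate_demand_prev=0.0)
        assert compute_investment(make_firm(labour=3), market, econ) == 0.0

    def test_hand_value(self):
        econ = EconomyParams(correction_factor=0.01)
        market = MarketState(aggregate_demand_prev=2.0)
        f = make_firm(capital=10.0, labour=3)
        assert compute_investment(f, market, econ) == pytest.approx(0.6)

    def test_zero_correction_factor(self):
        econ = EconomyParams(correction_factor=0.0)
        market = MarketState(aggregate_demand_prev=5.0)
        assert compute_investment(make_firm(labour=3), market, econ) == 0.0

    def test_negative_capital_floors_at_zero(self, econ):
        market = MarketState(aggregate_demand_prev=5.0)
        f = make_firm(capital=-10.0, labour=3)
        assert compute_investment(f, market, econ) == 0.0


class TestPrice:
    def test_hand_value(self):
        econ = EconomyParams(speculation_price_floor=1.0)
        market = MarketState(speculation_rate=2.0)
        f = make_firm(demand=30.0, biomass_reserve=20.0)
        assert set_price(f, market, econ) == pytest.approx(3.0)

    def test_linear_in_speculation(self):
        econ = EconomyParams(speculation_price_floor=1.0)
        f = make_firm(demand=30.0, biomass_reserve=20.0)
        p1 = set_price(f, MarketState(speculation_rate=2.0), econ)
        p2 = set_price(f, MarketState(speculation_rate=4.0), econ)
        assert p2 == pytest.approx(2 * p1)

    def test_zero_reserve_guarded(self):
        econ = EconomyParams(speculation_price_floor=1.0)
        f = make_firm(demand=30.0, biomass_reserve=0.0)
        p = set_price(f, MarketState(speculation_rate=1.0), econ)
        assert math.isfinite(p) and p > 0


class TestSellGoods:
    def test_no_demand_no_money_moves(self, econ):
        f = make_firm(biomass_reserve=10.0, price=2.0)
        goods, revenue = sell_goods(f, [], econ)
        assert goods == 0.0 and revenue == 0.0

    def test_proportional_rationing(self):
        econ = EconomyParams(conversion_factor=1.0)
        f = make_firm(biomass_reserve=10.0, price=1.0, tech_efficiency=1.0)
        buyers = [(make_household(1000.0), 10.0), (make_household(1000.0), 10.0)]
        goods, _ = sell_goods(f, buyers, econ)
        assert goods == pytest.approx(10.0)
        spent = [1000.0 - b.capital for b, _ in buyers]
        assert spent[0] == pytest.approx(spent[1])
        assert spent[0] == pytest.approx(5.0)  # 5 goods each at price 1

    def test_money_conservation(self, rng):
        econ = EconomyParams(conversion_factor=0.7)
        f = make_firm(biomass_reserve=30.0, price=1.7, tech_efficiency=1.3)
        buyers = [
            (make_household(float(c)), float(d))
            for c, d in zip(rng.uniform(5, 200, 6), rng.uniform(0, 40, 6))
        ]
        total_before = f.capital + sum(b.capital for b, _ in buyers)
        sell_goods(f, buyers, econ)
        total_after = f.capital + sum(b.capital for b, _ in buyers)
        assert total_after == pytest.approx(total_before, abs=1e-9)

    def test_reserve_decreases_by_goods_content(self):
        econ = EconomyParams(conversion_factor=2.0)
        f = make_firm(biomass_reserve=10.0, price=1.0, tech_efficiency=1.0)
        goods, _ = sell_goods(f, [(make_household(1e6), 8.0)], econ)
        assert f.biomass_reserve == pytest.approx(10.0 - goods / 2.0)

    def test_negative_demand_rejected(self, econ):
        with pytest.raises(ValueError):
            sell_goods(make_firm(biomass_reserve=5), [(make_household(), -1.0)], econ)


class TestProductivityAndWages:
    def test_productivity_unchanged_capital(self):
        f = make_firm(capital=100.0, capital_prev=100.0, labour=4)
        assert compute_productivity(f) == 0.0

    def test_productivity_hand_value(self):
        f = make_firm(capital=110.0, capital_prev=100.0, labour=5)
        assert compute_productivity(f) == pytest.approx(2.0)

    def test_productivity_zero_labour_convention(self):
        f = make_firm(capital=110.0, capital_prev=100.0, labour=0)
        assert compute_productivity(f) == 0.0

    def test_wage_hand_value(self):
        econ = EconomyParams(wage_coefficient=0.4)
        f = make_firm(capital=100.0)
        workers = [make_household(0.0) for _ in range(8)]
        wage, payroll = pay_wages(f, workers, econ)
        assert wage == pytest.approx(5.0)
        assert payroll == pytest.approx(40.0)
        assert f.capital == pytest.approx(60.0)
        assert sum(w.capital for w in workers) == pytest.approx(40.0)

    def test_broke_firm_pays_nothing(self, econ):
        f = make_firm(capital=0.0)
        wage, payroll = pay_wages(f, [make_household()], econ)
        assert wage == 0.0 and payroll == 0.0


class TestBank:
    def test_partition_fractional(self):
        bank = Bank(cash_reserve_ratio=0.02)
        households = [make_household(500.0), make_household(500.0)]
        bank_accounting(bank, households)
        assert bank.withdrawable_capital == pytest.approx(20.0)
        assert bank.bank_reserves == pytest.approx(980.0)

    def test_partition_full_reserve(self):
        bank = Bank(cash_reserve_ratio=1.0)
        bank_accounting(bank, [make_household(1000.0)])
        assert bank.withdrawable_capital == pytest.approx(1000.0)
        assert bank.bank_reserves == 0.0

    def test_full_reserve_surplus_funds_lending(self):
        bank = Bank(cash_reserve_ratio=1.0, interest_surplus=50.0)
        bank_accounting(bank, [make_household(1000.0)])
        assert bank.bank_reserves == pytest.approx(50.0)

    def test_lend_refused_beyond_reserves(self, econ):
        bank = Bank(bank_reserves=5.0)
        assert bank_lend(bank, make_firm(), 10.0, econ) is None

    def test_lend_double_entry(self, econ):
        bank = Bank(bank_reserves=100.0)
        f = make_firm(capital=50.0)
        loan = bank_lend(bank, f, 10.0, econ)
        assert loan is not None
        assert f.capital == pytest.approx(60.0)
        assert f.outstanding_debt == pytest.approx(10.0)
        assert bank.bank_reserves == pytest.approx(90.0)
        assert bank.outstanding_total() == pytest.approx(10.0)

    def test_lend_refused_for_uncreditworthy(self):
        econ = EconomyParams(debt_to_capital_cap=2.0)
        bank = Bank(bank_reserves=1e6)
        f = make_firm(capital=10.0, outstanding_debt=15.0)
        assert bank_lend(bank, f, 10.0, econ) is None

    def test_repay_hand_value(self, econ):
        bank = Bank()
        f = make_firm(capital=1e6)
        loan = Loan(0, "firm", 0, principal=100.0, balance=100.0, rate=0.05, ticks_remaining=10)
        rec = repay_credits(f, bank, loan, econ)
        assert rec["principal"] == pytest.approx(10.0)
        assert rec["interest"] == pytest.approx(5.0)
        assert loan.balance == pytest.approx(90.0)
        assert f.capital == pytest.approx(1e6 - 15.0)
        assert bank.interest_surplus == pytest.approx(5.0)

    def test_repay_settled_loan_is_noop(self, econ):
        bank = Bank()
        loan = Loan(0, "firm", 0, 100.0, 0.0, 0.05, 5)
        rec = repay_credits(make_firm(), bank, loan, econ)
        assert rec == {
            "principal": 0.0, "interest": 0.0, "written_off": 0.0, "defaulted": False,
        }

    def test_insolvent_borrower_defaults_to_bad_debt(self, econ):
        bank = Bank()
        spec = Speculator(spec_id=0, capital=0.5, outstanding_debt=40.0)
        loan = Loan(0, "speculator", 0, 40.0, 40.0, 0.05, 8)
        rec = repay_credits(spec, bank, loan, econ)
        assert rec["defaulted"]
        assert bank.bad_debt == pytest.approx(40.0)
        assert bank.interest_surplus == pytest.approx(-40.0)  # the bank's debt
        assert loan.balance == 0.0

    def test_spread_validation(self):
        with pytest.raises(ValueError):
            EconomyParams(credit_interest_rate=0.01, deposit_interest_rate=0.02).validate()


class TestSpeculation:
    def test_update_rule(self):
        market = MarketState(gdp_growth=0.02, output=500.0)
        assert update_speculation(market) == pytest.approx(10.0)

    def test_zero_growth_zero_rate(self):
        assert update_speculation(MarketState(gdp_growth=0.0, output=500.0)) == 0.0

    def test_negative_growth_floored(self):
        assert update_speculation(MarketState(gdp_growth=-0.5, output=500.0)) == 0.0

    def _rising_market(self):
        m = MarketState(gdp_growth=0.1, output=100.0)
        m.mean_price_trend = 1.1
        m._mean_price_trend_prev = 1.0
        return m

    def test_no_bet_in_falling_market(self, econ):
        m = MarketState(gdp_growth=-0.1)
        spec = Speculator(0, capital=100.0)
        bank = Bank(bank_reserves=1e6)
        rec = speculator_step(spec, m, bank, econ)
        assert rec["staked"] == 0.0 and spec.pending_stake == 0.0

    def test_bet_cycle_returns_stake_times_price_change(self):
        econ = EconomyParams(speculator_borrow_fraction=0.5)
        bank = Bank(bank_reserves=1e6)
        spec = Speculator(0, capital=100.0)
        m = self._rising_market()
        rec = speculator_step(spec, m, bank, econ)
        stake = rec["staked"]
        assert stake == pytest.approx(50.0)
        total_before_settle = spec.capital + spec.pending_stake
        # settle next tick at a realized +10% price change
        m2 = self._rising_market()
        rec2 = speculator_step(spec, m2, bank, econ)
        q = m2.price_change
        assert rec2["settled"] == pytest.approx(stake * q)

    def test_bankruptcy_when_unable_to_borrow(self):
        econ = EconomyParams(bankruptcy_floor=1.0)
        bank = Bank(bank_reserves=1e6)
        spec = Speculator(0, capital=0.2, outstanding_debt=30.0)
        loan = Loan(0, "speculator", 0, 30.0, 30.0, 0.05, 5)
        bank.loans.append(loan)
        rec = speculator_step(spec, self._rising_market(), bank, econ)
        assert rec["went_bankrupt"]
        assert not spec.active
        assert bank.bad_debt == pytest.approx(30.0)

    def test_blocked_borrowing_places_no_bet(self, econ):
        bank = Bank(bank_reserves=1e6)
        spec = Speculator(0, capital=100.0)
        rec = speculator_step(spec, self._rising_market(), bank, econ, borrowing_blocked=True)
        assert rec["staked"] == 0.0


class TestExpansion:
    def _landscape(self):
        env = EnvironmentParams(grid_rows=3, grid_cols=3, initial_stock_per_patch=50.0)
        return Landscape(env)

    def test_poor_firm_no_branch(self):
        econ = EconomyParams(expansion_cost=400.0, expansion_trigger_multiple=2.0)
        bank = Bank(bank_reserves=0.0)
        f = make_firm(capital=100.0)
        assert consider_expansion(f, self._landscape(), bank, econ, 1) is None

    def test_tie_broken_by_lowest_patch_id(self):
        econ = EconomyParams(expansion_cost=100.0, expansion_trigger_multiple=2.0)
        land = self._landscape()
        land.stock[:] = 10.0
        land.stock[[4, 7]] = 90.0  # two equally rich patches
        child = consider_expansion(make_firm(capital=500.0), land, Bank(), econ, 1)
        assert child is not None and child.patch_id == 4

    def test_expansion_ledger_consistent(self):
        econ = EconomyParams(expansion_cost=100.0, expansion_trigger_multiple=2.0)
        f = make_firm(capital=500.0)
        child = consider_expansion(f, self._landscape(), Bank(), econ, 7)
        assert child is not None
        assert f.capital == pytest.approx(400.0)
        assert child.capital == pytest.approx(100.0)
        assert child.firm_id == 7

    def test_protected_rich_patch_skipped(self):
        econ = EconomyParams(expansion_cost=100.0, expansion_trigger_multiple=2.0)
        land = self._landscape()
        land.stock[:] = 10.0
        land.stock[2] = 90.0
        land.protected[2] = True
        child = consider_expansion(make_firm(capital=500.0), land, Bank(), econ, 1)
        assert child is not None and child.patch_id != 2


class TestTechnology:
    def test_zero_fraction_no_change(self):
        econ = EconomyParams(tech_investment_fraction=0.0)
        f = make_firm(capital=1000.0)
        assert invest_in_technology(f, econ) == 0.0
        assert f.tech_efficiency == 1.0

    def test_update_rule_hand_value(self):
        econ = EconomyParams(
            tech_investment_fraction=0.1,
            tech_efficiency_gain=0.001,
            working_capital_target=0.0,
        )
        f = make_firm(capital=1000.0, tech_efficiency=1.0)
        spend = invest_in_technology(f, econ)
        assert spend == pytest.approx(100.0)
        assert f.tech_efficiency == pytest.approx(1.1)
        assert f.capital == pytest.approx(900.0)

    def test_non_decreasing_over_time(self):
        econ = EconomyParams(working_capital_target=0.0)
        f = make_firm(capital=500.0)
        effs = []
        for _ in range(5):
            f.capital = 500.0
            invest_in_technology(f, econ)
            effs.append(f.tech_efficiency)
        assert all(b >= a for a, b in zip(effs, effs[1:]))

    def test_government_cap_limits_fraction(self):
        econ = EconomyParams(
            tech_investment_fraction=0.1, working_capital_target=0.0
        )
        f = make_firm(capital=1000.0)
        spend = invest_in_technology(f, econ, cap_fraction=0.0)
        assert spend == 0.0 and f.tech_efficiency == 1.0


class TestHouseholdStep:
    def _landscape(self):
        return Landscape(EnvironmentParams(grid_rows=10, grid_cols=10))

    def test_no_solvent_firms(self, econ):
        h = make_household()
        alloc = household_step(h, [make_firm(bankrupt=True)], self._landscape(), econ)
        assert alloc == {} and h.target_firm is None

    def test_moves_toward_nearer_of_equal_priced_firms(self, econ):
        land = self._landscape()
        near = make_firm(firm_id=1, patch_id=land.patch_id(2, 2), price=5.0)
        far = make_firm(firm_id=2, patch_id=land.patch_id(9, 9), price=5.0)
        h = make_household(row=0, col=0)
        household_step(h, [near, far], land, econ)
        assert h.target_firm == 1
        assert (h.row, h.col) == (1, 1)

    def test_allocation_spending_within_capital(self, econ, rng):
        land = self._landscape()
        firms = [
            make_firm(firm_id=i, patch_id=int(rng.integers(100)), price=float(p))
            for i, p in enumerate(rng.uniform(0.5, 5.0, 4))
        ]
        h = make_household(capital=50.0, row=5, col=5)
        alloc = household_step(h, firms, land, econ)
        spend = sum(alloc[f.firm_id] * f.price for f in firms)
        assert spend <= h.capital + 1e-9


class TestDepositInterest:
    def test_interest_credited_from_surplus(self):
        from ecocredit.economy import pay_deposit_interest

        econ = EconomyParams(deposit_interest_rate=0.01)
        bank = Bank(interest_surplus=1000.0)
        h = make_household(capital=200.0)
        paid = pay_deposit_interest(bank, [h], econ)
        assert paid == pytest.approx(2.0)
        assert h.capital == pytest.approx(202.0)
        assert bank.interest_surplus == pytest.approx(998.0)

    def test_no_payment_from_negative_equity(self):
        from ecocredit.economy import pay_deposit_interest

        econ = EconomyParams(deposit_interest_rate=0.01)
        bank = Bank(interest_surplus=-5.0)
        h = make_household(capital=200.0)
        assert pay_deposit_interest(bank, [h], econ) == 0.0
        assert h.capital == 200.0


@given(
    hc=st.floats(0.0, 1e4),
    price=st.floats(0.01, 1e3),
    v=st.floats(0.1, 10.0),
    dist=st.floats(0.0, 50.0),
)
@settings(max_examples=200, deadline=None)
def test_demand_matches_closed_form(hc, price, v, dist):
    """Function-form check on randomized inputs against an independent formula."""
    econ = EconomyParams(accelerator=v, distance_decay=0.05)
    d = compute_demand(make_household(capital=hc), make_firm(price=price), econ, dist)
    expected = min(hc / (price * v) * math.exp(-0.05 * dist), hc / price)
    assert d == pytest.approx(expected, abs=1e-9, rel=1e-9)
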