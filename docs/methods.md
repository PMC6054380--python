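# Model and methods

`ecocredit` simulates a closed social-ecological system: a debt-based
monetary economy (firms, households, speculators, one commercial bank, a
government) coupled to a renewable biological resource landscape.  The
economic side follows the monetary-circuit view of a credit economy — bank
lending creates deposits, principal repayment destroys them, defaulted
balances become the bank's own debt — and the ecological side is a grid of
land parcels with logistic biomass regrowth.  The question the simulator is
built around is how the banking regime (how freely credit is created) and
threshold-triggered conservation policy shape the fate of the resource base.

## Entities

* **Patch** — one land parcel with a biomass stock `R_s` regrowing
  logistically toward a carrying capacity `K`; depletion to exactly zero is
  absorbing (only paid restoration revives a stripped patch).  Biocapacity
  `B = R_s · F_y · F_eq` uses footprint-accounting yield and equivalence
  factors (forest-land placeholder values 1.26 / 1.28); it is reported but
  does not cap extraction.
* **Firm** — holds monetary capital `F_c`, labour `L`, a biomass reserve
  `B_r`, a posted price `P`, a technology-efficiency multiplier, and debt.
* **Household** — holds monetary capital `H_c` as a bank deposit, works for
  one firm, consumes goods, moves on the grid.
* **Bank** — a single commercial bank with the two-stock balance sheet:
  withdrawable capital (the reserve-ratio share of deposits) and bank
  reserves (lending headroom).  Equity (`interest_surplus`) accumulates the
  interest spread and absorbs loan write-offs.
* **Speculator** — borrows to place directional bets on the goods price;
  never produces or consumes.
* **Government** — watches the total resource stock and activates a
  permanent conservation-policy package when it first drops below the
  *critical-biomass-stock* fraction of the initial stock.

## Core behavioural functions

    biocapacity          B   = R_s · F_y · F_eq
    resource extraction  R_e = max(0, D · L · c · e − B_r)   (e = tech efficiency)
    demand               D   = H_c / (P · v) · exp(−λ · dist), spending ≤ H_c
    investment           K   = AGD(t−1) · L · F_c · M_c      (0 ≤ K ≤ F_c)
    price target         P*  = D · max(P_k, P_k,floor) / max(B_r, ε)
    productivity         p   = (F_c(t) − F_c(t−1)) / L
    nominal wage         W_n = W_c · F_c / L
    speculation rate     P_k = max(k_g, 0) · Y

`D` is demand in goods, `v` the accelerator, `λ` a distance-decay constant,
`c` the biomass→goods conversion factor, `AGD` aggregate household demand,
`M_c` the extraction-demand correction factor, `k_g` the GDP growth rate and
`Y` real output (goods sold per tick).

Two behavioural layers sit on top of the raw functions, both needed for a
well-posed market (the price and demand rules alone form an undamped
cobweb whose log-price oscillation diverges):

* **Price stickiness.** Firms move their posted price geometrically toward
  the target: `P ← P · (P*/P)^α` with adjustment speed `α = 0.2`.  `α = 1`
  recovers the raw rule.
* **Trend-based growth signals.** `k_g` and the price change that gates
  speculative betting are computed on exponentially smoothed (weight 0.3)
  GDP and mean-price levels, because growth-sensitive behaviour should track
  the trend, not the alternating tick-to-tick micro-cycle.

## The tick (processes i–xi)

Each tick runs, in fixed order: (i) patch growth and funded restoration;
(ii) firm extraction (concession window of radius 1 around the firm's patch,
richest patch first; a firm relocates within radius 8 when its window cannot
meet the target) and payment of the extraction investment `K`; (iii)
household movement toward the cheapest distance-discounted firm and demand
allocation across all solvent firms; (iv) pricing, sales with proportional
rationing, and market-aggregate updates; (v) hiring/releasing, wages,
productivity, technology investment; (vi) bank accounting — deposit
partition by the cash reserve ratio, deposit interest (payable only out of
positive bank equity), and a dividend that recycles equity above the bank's
endowment back to households; (vii) firm borrowing (working-capital shortfall
plus a pro-cyclical tranche `0.5 · min(k_g, 1) · F_c`, subject to a
debt-to-capital cap of 8 and available headroom); (viii) branch expansion
onto the richest unprotected patch once capital reaches twice the expansion
cost; (ix) speculator settlement and new credit-funded bets in rising
markets, with bankruptcy and default for speculators below the bankruptcy
floor; (x) equal-principal amortization with interest on the outstanding
balance, partial payment when short, default and write-off below the floor;
(xi) the government trigger and policy package.  An indicator row and a
double-entry ledger row are recorded, then collapse detection runs: the run
halts when the total stock falls strictly below 1% of its initial value.

Agent order within a process is re-randomized every tick from the run seed.
Households do not interact within their process, so their update is
vectorized; a test asserts exact agreement with sequential per-household
steps.

## Money accounting

The counted money aggregate is firm + household + speculator capital plus
bank equity.  Household capital *is* the deposit stock; the bank's
withdrawable capital and reserves are the ratio partition of those deposits
plus lending headroom, recomputed each tick rather than independently
counted (counting both would double-count deposits).  Under this convention
the stock-flow identity

    ΔM(t) = loans granted − principal repaid − principal written off

holds to floating-point exactness every tick, and every non-credit operation
is a pure transfer.  Three closure choices make the circuit leak-free, since
the source model does not say who receives firms' real expenditures: the
extraction investment, technology spending and restoration payments are paid
to the household sector (equipment/services income); derivative bets are
cleared against bank equity (the bank as market maker); and the bank pays
out 20% of its above-endowment equity per tick as dividends.  Without the
recycling flows the bank accumulates the entire money stock and every
scenario ends in demand collapse rather than resource dynamics.

## Conservation governance

When the total stock first drops strictly below the critical fraction the
package activates permanently: (1) the technology-investment fraction is
capped (default cap 0: a freeze — the precautionary principle); (2) the
speculation rate is capped (default 0) and speculator borrowing is blocked;
(3) the protected-patch fraction is raised once by 3 percentage points,
patches drawn uniformly at random (no siting rule is assumed; the protected
floor this creates is proportional to the stock remaining at trigger time,
which is exactly why late intervention protects less); (4) every depleted,
previously harvested patch is flagged for restoration, paid per patch-tick
by its last harvester within a small budget share (0.5% of capital).

## Scenarios and experiment design

Four presets pair the cash reserve ratio with the conservation threshold:
`fractional_no_gov` (0.02, 0), `fractional_gov25` (0.02, 0.25),
`fractional_gov50` (0.02, 0.50) and `full_reserve` (1.0, 0; under a 100%
reserve requirement only the bank's own interest surplus is lendable, so a
small but non-zero credit trickle remains).  Ensembles run a scenario over
consecutive seeds (`base_seed .. base_seed+n−1`, shared across scenarios for
paired comparison) and summarize each indicator per tick as mean ± standard
error (sample SD / √n) over the runs still alive at that tick, with survivor
counts.  The OFAT sweep varies one dotted config field at a time.  Runs are
labelled `collapse` (halted on resource collapse), `stable` (final stock
≥ 25% of initial and non-negative last-quartile trend) or `decline`.

## Spatial and problem scale

The reference world is a 100 × 100 grid with 30 firms, 300 households and 20
speculators.  Tests and the acceptance script use a half-linear-scale world
(50 × 50, 8 firms, 80 households, 10 speculators) that preserves per-patch
extraction pressure and reproduces the same regime structure at desk speed
(~0.3 s per run; a full-scale run takes ~3 s); the tiny 10 × 10 `toy_world`
exists for accounting audits and fixtures.  Test ensembles use 20
replicates; the reference design is 100, exposed through configuration.

## Calibration

No empirical parameter table is built in; every coefficient is a documented
configurable default.  The defaults were fixed once, by calibrating the
coupled system until it reproduces the qualitative regime structure the
model is meant to exhibit, and have not been tuned per scenario:

* an unregulated fractional-reserve economy goes through a credit boom,
  a speculative episode that rises and collapses (both the speculation rate
  and the debt growth rate show a rise-then-fall), and eventual resource
  collapse around ticks 180–215 (16 of 20 seeded replicates; the rest end
  just above the collapse line);
* conservation triggered at 50% of initial stock prevents collapse in all
  replicates; triggered at 25% it fails in a minority of replicates (the
  tipping point sits between the two thresholds — late intervention freezes
  technology at a higher level, protects a floor proportional to a smaller
  remaining stock, and arrives after more credit has accumulated);
* the full-reserve economy creates ~3 orders of magnitude less credit and
  never collapses, stabilizing at a much higher stock.

Load-bearing calibrated values: conversion factor `c = 0.3` (≈ `1/√L`,
which balances the reserve inflow `D·L·c` against the sales outflow
`D/(c·e)` at `e ≈ 1`), accelerator `v = 3.5`, speculation price floor 25
(this sets the baseline price scale and hence the demand-driven extraction
flux), technology gain `1e-4` per money unit invested, regrowth rate
`r = 0.12`, working-capital target 450, credit/deposit interest 5% / 0.5%
per tick over a 20-tick term.  One tick is read as one year (productivity
compares capital "from one year to the next").

## What the generator does and does not emulate

The synthetic world reproduces the *mechanisms* — endogenous credit money,
Minsky-style speculative euphoria and bust, demand-driven spatial resource
depletion, threshold governance — not any empirical economy: prices, GDP
and stocks are in model units; all firms sell one good; households never
borrow; there is one bank and no policy interest rate.  Passing tests
therefore show internal consistency and the qualitative regime logic, not
forecasts for real economies.

## Numerical choices and degenerate inputs

Division guards: the biomass reserve in the price rule is floored at 1e−6,
prices at 1e−3; productivity and wages return 0 for `L = 0`; the investment
`K` is clipped to `[0, F_c]`; technology efficiency has a numerical ceiling
of 1e6, far above the operating range (collapse occurs near e ≈ 2–10).
Growth rates with a zero base are defined as 0.  Expansion ties break toward
the lowest patch id; agentless or zero-stock worlds step cleanly (an
all-zero world only advances its tick).  All randomness flows through one
`numpy` generator per run, so identical (config, seed) pairs give
byte-identical CSV output.

## Known limitations

The cobweb damping and trend smoothing are behavioural assumptions the raw
function set does not specify; different damping constants shift the regime
boundaries.  The collapse/no-collapse outcome near the 25% threshold is
genuinely stochastic (a tipping point), so small ensembles can miss it.
Labour is a fixed head-count per firm up to a target; there is no wage
bargaining.  The protected-area siting is uniform random, which understates
what a targeted conservation plan could protect.  Restoration inventories
are deliberately small (fast re-activation at 5% of capacity) so that
restored land re-enters the extractive economy rather than accumulating as
a hidden sanctuary.
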