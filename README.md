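# pescheme

Design and optimization of budget-constrained payment schemes for nature
recovery on farmland.

A government wants to spend a fixed public budget incentivizing landowners
to convert farmland into new natural habitat — woodland or species-rich
semi-natural grassland, with or without public access. Each parcel × option
project changes a bundle of ecosystem services (carbon sequestration,
recreation, water quality, flood mitigation, pollination, …) whose monetized
value can be predicted, plus unmonetized biodiversity measured as species
prevalence across eight taxonomic groups. The policy question is not *which
projects are best* but *how to design the payment schedule*: landowners
volunteer only when a posted payment beats their private reservation cost,
and they pick the option that gives them the most surplus. `pescheme` is an
analysis toolkit for that problem, aimed at environmental economists and
conservation-policy modellers.

## The model

For parcel *i* and habitat-creation option *j*:

* **Reservation cost** `c_ij = (F + E + A)(1 + m)` — the NPV of foregone
  agricultural income *F*, habitat establishment/maintenance *E* and
  access-provision *A* costs, marked up by a transaction-cost fraction
  *m* = 15%. All values are NPVs at a 3.5% discount rate over 100 years.
* **Payment rules.** Activity payments pay `p_j · area_i` (£/ha); outcome
  payments pay `p · q_ij` per unit of eight environmental outcomes
  (tCO₂e, nutrient and peak-flow reductions, pollinator richness, new
  habitat areas); ecosystem-service-value payments pay `p · v_ij⁺` per £
  of value in seven priceable channels. Extended schedules add prices per
  additional (species, 2 km cell) presence for each of eight species groups.
* **Uptake.** A landowner enrols in `argmax_j (payment_ij − c_ij)` when the
  maximal surplus exceeds a participation margin ε, else opts out. Under
  cost-based flat rates (per-option median cost/ha) demand exceeds the
  budget and uptake is rationed first-come-first-served over random arrival
  orders (Monte-Carlo mean of 1000 runs).
* **Optimal pricing** is a unit-demand envy-free pricing problem: choose
  non-negative prices maximizing the aggregate value of self-selected
  enrolments subject to `Σ payments ≤ B` and optional biodiversity floors
  `Σ b_ijg ≥ τ · baseline_g` (τ = 15%). Solved exactly as a mixed-integer
  program (binary enrolments, continuous prices, big-M incentive
  constraints) with HiGHS, cross-checked against a breakpoint-enumeration
  oracle on small instances.
* **Upper bound.** Paying every landowner exactly `c_ij` and hand-picking
  projects is a multiple-choice knapsack — the in-theory best any payment
  scheme could do.
* **Value for money (VfM)** = aggregate ecosystem-service value delivered /
  public money spent.

The real national parcel dataset behind such analyses is not shareable, so
the package ships a seeded synthetic-landscape generator
(`pescheme.landscape`) reproducing its load-bearing statistics: cost/ha
medians near the published per-option anchors, an order-of-magnitude spread
in mean value/ha across options, per-option cost–value correlations in
[−0.373, 0.301], spatially homogeneous carbon versus hotspot-concentrated
recreation and flood value, and species-group gains only weakly coupled to
monetized value.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
landscapes and write tables to `results/`. For example:

```bash
python analysis/03_optimal_pricing.py --seed 0
```

prints (200 parcels, budget pro-rated from the £1bn full-scale commitment):

```
value-for-money ladder (budget 3,353,004, 200 parcels):
  in-theory upper bound:    3.634
  cost_based_fcfs           0.576  (16% of upper bound)
  activity                  2.394  (66% of upper bound)
  outcome                   2.925  (80% of upper bound)
  es_value                  3.532  (97% of upper bound)
```

i.e. the status-quo cost-based scheme destroys value (58p of services per
£1 spent), optimally chosen per-hectare rates more than triple that, and
pricing outcomes or service value directly closes most of the remaining gap
to the knapsack bound. Adding 15% biodiversity-prevalence targets
(`analysis/04_biodiversity_targets.py`) shows the companion pattern:

```
activity : unconstrained 1.845 | +targets 0.508 | +biodiversity prices 1.229
outcome  : unconstrained 2.055 | +targets 0.557 | +biodiversity prices 1.226
es_value : unconstrained 2.083 | +targets infeasible_pricing | +biodiversity prices 1.225
```

The mechanism that is best at delivering monetized value cannot reach the
biodiversity targets at any prices — although a direct selection of
projects could — and pricing biodiversity itself restores feasibility at
modest cost. `analysis/05_summary_tables.py` assembles the full
mechanism × scenario comparison table.

A `pescheme` CLI wraps the same library:
`pescheme generate | simulate | optimize | report | run`.

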