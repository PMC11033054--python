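# Methods

## Decision model

The analysis treats scheme design as a bilevel problem. The lower level is
landowner behaviour: parcel *i* facing posted prices enrols in the option
`argmax_j s_ij`, `s_ij = payment_ij − c_ij`, whenever `max_j s_ij > ε`, and
opts out otherwise. The upper level chooses the price schedule to maximize
the aggregate monetized ecosystem-service value of the enrolled projects
subject to the budget and, optionally, biodiversity floors.

Key assumptions, all load-bearing:

* **Additive, parcel-independent values.** Each project's service values
  are fixed per (parcel, option) and sum across funded projects. Real
  inter-parcel interactions (e.g. recreation-site substitution) are
  averaged into the per-project numbers before the optimization sees them;
  the combinatorial problems would otherwise be intractable.
* **Unit demand.** A parcel hosts at most one project; all-or-nothing
  funding (no partial enrolment of the marginal applicant).
* **Self-selection without rationing under optimized prices.** A posted
  price is a public offer: every willing parcel enrols and must be paid.
  Prices alone must keep spend within budget. The cost-based scheme is the
  exception — its prices are fixed by the median-cost rule, demand
  overshoots, and uptake is rationed first-come-first-served.
* **Truthful reservation costs**, uniform 15% transaction-cost mark-up, no
  strategic timing or learning.

## Monetary conventions

All money is GBP NPV, 2020 base year, end-of-year cash flows discounted at
3.5%/yr over a 100-year horizon. `equivalent_annuity` inverts the annuity
factor `a(r,T) = (1 − (1+r)^(−T))/r`, computed via `log1p`/`expm1` so the
`r → 0` limit (the arithmetic mean) is exact. The reservation-cost mark-up
multiplies the *sum* of foregone income, establishment/maintenance and
access-provision costs; the alternative (mark-up on a subset) changes
reservation costs by ≤ ~1% at the default cost split and no qualitative
result.

## Payment mechanisms and their parameters

| parameter | default | meaning |
|---|---|---|
| discount rate | 0.035 /yr | NPV conversions |
| horizon | 100 yr | appraisal window |
| mark-up | 0.15 | private transaction costs on participation |
| budget | £1e9 full scale; pro-rated by n/59,648 otherwise | public commitment |
| τ (biodiversity target) | 0.15 | required fractional prevalence gain, all 8 groups |
| ε (participation margin) | 1e-6 × median reservation cost | "payment must exceed cost" without float fragility |
| price caps | 1.5 × max per-unit cost breakpoint | bounds the price search box (below) |

Payments dot prices with non-negative bases only (positive parts of
channel values and prevalence deltas): the scheme never claws back negative
outcomes. Value-for-money with zero spend is reported as undefined, never 0.

## The pricing MIP

Variables: prices `p ∈ [0, cap]^K` (continuous), enrolments
`z_ij ∈ {0,1}`, per-parcel payments `y_i ≥ 0`. Constraints:

* unit demand `Σ_j z_ij ≤ 1`;
* participation `A_ij·p ≥ (c_ij + ε) z_ij` (exact, no big-M);
* best-response dominance `(A_ij − A_ik)·p ≥ (c_ij − c_ik) − M(1 − z_ij)`;
* no unenrolled surplus `A_ij·p ≤ c_ij + ε + M Σ_k z_ik`;
* payment accounting `y_i ≥ A_ij·p − M(1 − z_ij)`; budget `Σ y_i ≤ B`;
* optional floors `Σ_ij b_ijg z_ij ≥ T_g`;
* two valid inequalities that tighten the LP relaxation decisively:
  `Σ_ij (c_ij + ε) z_ij ≤ B` (payments are at least costs, so enrolled
  costs must fit the budget) and `y_i ≥ Σ_j (c_ij + ε) z_ij`.

Big-M constants are computed per constraint from the price caps. Caps
default to 1.5 × the largest reservation-cost-per-unit breakpoint per
coordinate, ignoring quantities below 1% of the coordinate's maximum
(near-zero quantities would otherwise inflate caps and big-Ms with prices
that can only add spend, never enrolment). Internally the model is
normalized — each price as a fraction of its cap, money in units of the
median reservation cost — which keeps the constraint matrix within a few
orders of magnitude; without this, mixed physical units (litres/day vs £)
produce silently mis-converged solves. The solver is HiGHS through
`scipy.optimize.milp`, default relative gap 1e-9. Among value-maximizing
schedules the spend-minimizing one is selected by a second lexicographic
solve with the optimal value fixed.

Ties (a parcel indifferent between options) are resolved in the
decision-maker's favour in the MIP; the simulator breaks ties toward the
higher-value option, then the lower option index, so simulated uptake
matches the optimizer's prediction on generic instances.

The independent oracle (`brute_force_price_search`) enumerates the vertex
arrangement of the indifference hyperplanes (payment = cost; equal surplus
between option pairs), nudges every vertex by ±δ per coordinate to sample
both sides of each breakpoint, simulates best responses at every candidate,
and keeps the best feasible (value, then min spend) point. It is exact for
≤ 2 active price dimensions and is never used as the production path.

`solve_upper_bound` is the exact multiple-choice knapsack (pay costs,
pick projects); `feasibility_check` distinguishes targets no *selection*
can reach (`infeasible_by_allocation`) from targets no *posted price* can
reach (`infeasible_pricing`) — the central mechanism-vs-allocation
distinction. The cost-based scheme's target cell is a feasibility MIP over
budget-feasible subsets of its willing set, since that scheme has no free
prices to adjust.

## Synthetic landscape generator

The generator emulates the statistical structure of a national parcel ×
option dataset that cannot be shared:

* 2 km grid cells, one parcel per cell; farm type Bernoulli(0.5); areas
  log-normal (median 30 ha, σ = 0.5) — small enough that a pro-rated
  budget funds a double-digit number of projects at desk scale.
* Cost/ha log-normal per option (σ = 0.3) with medians at the published
  cost-based price anchors (≈ £11,100–23,300/ha), split 65/29/6 into
  foregone income, establishment and access components before the mark-up.
* Value/ha per option composed of eight channels with fixed mean shares.
  Carbon is near-homogeneous per hectare within an option (CV 5%) and
  dominates woodland-on-arable; recreation (access options) and flood
  value decay from randomly placed hotspot cells and are zero-inflated
  off-hotspot; nutrient, pollination and river channels carry log-normal
  heterogeneity (σ = 0.7). Mean value/ha spans 12.5× across options.
* Outcome quantities are the channel values divided by fixed unit values
  (£100/tCO₂e, £40 and £25 per µg/l of phosphate/nitrate, £0.5 per l/day,
  £800 per richness point), so outcome prices can target value through
  quantities; recreation is reachable only through the pooled
  accessible-area metrics — the structural reason outcome pricing sits
  between activity and service-value pricing.
* Per-option cost–value correlation is imposed by a Gaussian-scores
  reordering of the cost draws against realized value, with a few
  deterministic fixed-point adjustments of the latent correlation; default
  targets spread evenly over [−0.373, 0.301].
* Biodiversity deltas come from a group × option affinity matrix
  (per-50 ha units) with log-normal noise and an access-disturbance term;
  lichen and lower plants concentrate on the cheapest, least valuable
  option (no-access grassland on pasture), so their delivery is decoupled
  from monetized value — the precondition for pricing-level target
  infeasibility. Deltas may be negative (configurable floor at 0).
* Baseline prevalence is calibrated per group so the 15% target consumes
  half of what a pro-rated budget could deliver for that group alone
  (greedy cost-effectiveness estimate): demanding, allocation-feasible,
  and stressful for value-targeted pricing.

What the generator does *not* emulate: real spatial patterns, within-parcel
cost correlation across options, inter-parcel value interactions, species
identities below group level, or the absolute value magnitudes of any real
landscape. Passing tests therefore certify the *machinery* and the
*qualitative mechanism ordering* under these conditions, not quantitative
predictions for any real scheme.

## Problem sizes

Exact envy-free pricing is NP-hard and the big-M MIP scales steeply, so the
analyses fix sizes where exact solves are routine: calibration statistics
at 2,000 parcels; the unconstrained mechanism ladder and FCFS at 200
parcels (seconds to ~half a minute per solve); the biodiversity grid with
16-instrument extended schedules at 80 parcels (the acceptance sweep runs
its extended comparisons at 60). Budgets are always pro-rated from the
full-scale £1e9 by n/59,648. At these sizes a funded scheme holds ~5–15
projects, so ratio statistics (VfM, spend fractions) are granular; sweep
assertions are therefore about orderings and feasibility patterns, with
Monte-Carlo cells compared at mean ± 3 SE.

## Known limitations

* The spend fraction under optimized prices can sit well below the ~100%
  a full-scale scheme would show, purely from project granularity.
* Which channels dominate an optimized activity scheme is scale-dependent:
  with few funded projects the optimizer can cherry-pick hotspot parcels,
  so the full-scale "activity pricing leans on homogeneous carbon"
  signature is attenuated at desk scale.
* Extended (biodiversity-priced) exact solves above ~100 parcels exceed
  practical time on one CPU; larger runs would need a specialized
  formulation or a heuristic incumbent with a proven bound.
* The FCFS closure rule ("stop" at the first unaffordable application) is
  one reading of budget exhaustion; the "skip" variant is provided and
  spends weakly more on the same arrival order.
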