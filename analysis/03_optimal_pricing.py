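"""Optimize posted prices: activity, outcome and service-value mechanisms.

Solves, on the same landscape and budget as the cost-based simulation:

* the in-theory upper bound (pay exact costs, hand-pick projects:
  a multiple-choice knapsack),
* optimal flat rates per hectare of activity,
* optimal flat rates per unit of environmental outcome,
* optimal prices per pound of ecosystem-service value,

each as an envy-free unit-demand pricing MIP, and reports the
value-for-money ladder, each mechanism's fraction of the upper bound, and
the channel decomposition showing how activity payments lean on
spatially homogeneous carbon while value-targeted payments reach
heterogeneous services.

Writes results/optimal_pricing.json and results/optimal_activity_prices.csv.
"""

import argparse
import json
import pathlib

from pescheme import (
    LandscapeConfig,
    default_epsilon,
    generate_landscape,
    median_cost_prices,
    optimize_prices,
    scaled_budget,
    simulate_fcfs,
    solve_upper_bound,
)
from pescheme.report import outcome_summary, price_table, value_decomposition

STUDY_N = 200
FCFS_RUNS = 1000


def main(seed: int = 0, outdir: str = "results") -> dict:
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    landscape = generate_landscape(LandscapeConfig(n_parcels=STUDY_N), seed=seed)
    budget = scaled_budget(STUDY_N)
    eps = default_epsilon(landscape)

    ub = solve_upper_bound(landscape, budget)
    fcfs = simulate_fcfs(landscape, median_cost_prices(landscape), budget,
                         runs=FCFS_RUNS, seed=seed + 1, epsilon=eps)
    solved = {"upper_bound": ub}
    for mech in ("activity", "outcome", "es_value"):
        solved[mech] = optimize_prices(landscape, budget, mech, epsilon=eps)

    ub_vfm = ub.result.value_for_money
    print(f"value-for-money ladder (budget {budget:,.0f}, {STUDY_N} parcels):")
    print(f"  in-theory upper bound:    {ub_vfm:.3f}")
    rows = {
        "cost_based_fcfs": fcfs.mean_value_for_money,
        "activity": solved["activity"].result.value_for_money,
        "outcome": solved["outcome"].result.value_for_money,
        "es_value": solved["es_value"].result.value_for_money,
    }
    for name, vfm in rows.items():
        print(f"  {name:24s}  {vfm:.3f}  ({vfm / ub_vfm:.0%} of upper bound)")

    act_shares = value_decomposition(solved["activity"].result)
    es_shares = value_decomposition(solved["es_value"].result)
    print("\nwhere the value comes from (share of aggregate value):")
    print(f"  activity pricing: carbon {act_shares['carbon']:.0%}, "
          f"recreation {act_shares['recreation']:.0%}, "
          f"flood {act_shares['flood']:.0%}")
    print(f"  service-value pricing: carbon {es_shares['carbon']:.0%}, "
          f"recreation {es_shares['recreation']:.0%}, "
          f"flood {es_shares['flood']:.0%}")

    payload = {
        "budget": budget,
        "n_parcels": STUDY_N,
        "upper_bound": outcome_summary(ub),
        "cost_based_fcfs": outcome_summary(fcfs),
        **{m: outcome_summary(solved[m]) for m in ("activity", "outcome", "es_value")},
        "activity_channel_shares": act_shares.to_dict(),
        "es_value_channel_shares": es_shares.to_dict(),
    }
    with open(out / "optimal_pricing.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    price_table(
        {
            "cost_based": median_cost_prices(landscape),
            "optimal_budget_constrained": solved["activity"].schedule,
        }
    ).to_csv(out / "optimal_activity_prices.csv")
    return payload


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    main(args.seed, args.out)
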