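"""Optimization stack: knapsack bound, pricing MIP, oracle, audits."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_landscape
from pescheme import (
    LandscapeConfig,
    biodiversity_targets,
    brute_force_price_search,
    check_envy_free,
    default_price_caps,
    feasibility_check,
    generate_landscape,
    make_assignment,
    median_cost_prices,
    optimize_prices,
    scaled_budget,
    solve_upper_bound,
)
from pescheme.schema import (
    N_OPTIONS,
    OPTION_INDEX,
    SPECIES_GROUPS,
    BiodiversityTargets,
    PriceSchedule,
)

SNG_A = "sng_access_arable"
WOOD_A = "woodland_access_arable"
IDX_SNG_A = OPTION_INDEX[SNG_A]


def targets_for(**gains):
    return BiodiversityTargets(
        pd.Series({g: float(gains.get(g, 0.0)) for g in SPECIES_GROUPS})
    )


class TestMedianCostPrices:
    def test_single_parcel_price_is_own_cost_per_ha(self):
        L = build_landscape(
            parcels=[("p1", "arable", 4.0)],
            effects=[("p1", SNG_A, 4000.0, 10.0)],
        )
        sched = median_cost_prices(L)
        assert sched.base_prices[IDX_SNG_A] == pytest.approx(1000.0)

    def test_odd_count_median(self):
        L = build_landscape(
            parcels=[(f"p{i}", "arable", 1.0) for i in range(3)],
            effects=[
                ("p0", SNG_A, 10.0, 1.0),
                ("p1", SNG_A, 20.0, 1.0),
                ("p2", SNG_A, 40.0, 1.0),
            ],
        )
        assert median_cost_prices(L).base_prices[IDX_SNG_A] == pytest.approx(20.0)

    def test_even_count_median_averages_middle_pair(self):
        L = build_landscape(
            parcels=[(f"p{i}", "arable", 1.0) for i in range(4)],
            effects=[
                (f"p{i}", SNG_A, cost, 1.0)
                for i, cost in enumerate((10.0, 20.0, 30.0, 40.0))
            ],
        )
        assert median_cost_prices(L).base_prices[IDX_SNG_A] == pytest.approx(25.0)

    def test_option_without_parcels_warns_and_prices_zero(self):
        L = build_landscape(
            parcels=[("p1", "arable", 1.0)],
            effects=[("p1", SNG_A, 10.0, 1.0)],
        )
        with pytest.warns(UserWarning):
            sched = median_cost_prices(L)
        assert sched.base_prices[OPTION_INDEX["sng_access_pasture"]] == 0.0


class TestUpperBound:
    def test_zero_budget_empty_selection(self, three_parcel_flat):
        out = solve_upper_bound(three_parcel_flat, budget=0.0)
        assert out.status == "optimal"
        assert out.result.aggregate_value == 0.0

    def test_two_parcel_knapsack_against_enumeration(self):
        """P1 {a: cost 3/value 10, b: cost 5/value 14}, P2 {a: cost 4/value 9},
        budget 7: brute enumeration of the 6 selections gives P1a + P2a."""
        L = build_landscape(
            parcels=[("p1", "arable", 1.0), ("p2", "arable", 1.0)],
            effects=[
                ("p1", SNG_A, 3.0, 10.0),
                ("p1", WOOD_A, 5.0, 14.0),
                ("p2", SNG_A, 4.0, 9.0),
            ],
        )
        out = solve_upper_bound(L, budget=7.0)
        assert out.result.aggregate_value == pytest.approx(19.0)
        assert out.result.spend == pytest.approx(7.0)
        chosen = dict(
            zip(out.assignment["parcel_id"], out.assignment["option_id"])
        )
        assert chosen == {"p1": SNG_A, "p2": SNG_A}

    def test_biodiversity_floor_changes_selection(self):
        """Exhaustive enumeration: unconstrained optimum takes the high-value
        project; a bio floor of 5 forces the low-value one."""
        L = build_landscape(
            parcels=[("p1", "arable", 1.0), ("p2", "arable", 1.0)],
            effects=[
                ("p1", SNG_A, 3.0, 10.0),
                ("p2", SNG_A, 3.0, 2.0, None, {"bees": 5.0}),
            ],
        )
        unconstrained = solve_upper_bound(L, budget=3.0)
        assert unconstrained.result.aggregate_value == pytest.approx(10.0)
        constrained = solve_upper_bound(L, budget=3.0, targets=targets_for(bees=5.0))
        assert constrained.status == "optimal"
        assert constrained.result.aggregate_value == pytest.approx(2.0)

    def test_unreachable_targets_are_allocation_infeasible(self, three_parcel_flat):
        out = solve_upper_bound(
            three_parcel_flat, budget=1e9, targets=targets_for(bees=1.0)
        )
        assert out.status == "infeasible_allocation"


class TestOptimizePrices:
    def test_three_parcel_breakpoint_example(self, three_parcel_flat):
        """Optimal flat price ~200 (+eps) enrols the 100- and 200-cost
        parcels: value 550, spend ~400 (breakpoint enumeration oracle)."""
        out = optimize_prices(
            three_parcel_flat, budget=700.0, mechanism="activity", epsilon=1e-4
        )
        assert out.status == "optimal"
        assert out.result.aggregate_value == pytest.approx(550.0)
        assert out.result.spend == pytest.approx(400.0, rel=1e-2)
        assert out.schedule.base_prices[IDX_SNG_A] == pytest.approx(200.0, rel=1e-2)
        assert out.result.n_funded == 2

    def test_budget_below_cheapest_breakpoint_is_empty(self, three_parcel_flat):
        out = optimize_prices(
            three_parcel_flat, budget=50.0, mechanism="activity", epsilon=1e-4
        )
        assert out.status == "optimal"
        assert out.result.aggregate_value == 0.0
        assert out.result.n_funded == 0

    def test_budget_zero_status(self, three_parcel_flat):
        assert (
            optimize_prices(three_parcel_flat, 0.0, "activity").status == "budget_zero"
        )

    def test_mechanism_vs_allocation_infeasibility(
        self, mechanism_infeasibility_fixture
    ):
        """The paper-style distinction: the lichen target is reachable by
        direct selection but by no flat price (any price enrolling the
        bio-rich parcel also enrols the cheap one and busts the budget)."""
        L = mechanism_infeasibility_fixture
        targets = targets_for(lichen=5.0)
        priced = optimize_prices(
            L, budget=350.0, mechanism="activity", targets=targets, epsilon=1e-4
        )
        assert priced.status == "infeasible_pricing"
        assert feasibility_check(L, 350.0, targets) == "feasible_by_allocation"
        allocation = solve_upper_bound(L, budget=350.0, targets=targets)
        assert allocation.status == "optimal"
        assert allocation.result.spend == pytest.approx(300.0)

    def test_unbounded_price_domain_rejected(self, three_parcel_flat):
        with pytest.raises(ValueError):
            optimize_prices(
                three_parcel_flat, 700.0, "activity",
                price_cap=np.full(N_OPTIONS, np.inf),
            )


class TestBruteForce:
    def test_matches_mip_on_breakpoint_example(self, three_parcel_flat):
        mip = optimize_prices(
            three_parcel_flat, 700.0, "activity", epsilon=1e-4
        )
        oracle = brute_force_price_search(
            three_parcel_flat, 700.0, "activity", epsilon=1e-4
        )
        assert oracle.objective_value == pytest.approx(mip.objective_value)
        assert oracle.result.spend == pytest.approx(mip.result.spend, rel=1e-3)

    def test_single_parcel_minimal_enrolling_price(self):
        """Min-spend canonicalization: the cheapest enrolling price is the
        reservation cost plus the participation margin."""
        L = build_landscape(
            parcels=[("p1", "arable", 1.0)],
            effects=[("p1", SNG_A, 100.0, 500.0)],
        )
        out = brute_force_price_search(L, budget=1e4, mechanism="activity",
                                       epsilon=1e-3)
        assert out.result.n_funded == 1
        assert out.schedule.base_prices[IDX_SNG_A] == pytest.approx(100.0, abs=0.1)

    def test_zero_value_landscape_funds_nothing(self):
        L = build_landscape(
            parcels=[("p1", "arable", 1.0), ("p2", "arable", 2.0)],
            effects=[("p1", SNG_A, 100.0, 0.0), ("p2", SNG_A, 150.0, 0.0)],
        )
        out = brute_force_price_search(L, budget=1e5, mechanism="activity",
                                       epsilon=1e-3)
        assert out.objective_value == pytest.approx(0.0)
        assert out.result.n_funded == 0

    def test_too_large_instance_rejected(self, small_default_landscape):
        with pytest.raises(ValueError):
            brute_force_price_search(
                small_default_landscape, 1e6, "activity", max_parcels=15
            )

    def test_explicit_grid(self, three_parcel_flat):
        out = brute_force_price_search(
            three_parcel_flat, 700.0, "activity", epsilon=1e-4,
            active_dims=[IDX_SNG_A], grid=[np.array([0.0, 150.0, 200.001, 330.0])],
        )
        assert out.objective_value == pytest.approx(550.0)


class TestEnvyFreeAudit:
    def test_empty_assignment_zero_prices_passes(self, three_parcel_flat):
        from pescheme.payments import zero_schedule
        from pescheme.evaluate import empty_assignment

        audit = check_envy_free(
            zero_schedule("activity"), empty_assignment(), three_parcel_flat,
            epsilon=1e-4,
        )
        assert audit.passed

    def test_dominated_assignment_names_better_option(self):
        L = build_landscape(
            parcels=[("p1", "arable", 1.0)],
            effects=[
                ("p1", SNG_A, 100.0, 10.0),
                ("p1", WOOD_A, 100.0, 10.0),
            ],
        )
        prices = np.zeros(N_OPTIONS)
        prices[IDX_SNG_A] = 105.0  # surplus 5
        prices[OPTION_INDEX[WOOD_A]] = 150.0  # surplus 50, dominant
        sched = PriceSchedule("activity", prices)
        audit = check_envy_free(
            sched, make_assignment(["p1"], [SNG_A], [105.0]), L, epsilon=1e-4,
            tol=1e-9,
        )
        assert not audit.passed
        assert (audit.violations["kind"] == "dominated_option").any()
        assert WOOD_A in set(audit.violations["better_option"].dropna())

    def test_unenrolled_with_surplus_flagged(self):
        L = build_landscape(
            parcels=[("p1", "arable", 1.0)],
            effects=[("p1", SNG_A, 100.0, 10.0)],
        )
        prices = np.zeros(N_OPTIONS)
        prices[IDX_SNG_A] = 200.0
        from pescheme.evaluate import empty_assignment

        audit = check_envy_free(
            PriceSchedule("activity", prices), empty_assignment(), L,
            epsilon=1e-4, tol=1e-9,
        )
        assert not audit.passed
        assert (audit.violations["kind"] == "unenrolled_with_surplus").any()


class TestFeasibilityCheck:
    def test_zero_targets_always_feasible(self, three_parcel_flat):
        assert (
            feasibility_check(three_parcel_flat, 10.0, targets_for())
            == "feasible_by_allocation"
        )

    def test_targets_above_total_supply_infeasible(self, three_parcel_flat):
        assert (
            feasibility_check(three_parcel_flat, 1e9, targets_for(bees=1e6))
            == "infeasible_by_allocation"
        )


class TestSolverInvariants:
    """Structural relationships between the solvers on small random
    instances (one landscape keeps the suite fast; the acceptance suite
    widens the sweep)."""

    @pytest.fixture(scope="module")
    @staticmethod
    def instance():
        L = generate_landscape(LandscapeConfig(n_parcels=10), seed=77)
        return L, float(L.effects["reservation_cost"].median()) * 3

    def test_upper_bound_dominates_pricing(self, instance):
        L, budget = instance
        ub = solve_upper_bound(L, budget)
        for mech in ("activity", "outcome", "es_value"):
            priced = optimize_prices(L, budget, mech, epsilon=1e-3)
            assert (
                priced.result.aggregate_value
                <= ub.result.aggregate_value * (1 + 1e-9) + 1e-6
            )

    def test_budget_monotonicity(self, instance):
        L, budget = instance
        small = optimize_prices(L, budget * 0.4, "activity", epsilon=1e-3)
        large = optimize_prices(L, budget, "activity", epsilon=1e-3)
        assert large.result.aggregate_value >= small.result.aggregate_value - 1e-6
        ub_small = solve_upper_bound(L, budget * 0.4)
        ub_large = solve_upper_bound(L, budget)
        assert (
            ub_large.result.aggregate_value
            >= ub_small.result.aggregate_value - 1e-6
        )

    def test_targets_never_increase_value(self, instance):
        L, budget = instance
        base = optimize_prices(L, budget, "activity", epsilon=1e-3)
        constrained = optimize_prices(
            L, budget, "activity", targets=biodiversity_targets(L, 0.01),
            epsilon=1e-3,
        )
        if constrained.status == "optimal":
            assert (
                constrained.result.aggregate_value
                <= base.result.aggregate_value * (1 + 1e-9) + 1e-6
            )

    def test_optimal_outcomes_pass_envy_audit_and_budget(self, instance):
        L, budget = instance
        for mech in ("activity", "outcome"):
            out = optimize_prices(L, budget, mech, epsilon=1e-3)
            assert out.status == "optimal"
            audit = check_envy_free(out.schedule, out.assignment, L, epsilon=1e-3)
            assert audit.passed, audit.violations
            assert out.result.spend <= budget * (1 + 1e-6)

    def test_default_caps_are_finite_and_positive_on_support(self, instance):
        L, _ = instance
        caps = default_price_caps(L, "activity")
        assert np.all(np.isfinite(caps))
        present = L.effects["option_id"].map(OPTION_INDEX).unique()
        assert (caps[present] > 0).all()
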