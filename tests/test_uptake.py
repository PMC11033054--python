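"""Landowner best responses and first-come-first-served rationing."""

import numpy as np
import pytest

from conftest import build_landscape
from pescheme import PriceSchedule, simulate_fcfs, willing_set
from pescheme.payments import zero_schedule
from pescheme.schema import N_OPTIONS, OPTION_INDEX
from pescheme.uptake import best_responses


def activity_prices(**per_option):
    prices = np.zeros(N_OPTIONS)
    for opt, p in per_option.items():
        prices[OPTION_INDEX[opt]] = p
    return PriceSchedule("activity", prices)


@pytest.fixture
def two_option_parcel():
    return build_landscape(
        parcels=[("p1", "arable", 1.0)],
        effects=[
            ("p1", "sng_access_arable", 1000.0, 10.0),
            ("p1", "woodland_access_arable", 3000.0, 500.0),
        ],
    )


def test_zero_prices_mean_opt_out(two_option_parcel):
    br = best_responses(two_option_parcel, zero_schedule("activity"), epsilon=1e-6)
    assert br["option_id"].isna().all()
    assert willing_set(two_option_parcel, zero_schedule("activity"), 1e-6).empty


def test_chooses_highest_surplus(two_option_parcel):
    sched = activity_prices(sng_access_arable=2000.0, woodland_access_arable=2000.0)
    br = best_responses(two_option_parcel, sched, epsilon=1e-6)
    # surpluses: sng +1000, woodland -1000
    assert br.loc[0, "option_id"] == "sng_access_arable"
    assert br.loc[0, "surplus"] == pytest.approx(1000.0)


def test_exact_tie_breaks_toward_higher_value(two_option_parcel):
    # both surpluses exactly +500: woodland delivers value 500 vs 10
    sched = activity_prices(sng_access_arable=1500.0, woodland_access_arable=3500.0)
    br = best_responses(two_option_parcel, sched, epsilon=1e-6)
    assert br.loc[0, "option_id"] == "woodland_access_arable"


def test_willing_set_excludes_unprofitable():
    L = build_landscape(
        parcels=[("a", "arable", 1.0), ("b", "arable", 1.0), ("c", "arable", 1.0)],
        effects=[
            ("a", "sng_access_arable", 100.0, 1.0),
            ("b", "sng_access_arable", 150.0, 1.0),
            ("c", "sng_access_arable", 900.0, 1.0),  # priced out
        ],
    )
    w = willing_set(L, activity_prices(sng_access_arable=200.0), epsilon=1e-6)
    assert sorted(w["parcel_id"]) == ["a", "b"]
    assert (w["surplus"] > 1e-6).all()


def test_surplus_strictly_exceeds_epsilon_property(small_default_landscape):
    from pescheme import median_cost_prices, default_epsilon

    eps = default_epsilon(small_default_landscape)
    sched = median_cost_prices(small_default_landscape)
    w = willing_set(small_default_landscape, sched, eps)
    assert len(w) > 0
    assert (w["surplus"] > eps).all()


class TestFcfs:
    @pytest.fixture
    def three_identical_applicants(self):
        return build_landscape(
            parcels=[(f"p{i}", "arable", 1.0) for i in range(3)],
            effects=[
                (f"p{i}", "sng_access_arable", 30.0, 100.0) for i in range(3)
            ],
        )

    def test_zero_budget_funds_nothing(self, three_identical_applicants):
        r = simulate_fcfs(
            three_identical_applicants, activity_prices(sng_access_arable=60.0),
            budget=0.0, runs=20, seed=1, epsilon=1e-6,
        )
        assert (r.runs_table["n_funded"] == 0).all()
        assert r.mean_value_for_money is None

    def test_budget_for_two_of_three(self, three_identical_applicants):
        """Payment 60 each, budget 150: every arrival order funds exactly
        two applicants, spend 120, with zero Monte-Carlo error."""
        r = simulate_fcfs(
            three_identical_applicants, activity_prices(sng_access_arable=60.0),
            budget=150.0, runs=60, seed=1, epsilon=1e-6,
        )
        assert (r.runs_table["n_funded"] == 2).all()
        assert np.allclose(r.runs_table["spend"], 120.0)
        assert r.se_value_for_money == 0.0

    def test_ample_budget_is_order_invariant(self, three_identical_applicants):
        r = simulate_fcfs(
            three_identical_applicants, activity_prices(sng_access_arable=60.0),
            budget=1000.0, runs=40, seed=2, epsilon=1e-6,
        )
        assert (r.runs_table["n_funded"] == 3).all()
        assert r.runs_table["value"].nunique() == 1
        assert r.se_value_for_money == 0.0
        assert r.mean_spend == pytest.approx(180.0)

    def test_spend_never_exceeds_budget(self, small_default_landscape):
        from pescheme import median_cost_prices, default_epsilon, scaled_budget

        L = small_default_landscape
        budget = scaled_budget(L.n_parcels)
        r = simulate_fcfs(
            L, median_cost_prices(L), budget, runs=100, seed=3,
            epsilon=default_epsilon(L),
        )
        assert (r.runs_table["spend"] <= budget * (1 + 1e-9)).all()

    def test_stop_spends_weakly_less_than_skip(self):
        """On the same arrival order, closing at the first unaffordable
        application can never spend more than skipping it."""
        L = build_landscape(
            parcels=[(f"p{i}", "arable", 1.0 + 0.4 * i) for i in range(6)],
            effects=[
                (f"p{i}", "sng_access_arable", 10.0 + 17.0 * i, 50.0)
                for i in range(6)
            ],
        )
        sched = activity_prices(sng_access_arable=120.0)  # payments 120..360
        # same seed => identical permutation sequence in both runs
        stop = simulate_fcfs(L, sched, budget=300.0, runs=50, seed=4,
                             closure="stop", epsilon=1e-6)
        skip = simulate_fcfs(L, sched, budget=300.0, runs=50, seed=4,
                             closure="skip", epsilon=1e-6)
        assert (stop.runs_table["spend"] <= skip.runs_table["spend"] + 1e-9).all()

    def test_run_results_optionally_kept(self, three_identical_applicants):
        r = simulate_fcfs(
            three_identical_applicants, activity_prices(sng_access_arable=60.0),
            budget=150.0, runs=5, seed=1, epsilon=1e-6, keep_runs=True,
        )
        assert len(r.run_results) == 5
        assert all(s.spend == pytest.approx(120.0) for s in r.run_results)

    def test_invalid_arguments(self, three_identical_applicants):
        sched = activity_prices(sng_access_arable=60.0)
        with pytest.raises(ValueError):
            simulate_fcfs(three_identical_applicants, sched, 100.0, runs=0)
        with pytest.raises(ValueError):
            simulate_fcfs(three_identical_applicants, sched, 100.0, closure="queue")
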