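"""Reporting: decomposition shares, comparison/price tables, experiments."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_landscape
from pescheme import evaluate_scheme, make_assignment
from pescheme.report import (
    INFEASIBLE,
    NOT_APPLICABLE,
    ExperimentSpec,
    price_table,
    run_experiment,
    scheme_comparison_table,
    value_decomposition,
)
from pescheme.optimize import OptimizationOutcome
from pescheme.schema import N_OPTIONS, N_PRICEABLE, PriceSchedule


@pytest.fixture
def scored_scheme():
    L = build_landscape(
        parcels=[("p1", "arable", 1.0)],
        effects=[("p1", "sng_access_arable", 50.0,
                  {"carbon": 84.0, "recreation": 16.0})],
    )
    a = make_assignment(["p1"], ["sng_access_arable"], [60.0])
    return evaluate_scheme(a, L, budget=100.0)


class TestValueDecomposition:
    def test_two_channel_shares(self, scored_scheme):
        shares = value_decomposition(scored_scheme)
        assert shares["carbon"] == pytest.approx(0.84)
        assert shares["recreation"] == pytest.approx(0.16)

    def test_shares_sum_to_one(self, scored_scheme):
        assert value_decomposition(scored_scheme).sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_single_channel_share_is_one(self):
        L = build_landscape(
            parcels=[("p1", "arable", 1.0)],
            effects=[("p1", "sng_access_arable", 50.0, 75.0)],
        )
        res = evaluate_scheme(
            make_assignment(["p1"], ["sng_access_arable"], [60.0]), L, 100.0
        )
        shares = value_decomposition(res)
        assert shares["carbon"] == pytest.approx(1.0)

    def test_zero_value_rejected(self):
        L = build_landscape(
            parcels=[("p1", "arable", 1.0)],
            effects=[("p1", "sng_access_arable", 50.0, 0.0)],
        )
        res = evaluate_scheme(
            make_assignment(["p1"], ["sng_access_arable"], [60.0]), L, 100.0
        )
        with pytest.raises(ValueError):
            value_decomposition(res)

    def test_negative_channel_gives_signed_share(self):
        L = build_landscape(
            parcels=[("p1", "arable", 1.0)],
            effects=[("p1", "sng_access_arable", 50.0,
                      {"carbon": 120.0, "residual_production": -20.0})],
        )
        res = evaluate_scheme(
            make_assignment(["p1"], ["sng_access_arable"], [60.0]), L, 100.0
        )
        shares = value_decomposition(res)
        assert shares["residual_production"] == pytest.approx(-0.2)
        assert shares.sum() == pytest.approx(1.0, abs=1e-9)


class TestComparisonTable:
    def test_single_cell(self):
        out = OptimizationOutcome(status="infeasible_pricing")
        table = scheme_comparison_table({("activity", "budget_constrained"): out})
        assert table.shape == (1, 1)
        assert table.loc["activity", "budget_constrained"] == INFEASIBLE

    def test_infeasible_cells_are_markers_not_numbers(self):
        ok = OptimizationOutcome(status="infeasible_pricing")
        table = scheme_comparison_table(
            {
                ("es_value", "budget_constrained"): ok,
                ("es_value", "biodiversity_constrained"): None,
            }
        )
        assert table.loc["es_value", "budget_constrained"] == INFEASIBLE
        assert table.loc["es_value", "biodiversity_constrained"] == NOT_APPLICABLE

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            scheme_comparison_table({("lottery", "budget_constrained"): None})

    def test_csv_round_trip_preserves_cells(self, tmp_path):
        table = scheme_comparison_table(
            {
                ("activity", "budget_constrained"): OptimizationOutcome(
                    status="infeasible_pricing"
                ),
                ("upper_bound", "budget_constrained"): None,
            }
        )
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        assert back.loc["activity", "budget_constrained"] == INFEASIBLE
        assert back.loc["upper_bound", "budget_constrained"] == NOT_APPLICABLE


class TestPriceTable:
    def test_activity_schedule_has_eight_rows(self):
        t = price_table({"base": PriceSchedule("activity", np.zeros(N_OPTIONS))})
        assert len(t) == N_OPTIONS
        # zero prices render as numeric 0, not blanks
        assert (t["base"] == 0.0).all()

    def test_extended_schedule_adds_biodiversity_block(self):
        sched = PriceSchedule(
            "activity", np.zeros(N_OPTIONS), biodiversity_prices=np.arange(8.0)
        )
        plain = PriceSchedule("activity", np.ones(N_OPTIONS))
        t = price_table({"ext": sched, "plain": plain})
        assert len(t) == 16
        assert t.loc["gastropods", "ext"] == pytest.approx(4.0)
        assert t.loc["gastropods", "plain"] == NOT_APPLICABLE

    def test_mechanism_mix_rejected(self):
        with pytest.raises(ValueError):
            price_table(
                {
                    "a": PriceSchedule("activity", np.zeros(N_OPTIONS)),
                    "b": PriceSchedule("es_value", np.zeros(N_PRICEABLE)),
                }
            )


class TestRunExperiment:
    SPEC = dict(
        landscape={"generate": {"n_parcels": 60}},
        scenarios=[
            {"mechanism": "upper_bound"},
            {"mechanism": "cost_based"},
            {"mechanism": "activity"},
        ],
        runs=50,
        seed=5,
        min_spend=False,
    )

    def test_end_to_end_smoke(self, tmp_path):
        result = run_experiment(ExperimentSpec(**self.SPEC), outdir=tmp_path)
        assert set(result.comparison.index) == {"upper_bound", "cost_based", "activity"}
        assert (tmp_path / "comparison.csv").exists()
        assert (tmp_path / "results.json").exists()
        # knapsack dominance is on aggregate value (VfM is a ratio and can
        # flip when spends differ)
        ub = result.outcomes[("upper_bound", "budget_constrained")]
        act = result.outcomes[("activity", "budget_constrained")]
        assert ub.result.aggregate_value >= act.result.aggregate_value - 1e-6

    def test_rerun_is_deterministic(self, tmp_path):
        a = run_experiment(ExperimentSpec(**self.SPEC), outdir=tmp_path / "a")
        b = run_experiment(ExperimentSpec(**self.SPEC), outdir=tmp_path / "b")
        assert (tmp_path / "a" / "comparison.csv").read_text() == (
            tmp_path / "b" / "comparison.csv"
        ).read_text()
        pd.testing.assert_frame_equal(a.comparison, b.comparison)

    def test_missing_landscape_file_is_stage_labelled(self):
        with pytest.raises(FileNotFoundError):
            ExperimentSpec(
                landscape={"file": "/nonexistent/landscape"},
                scenarios=[{"mechanism": "activity"}],
            )

    def test_empty_scenarios_rejected(self):
        with pytest.raises(ValueError):
            ExperimentSpec(landscape={"generate": {"n_parcels": 10}}, scenarios=[])
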