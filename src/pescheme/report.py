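"""Comparison tables, value decomposition, and experiment orchestration.

The headline deliverable of a scheme analysis is a mechanism-comparison
table: rows are payment mechanisms (in-theory upper bound, cost-based
activity prices, optimal activity prices, optimal outcome prices, optimal
ecosystem-service-value prices), columns are the scenario family
(budget-constrained only; plus biodiversity targets; plus biodiversity
pricing), and each cell holds the scheme's value-for-money or an
infeasibility marker.  A companion price table lists the posted prices
behind each scenario.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import __version__ as _pkg_version
from .landscape import LandscapeConfig, generate_landscape, read_landscape
from .optimize import (
    OptimizationOutcome,
    biodiversity_targets,
    default_epsilon,
    median_cost_prices,
    optimize_prices,
    solve_upper_bound,
)
from .schema import (
    B_COLS,
    N_GROUPS,
    OPTION_IDS,
    SPECIES_GROUPS,
    BiodiversityTargets,
    Landscape,
    PriceSchedule,
    SchemeResult,
    scaled_budget,
)
from .uptake import FcfsResult, simulate_fcfs, willing_set

INFEASIBLE = "infeasible"
NOT_APPLICABLE = "—"

SCENARIO_COLUMNS = ("budget_constrained", "biodiversity_constrained", "biodiversity_pricing")
MECHANISM_ROWS = ("upper_bound", "cost_based", "activity", "outcome", "es_value")

# Table-style display names for the eight options
OPTION_DISPLAY = {
    "sng_access_arable": "arable to SNG, access",
    "sng_access_pasture": "pasture to SNG, access",
    "woodland_access_arable": "arable to woods, access",
    "woodland_access_pasture": "pasture to woods, access",
    "sng_noaccess_arable": "arable to SNG, no access",
    "sng_noaccess_pasture": "pasture to SNG, no access",
    "woodland_noaccess_arable": "arable to woods, no access",
    "woodland_noaccess_pasture": "pasture to woods, no access",
}

_PRICE_UNITS = {
    "activity": "£ per hectare",
    "outcome": "£ per unit of outcome",
    "es_value": "£ per £ of service value",
}
_BIO_UNIT = "£ per additional species presence in a 2 km cell delivered by project"


def value_decomposition(result: SchemeResult) -> pd.Series:
    """Share of aggregate value arriving through each channel (sums to 1).

    Shares are signed: a channel that loses value (for example residual
    production margins) carries a negative share.
    """
    if result.aggregate_value == 0:
        raise ValueError("value decomposition undefined for zero aggregate value")
    return result.channel_decomposition / result.aggregate_value


def _cell(outcome: Union[OptimizationOutcome, FcfsResult, None]):
    if outcome is None:
        return NOT_APPLICABLE
    if isinstance(outcome, FcfsResult):
        return outcome.mean_value_for_money
    if isinstance(outcome, str):
        return outcome
    if outcome.status != "optimal":
        return INFEASIBLE
    if outcome.result is None or outcome.result.value_for_money is None:
        return np.nan
    return outcome.result.value_for_money


def scheme_comparison_table(labelled_outcomes: dict) -> pd.DataFrame:
    """Assemble the mechanism x scenario value-for-money table.

    ``labelled_outcomes`` maps (mechanism_row, scenario_column) to an
    OptimizationOutcome, an FcfsResult, a status string, or None (cell not
    in the experiment).  Rows/columns follow the canonical ordering;
    infeasible outcomes render as markers, never numbers.
    """
    seen = set()
    for key in labelled_outcomes:
        if key in seen:
            raise ValueError(f"duplicate scenario label {key}")
        seen.add(key)
    rows = [r for r in MECHANISM_ROWS if any(k[0] == r for k in labelled_outcomes)]
    cols = [c for c in SCENARIO_COLUMNS if any(k[1] == c for k in labelled_outcomes)]
    table = pd.DataFrame(index=rows, columns=cols, dtype=object)
    for (r, c), outcome in labelled_outcomes.items():
        if r not in MECHANISM_ROWS or c not in SCENARIO_COLUMNS:
            raise ValueError(f"unknown scenario label ({r}, {c})")
        table.loc[r, c] = _cell(outcome)
    table.index.name = "payment_mechanism"
    return table.where(table.notna(), NOT_APPLICABLE)


def price_table(schedules: dict[str, Optional[PriceSchedule]]) -> pd.DataFrame:
    """One column per scenario, one row per price coordinate, units annotated.

    All non-None schedules must share a mechanism.  Zero prices render as
    0.0; a scenario that lacks a coordinate block (no biodiversity prices)
    renders as the '—' marker.
    """
    mechs = {s.mechanism for s in schedules.values() if s is not None}
    if len(mechs) > 1:
        raise ValueError(f"schedules mix mechanisms: {sorted(mechs)}")
    if not mechs:
        return pd.DataFrame()
    mech = mechs.pop()
    ref = next(s for s in schedules.values() if s is not None)
    labels = [
        OPTION_DISPLAY.get(l, l) if mech == "activity" else l for l in ref.price_labels
    ]
    any_extended = any(s is not None and s.extended for s in schedules.values())

    index = labels + (list(SPECIES_GROUPS) if any_extended else [])
    units = [_PRICE_UNITS[mech]] * len(labels) + (
        [_BIO_UNIT] * N_GROUPS if any_extended else []
    )
    table = pd.DataFrame(index=index, dtype=object)
    table["unit"] = units
    for name, sched in schedules.items():
        if sched is None:
            table[name] = NOT_APPLICABLE
            continue
        col = list(np.asarray(sched.base_prices, dtype=float))
        if any_extended:
            if sched.extended:
                col += list(np.asarray(sched.biodiversity_prices, dtype=float))
            else:
                col += [NOT_APPLICABLE] * N_GROUPS
        table[name] = col
    table.index.name = "price"
    return table


def cost_based_target_feasibility(
    landscape: Landscape,
    schedule: PriceSchedule,
    budget: float,
    targets: BiodiversityTargets,
    epsilon: Optional[float] = None,
) -> str:
    """Could ANY budget-feasible draw of the FCFS queue meet the targets?

    The cost-based scheme has no prices to adjust: uptake is fixed by the
    posted median prices and only the arrival order varies.  The most
    favourable case is the best budget-feasible subset of the willing set,
    found by a small feasibility MIP.  Returns 'feasible' or 'infeasible'.
    """
    eps = default_epsilon(landscape) if epsilon is None else float(epsilon)
    willing = willing_set(landscape, schedule, eps)
    if len(willing) == 0:
        return "infeasible" if (targets.values > 0).any() else "feasible"
    merged = willing.merge(
        landscape.effects[["parcel_id", "option_id"] + list(B_COLS)],
        on=["parcel_id", "option_id"],
    )
    pay = merged["payment"].to_numpy(dtype=float)
    bio = merged[list(B_COLS)].to_numpy(dtype=float)
    m = len(merged)
    A = sparse.vstack(
        [sparse.csr_matrix(pay[None, :]), sparse.csr_matrix(bio.T)], format="csr"
    )
    lb = np.concatenate([[-np.inf], targets.values])
    ub = np.concatenate([[budget], np.full(N_GROUPS, np.inf)])
    res = milp(
        c=np.zeros(m),
        constraints=[LinearConstraint(A, lb, ub)],
        integrality=np.ones(m),
        bounds=Bounds(0, 1),
    )
    return "feasible" if res.status == 0 else "infeasible"


# ----------------------------------------------------------------------
# experiment orchestration
# ----------------------------------------------------------------------

@dataclass
class ExperimentSpec:
    """Declarative description of a full scheme-comparison experiment."""

    landscape: dict  # {"generate": {config kwargs}} or {"file": path}
    scenarios: list  # [{"mechanism": ..., "variant": ..., "tau": ...}, ...]
    budget: Optional[float] = None  # None => pro-rated from the full-scale 1e9
    tau: float = 0.15
    runs: int = 1000
    seed: int = 0
    closure: str = "stop"
    min_spend: bool = True

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("scenario list must be non-empty")
        if "file" in self.landscape:
            p = pathlib.Path(self.landscape["file"])
            if not p.exists():
                raise FileNotFoundError(f"landscape source missing: {p}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    landscape: Landscape
    budget: float
    outcomes: dict  # (mechanism, variant) -> outcome object
    comparison: pd.DataFrame
    price_tables: dict  # mechanism -> DataFrame
    log: dict = field(default_factory=dict)


def _spec_hash(spec: ExperimentSpec) -> str:
    payload = json.dumps(spec.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(spec: ExperimentSpec, outdir=None) -> ExperimentResult:
    """Execute generate -> simulate/optimize per scenario -> report.

    Fully reproducible from the spec: the landscape seed, the FCFS seed
    and the solver are all pinned, and run metadata (seed, config hash,
    solver, package version) is embedded in the output log.
    """
    try:
        if "generate" in spec.landscape:
            cfg = LandscapeConfig(**spec.landscape["generate"])
            landscape = generate_landscape(cfg, seed=spec.seed)
        else:
            landscape = read_landscape(spec.landscape["file"])
    except Exception as exc:  # noqa: BLE001 - stage-labelled diagnostics
        raise RuntimeError(f"[stage: landscape] {exc}") from exc

    budget = spec.budget if spec.budget is not None else scaled_budget(landscape.n_parcels)
    eps = default_epsilon(landscape)
    targets = biodiversity_targets(landscape, spec.tau)

    outcomes: dict = {}
    schedules: dict[str, dict[str, Optional[PriceSchedule]]] = {}
    for scen in spec.scenarios:
        mech = scen["mechanism"]
        variant = scen.get("variant", "budget_constrained")
        tgt = targets if variant != "budget_constrained" else None
        ext = variant == "biodiversity_pricing"
        label = (mech, variant)
        try:
            if mech == "upper_bound":
                outcomes[label] = solve_upper_bound(landscape, budget, tgt)
            elif mech == "cost_based":
                sched = median_cost_prices(landscape)
                schedules.setdefault("activity", {})[f"cost_based/{variant}"] = sched
                if variant == "budget_constrained":
                    outcomes[label] = simulate_fcfs(
                        landscape, sched, budget, runs=spec.runs,
                        seed=spec.seed, closure=spec.closure, epsilon=eps,
                    )
                elif variant == "biodiversity_constrained":
                    outcomes[label] = cost_based_target_feasibility(
                        landscape, sched, budget, targets, eps
                    )
                else:  # no free prices to extend
                    outcomes[label] = None
            else:
                out = optimize_prices(
                    landscape, budget, mech, targets=tgt, extended=ext,
                    epsilon=eps, min_spend=spec.min_spend,
                )
                outcomes[label] = out
                schedules.setdefault(mech, {})[f"{mech}/{variant}"] = out.schedule
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"[stage: scenario {label}] {exc}") from exc

    comparison = scheme_comparison_table(outcomes)
    tables = {mech: price_table(s) for mech, s in schedules.items()}
    log = {
        "package_version": _pkg_version,
        "seed": spec.seed,
        "budget": budget,
        "epsilon": eps,
        "tau": spec.tau,
        "spec_hash": _spec_hash(spec),
        "solver": "scipy.optimize.milp (HiGHS)",
        "n_parcels": landscape.n_parcels,
    }
    result = ExperimentResult(
        spec=spec, landscape=landscape, budget=budget, outcomes=outcomes,
        comparison=comparison, price_tables=tables, log=log,
    )
    if outdir is not None:
        _write_experiment(result, outdir)
    return result


def outcome_summary(outcome) -> dict:
    """JSON-friendly summary of any scenario outcome."""
    if outcome is None:
        return {"status": NOT_APPLICABLE}
    if isinstance(outcome, str):
        return {"status": outcome}
    if isinstance(outcome, FcfsResult):
        return {
            "status": "simulated",
            "mean_value_for_money": outcome.mean_value_for_money,
            "se_value_for_money": outcome.se_value_for_money,
            "mean_value": outcome.mean_value,
            "mean_spend": outcome.mean_spend,
            "mean_uptake": outcome.mean_uptake,
            "n_willing": outcome.n_willing,
            "closure": outcome.closure,
            "runs": outcome.n_runs,
        }
    summary = {"status": outcome.status, "gap": outcome.gap}
    if outcome.result is not None:
        summary.update(
            value_for_money=outcome.result.value_for_money,
            aggregate_value=outcome.result.aggregate_value,
            spend=outcome.result.spend,
            n_funded=outcome.result.n_funded,
            biodiversity_gain=outcome.result.biodiversity_gain.to_dict(),
        )
        if outcome.result.target_attainment is not None:
            summary["target_attainment"] = {
                k: bool(v) for k, v in outcome.result.target_attainment.items()
            }
    return summary


def _write_experiment(result: ExperimentResult, outdir) -> None:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.comparison.to_csv(outdir / "comparison.csv")
    for mech, table in result.price_tables.items():
        table.to_csv(outdir / f"prices_{mech}.csv")
    payload = {
        "log": result.log,
        "outcomes": {
            f"{m}/{v}": outcome_summary(o) for (m, v), o in result.outcomes.items()
        },
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    with open(outdir / "run.log", "w") as fh:
        for k, val in result.log.items():
            fh.write(f"{k}: {val}\n")
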