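"""Landowner behaviour under posted prices, and FCFS rationing.

Facing a posted-price schedule, each landowner compares the surplus
(payment minus reservation cost) of their four applicable options and
volunteers the parcel for the surplus-maximizing one, provided that
surplus strictly exceeds the participation margin epsilon.  Ties are
broken toward the option delivering more ecosystem-service value and then
toward the earlier option in the schema order, matching the tie rule the
price optimizer assumes.

When posted prices attract more demand than the budget can fund (the
cost-based scheme), uptake is rationed first-come-first-served: each
Monte-Carlo run draws a uniformly random arrival order over the willing
parcels and funds applications while the budget allows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .evaluate import evaluate_scheme, make_assignment
from .payments import payment_vector
from .schema import OPTION_INDEX, V_COLS, Landscape, PriceSchedule, SchemeResult


@dataclass
class UptakeChoice:
    """One landowner's best response to a schedule."""

    parcel_id: str
    option_id: Optional[str]  # None = opt out
    surplus: float
    payment: float


@dataclass
class FcfsResult:
    """Monte-Carlo summary of the first-come-first-served scheme."""

    runs_table: pd.DataFrame  # per run: spend, value, vfm, n_funded
    mean_value_for_money: Optional[float]
    se_value_for_money: float
    mean_value: float
    mean_spend: float
    mean_uptake: float
    closure: str
    budget: float
    n_willing: int
    run_results: Optional[list[SchemeResult]] = None

    @property
    def n_runs(self) -> int:
        return len(self.runs_table)


def best_responses(
    landscape: Landscape, schedule: PriceSchedule, epsilon: float
) -> pd.DataFrame:
    """Best response of every parcel: one row each, opt-outs included.

    Columns: parcel_id, option_id (NaN when opting out), surplus, payment,
    value (total monetized value of the chosen project, 0 for opt-outs).
    """
    eff = landscape.effects
    pay = payment_vector(schedule, landscape)
    cost = eff["reservation_cost"].to_numpy(dtype=float)
    surplus = pay - cost
    value = eff[list(V_COLS)].sum(axis=1).to_numpy(dtype=float)
    opt_idx = eff["option_id"].map(OPTION_INDEX).to_numpy()
    parcel_codes, parcel_ids = pd.factorize(eff["parcel_id"], sort=True)

    # sort so the last row per parcel is the tie-broken argmax
    order = np.lexsort((-opt_idx, value, surplus, parcel_codes))
    codes_sorted = parcel_codes[order]
    last = np.flatnonzero(
        np.r_[codes_sorted[1:] != codes_sorted[:-1], True]
    )
    pick = order[last]

    out = pd.DataFrame(
        {
            "parcel_id": parcel_ids[parcel_codes[pick]],
            "option_id": eff["option_id"].to_numpy()[pick],
            "surplus": surplus[pick],
            "payment": pay[pick],
            "value": value[pick],
        }
    )
    optout = out["surplus"] <= epsilon
    out.loc[optout, "option_id"] = None
    out.loc[optout, ["payment", "value"]] = 0.0
    return out


def best_response(
    parcel_effects: pd.DataFrame, schedule: PriceSchedule, parcel: pd.Series,
    epsilon: float,
) -> UptakeChoice:
    """Scalar convenience wrapper for a single parcel's effects rows."""
    from .payments import payment as _payment

    best = None
    for _, row in parcel_effects.iterrows():
        pay = _payment(schedule, row, parcel)
        s = pay - float(row["reservation_cost"])
        v = float(row[list(V_COLS)].sum())
        key = (s, v, -OPTION_INDEX[row["option_id"]])
        if best is None or key > best[0]:
            best = (key, row["option_id"], s, pay)
    if best is None or best[2] <= epsilon:
        pid = str(parcel_effects["parcel_id"].iloc[0]) if len(parcel_effects) else ""
        return UptakeChoice(pid, None, best[2] if best else -np.inf, 0.0)
    return UptakeChoice(
        str(parcel_effects["parcel_id"].iloc[0]), best[1], best[2], best[3]
    )


def willing_set(
    landscape: Landscape, schedule: PriceSchedule, epsilon: float
) -> pd.DataFrame:
    """Parcels whose best response is to participate (surplus > epsilon)."""
    br = best_responses(landscape, schedule, epsilon)
    return br[br["option_id"].notna()].reset_index(drop=True)


def _fund_stop(payments: np.ndarray, budget: float) -> np.ndarray:
    """Fund the arrival-order prefix; the scheme closes at the first
    application it cannot afford."""
    cum = np.cumsum(payments)
    over = cum > budget * (1 + 1e-12)
    k = int(np.argmax(over)) if over.any() else len(payments)
    mask = np.zeros(len(payments), dtype=bool)
    mask[:k] = True
    return mask

def _fund_skip(payments: np.ndarray, budget: float) -> np.ndarray:
    """Keep scanning the queue, funding any application that still fits."""
    mask = np.zeros(len(payments), dtype=bool)
    remaining = budget
    for i, p in enumerate(payments):
        if p <= remaining * (1 + 1e-12):
            mask[i] = True
            remaining -= p
    return mask


def simulate_fcfs(
    landscape: Landscape,
    schedule: PriceSchedule,
    budget: float,
    runs: int = 1000,
    seed: Optional[int] = None,
    closure: str = "stop",
    epsilon: float = 1e-3,
    keep_runs: bool = False,
) -> FcfsResult:
    """Monte-Carlo first-come-first-served rationing of a posted-price scheme.

    Each run permutes the willing set uniformly at random and funds
    applications in arrival order under the chosen closure rule ("stop":
    the scheme closes at the first unaffordable application; "skip": it
    continues scanning for affordable ones).  Returns per-run aggregates
    and the mean value-for-money with its Monte-Carlo standard error.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if closure not in ("stop", "skip"):
        raise ValueError("closure must be 'stop' or 'skip'")
    if budget < 0:
        raise ValueError("budget must be >= 0")
    rng = np.random.default_rng(seed)

    willing = willing_set(landscape, schedule, epsilon)
    nw = len(willing)
    payments = willing["payment"].to_numpy(dtype=float)
    values = willing["value"].to_numpy(dtype=float)
    fund = _fund_stop if closure == "stop" else _fund_skip

    rows = []
    run_results: Optional[list[SchemeResult]] = [] if keep_runs else None
    for _ in range(runs):
        perm = rng.permutation(nw)
        mask = fund(payments[perm], budget)
        funded = perm[mask]
        spend = float(payments[funded].sum())
        value = float(values[funded].sum())
        rows.append(
            {
                "spend": spend,
                "value": value,
                "vfm": value / spend if spend > 0 else np.nan,
                "n_funded": int(mask.sum()),
            }
        )
        if keep_runs:
            sub = willing.iloc[funded]
            run_results.append(
                evaluate_scheme(
                    make_assignment(sub["parcel_id"], sub["option_id"], sub["payment"]),
                    landscape,
                    budget,
                )
            )

    table = pd.DataFrame(rows)
    vfm = table["vfm"].dropna()
    mean_vfm = float(vfm.mean()) if len(vfm) else None
    if len(vfm) <= 1 or vfm.nunique() == 1:
        se = 0.0  # identical runs carry exactly zero Monte-Carlo error
    else:
        se = float(vfm.std(ddof=1) / np.sqrt(len(vfm)))
        # runs that fund the same set differ only in float summation
        # order; that is not Monte-Carlo error
        if mean_vfm is not None and se < 1e-12 * abs(mean_vfm):
            se = 0.0
    return FcfsResult(
        runs_table=table,
        mean_value_for_money=mean_vfm,
        se_value_for_money=se,
        mean_value=float(table["value"].mean()),
        mean_spend=float(table["spend"].mean()),
        mean_uptake=float(table["n_funded"].mean()),
        closure=closure,
        budget=budget,
        n_willing=nw,
        run_results=run_results,
    )
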