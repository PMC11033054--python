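"""Scheme evaluation: spend, aggregate value, value-for-money, decomposition.

Value-for-money (VfM) is judged from the policy-maker's side: the increase
in aggregate monetized ecosystem-service value delivered by funded projects
divided by the public money spent.  A scheme that funds nothing has
undefined VfM (reported as None, never 0).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .schema import (
    B_COLS,
    SPECIES_GROUPS,
    V_COLS,
    VALUE_CHANNELS,
    BiodiversityTargets,
    Landscape,
    SchemeResult,
)

ASSIGNMENT_COLUMNS = ("parcel_id", "option_id", "payment")


def empty_assignment() -> pd.DataFrame:
    return pd.DataFrame({c: [] for c in ASSIGNMENT_COLUMNS})


def make_assignment(parcel_ids, option_ids, payments) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "parcel_id": list(parcel_ids),
            "option_id": list(option_ids),
            "payment": np.asarray(list(payments), dtype=float),
        }
    )
    if df["parcel_id"].duplicated().any():
        raise ValueError("a parcel may be funded for at most one option")
    if len(df) and (df["payment"] < 0).any():
        raise ValueError("payments must be >= 0")
    return df


def evaluate_scheme(
    assignment: pd.DataFrame,
    landscape: Landscape,
    budget: float,
    targets: Optional[BiodiversityTargets] = None,
) -> SchemeResult:
    """Score a funded assignment against budget and (optionally) targets.

    ``assignment`` holds one row per funded parcel with its chosen option
    and the payment made.  Every (parcel, option) row must exist in the
    landscape's effects table.
    """
    assignment = assignment[list(ASSIGNMENT_COLUMNS)].copy()
    if assignment["parcel_id"].duplicated().any():
        raise ValueError("a parcel may be funded for at most one option")

    merged = assignment.merge(
        landscape.effects, on=["parcel_id", "option_id"], how="left", validate="1:1"
    )
    if merged["reservation_cost"].isna().any():
        bad = merged.loc[
            merged["reservation_cost"].isna(), ["parcel_id", "option_id"]
        ].values.tolist()
        raise KeyError(f"assignment references unknown parcel/option pairs: {bad[:5]}")

    spend = float(assignment["payment"].sum())
    channel = merged[list(V_COLS)].sum(axis=0)
    channel.index = list(VALUE_CHANNELS)
    aggregate_value = float(channel.sum())
    bio = merged[list(B_COLS)].sum(axis=0)
    bio.index = list(SPECIES_GROUPS)

    vfm = aggregate_value / spend if spend > 0 else None
    attainment = None
    if targets is not None:
        attainment = pd.Series(
            bio.to_numpy() >= targets.values - 1e-9, index=list(SPECIES_GROUPS)
        )

    return SchemeResult(
        assignment=assignment,
        spend=spend,
        aggregate_value=aggregate_value,
        value_for_money=vfm,
        channel_decomposition=channel.astype(float),
        biodiversity_gain=bio.astype(float),
        budget_ok=bool(spend <= budget + 1e-6 * max(1.0, budget)),
        target_attainment=attainment,
    )
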