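"""Payment rules: what a posted-price schedule pays for a given project.

All three mechanisms are linear in their prices:

* activity      payment = price[option] x hectares converted
* outcome       payment = sum_k price_k x outcome quantity_k
* es_value      payment = sum_k price_k x positive part of channel value_k

Extended schedules add sum_g biodiversity_price_g x positive part of the
group-g prevalence delta.  Negative outcome values or prevalence losses are
never clawed back: payments dot only the positive parts, so payments are
always non-negative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import (
    B_COLS,
    N_GROUPS,
    N_METRICS,
    N_OPTIONS,
    N_PRICEABLE,
    OPTION_INDEX,
    PRICEABLE_CHANNELS,
    Q_COLS,
    Landscape,
    PriceSchedule,
)

_V_PRICEABLE_COLS = tuple(f"v_{c}" for c in PRICEABLE_CHANNELS)

_BASE_DIM = {"activity": N_OPTIONS, "outcome": N_METRICS, "es_value": N_PRICEABLE}


def base_dim(mechanism: str) -> int:
    """Number of base price coordinates for a mechanism."""
    return _BASE_DIM[mechanism]


def payment_basis(
    effects: pd.DataFrame, parcels: pd.DataFrame, mechanism: str
) -> np.ndarray:
    """Per-effect quantity vectors dotted with base prices to give payments.

    Returns an (n_effects, K) array where K is the mechanism's price
    dimension.  Row order follows ``effects``.
    """
    m = len(effects)
    if mechanism == "activity":
        area = (
            effects[["parcel_id"]]
            .merge(parcels[["parcel_id", "area_ha"]], on="parcel_id", how="left")[
                "area_ha"
            ]
            .to_numpy(dtype=float)
        )
        basis = np.zeros((m, N_OPTIONS))
        opt_idx = effects["option_id"].map(OPTION_INDEX).to_numpy()
        basis[np.arange(m), opt_idx] = area
        return basis
    if mechanism == "outcome":
        return effects[list(Q_COLS)].to_numpy(dtype=float)
    if mechanism == "es_value":
        return np.clip(effects[list(_V_PRICEABLE_COLS)].to_numpy(dtype=float), 0.0, None)
    raise ValueError(f"unknown mechanism {mechanism!r}")


def biodiversity_basis(effects: pd.DataFrame) -> np.ndarray:
    """Positive part of the prevalence-delta vectors, (n_effects, 8)."""
    return np.clip(effects[list(B_COLS)].to_numpy(dtype=float), 0.0, None)


def payment_vector(schedule: PriceSchedule, landscape: Landscape) -> np.ndarray:
    """Payment for every row of the landscape's effects table."""
    basis = payment_basis(landscape.effects, landscape.parcels, schedule.mechanism)
    pay = basis @ schedule.base_prices
    if schedule.extended:
        pay = pay + biodiversity_basis(landscape.effects) @ schedule.biodiversity_prices
    return pay


def surplus_vector(schedule: PriceSchedule, landscape: Landscape) -> np.ndarray:
    """Landowner surplus (payment minus reservation cost) per effects row."""
    cost = landscape.effects["reservation_cost"].to_numpy(dtype=float)
    return payment_vector(schedule, landscape) - cost


def payment(schedule: PriceSchedule, effect: pd.Series, parcel: pd.Series) -> float:
    """Payment due for one project under a schedule (scalar convenience API)."""
    if schedule.mechanism == "activity":
        base = schedule.base_prices[OPTION_INDEX[effect["option_id"]]] * float(
            parcel["area_ha"]
        )
    elif schedule.mechanism == "outcome":
        q = effect[list(Q_COLS)].to_numpy(dtype=float)
        base = float(schedule.base_prices @ q)
    else:  # es_value
        v = np.clip(effect[list(_V_PRICEABLE_COLS)].to_numpy(dtype=float), 0.0, None)
        base = float(schedule.base_prices @ v)
    if schedule.extended:
        b = np.clip(effect[list(B_COLS)].to_numpy(dtype=float), 0.0, None)
        base += float(schedule.biodiversity_prices @ b)
    return base


def surplus(schedule: PriceSchedule, effect: pd.Series, parcel: pd.Series) -> float:
    """Payment minus reservation cost for one project."""
    return payment(schedule, effect, parcel) - float(effect["reservation_cost"])


def zero_schedule(mechanism: str, extended: bool = False) -> PriceSchedule:
    """All-zero prices for a mechanism (useful as a degenerate baseline)."""
    bio = np.zeros(N_GROUPS) if extended else None
    return PriceSchedule(mechanism, np.zeros(_BASE_DIM[mechanism]), bio)
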