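"""Discounting arithmetic: NPVs, equivalent annuities, reservation costs.

Every monetary quantity in the scheme is a net present value at a 3.5%
annual discount rate over a 100-year horizon from the 2020 base year.
Cash flows follow an end-of-year convention: a flow in year t (t = 1..T)
is discounted by (1 + r)^-t.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np


def npv_of_series(cashflows: Sequence[float], discount_rate: float) -> float:
    """Net present value of an annual cash-flow series.

    ``cashflows[0]`` falls at the end of year 1.  An empty series has NPV 0.
    """
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    flows = np.asarray(cashflows, dtype=float)
    if flows.size == 0:
        return 0.0
    t = np.arange(1, flows.size + 1)
    return float(np.sum(flows * np.exp(-t * np.log1p(discount_rate))))


def annuity_factor(discount_rate: float, horizon_years: int) -> float:
    """Present value of a 1-pound-per-year annuity over ``horizon_years``."""
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    r = discount_rate
    # log1p/expm1 keep the factor accurate as r -> 0 (limit: T years)
    if r < 1e-14:
        return float(horizon_years)
    return -np.expm1(-horizon_years * np.log1p(r)) / r


def equivalent_annuity(
    cashflows: Sequence[float], discount_rate: float, horizon_years: int | None = None
) -> float:
    """Constant annual payment with the same present value as ``cashflows``.

    At a zero discount rate this degenerates to the arithmetic mean.  When
    ``horizon_years`` is omitted, the length of the series is used.
    """
    flows = np.asarray(cashflows, dtype=float)
    T = flows.size if horizon_years is None else int(horizon_years)
    if T < 1:
        raise ValueError("horizon must be >= 1")
    npv = npv_of_series(flows, discount_rate)
    return npv / annuity_factor(discount_rate, T)


def reservation_cost(
    foregone_income_npv: float,
    establishment_maintenance_npv: float,
    access_provision_npv: float = 0.0,
    markup: float = 0.15,
) -> float:
    """Minimum payment a landowner requires to take up an option.

    The threshold is the NPV of foregone agricultural income plus the net
    costs of establishing and maintaining the habitat (plus path/parking
    provision for access options), all marked up by the transaction-cost
    fraction (default 15%).  Foregone income may be negative (land that
    loses money under farming); the other components may not.  Accepts
    scalars or aligned arrays.
    """
    if np.any(np.asarray(establishment_maintenance_npv) < 0) or np.any(
        np.asarray(access_provision_npv) < 0
    ):
        raise ValueError("cost components must be >= 0")
    if markup < 0:
        raise ValueError("markup must be >= 0")
    base = foregone_income_npv + establishment_maintenance_npv + access_provision_npv
    return base * (1.0 + markup)
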