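"""Domain vocabulary and containers for habitat-creation incentive schemes.

The scheme offers landowners payments to convert farmland parcels to new
natural habitat.  Eight options are on the table: {semi-natural grassland,
woodland} x {public access, no access} x {converted from arable, from
pasture}.  An option is applicable to a parcel only when its prior use
matches the parcel's farm type, so each parcel faces exactly four options
(or opting out).

Each parcel x option pair carries
  * a reservation cost (the all-in payment threshold below which the
    landowner will not participate),
  * physical outcome quantities (tCO2e sequestered, nutrient reductions,
    peak-flow reduction, pollinator richness, new habitat areas),
  * monetized ecosystem-service values per channel (pounds, NPV), and
  * biodiversity deltas: the expected change in the count of
    (species, 2 km grid cell) presences for eight species groups.

All monetary amounts are NPVs in 2020 pounds over a 100-year horizon unless
stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd


class FarmType(str, Enum):
    ARABLE = "arable"
    PASTURE = "pasture"


class Habitat(str, Enum):
    SNG = "sng"  # semi-natural grassland
    WOODLAND = "woodland"


@dataclass(frozen=True)
class OptionSpec:
    """One of the eight habitat-creation options."""

    option_id: str
    habitat: Habitat
    access: bool
    prior_use: FarmType

    def applicable_to(self, farm_type: FarmType | str) -> bool:
        return self.prior_use == FarmType(farm_type)


# Fixed option order (used everywhere a per-option vector appears).
OPTIONS: tuple[OptionSpec, ...] = (
    OptionSpec("sng_access_arable", Habitat.SNG, True, FarmType.ARABLE),
    OptionSpec("sng_access_pasture", Habitat.SNG, True, FarmType.PASTURE),
    OptionSpec("woodland_access_arable", Habitat.WOODLAND, True, FarmType.ARABLE),
    OptionSpec("woodland_access_pasture", Habitat.WOODLAND, True, FarmType.PASTURE),
    OptionSpec("sng_noaccess_arable", Habitat.SNG, False, FarmType.ARABLE),
    OptionSpec("sng_noaccess_pasture", Habitat.SNG, False, FarmType.PASTURE),
    OptionSpec("woodland_noaccess_arable", Habitat.WOODLAND, False, FarmType.ARABLE),
    OptionSpec("woodland_noaccess_pasture", Habitat.WOODLAND, False, FarmType.PASTURE),
)
OPTION_IDS: tuple[str, ...] = tuple(o.option_id for o in OPTIONS)
OPTION_INDEX: dict[str, int] = {o.option_id: i for i, o in enumerate(OPTIONS)}
N_OPTIONS = len(OPTIONS)


def option(option_id: str) -> OptionSpec:
    return OPTIONS[OPTION_INDEX[option_id]]


def applicable_options(farm_type: FarmType | str) -> list[OptionSpec]:
    ft = FarmType(farm_type)
    return [o for o in OPTIONS if o.prior_use == ft]


# Physical outcome metrics (fixed order; units in comments).
OUTCOME_METRICS: tuple[str, ...] = (
    "co2e_sequestered",        # tCO2e, net of displaced-production emissions
    "phosphate_reduction",     # micrograms/litre concentration reduction
    "nitrate_reduction",       # micrograms/litre concentration reduction
    "peak_flow_reduction",     # litres/day
    "pollinator_richness",     # species richness index gain
    "accessible_woodland_ha",  # hectares of new accessible woodland
    "accessible_sng_ha",       # hectares of new accessible grassland
    "nonaccessible_ha",        # hectares of new habitat without access
)
N_METRICS = len(OUTCOME_METRICS)

# Monetized ecosystem-service value channels (fixed order, pounds NPV).
# The first seven are priceable under the payment-for-ecosystem-service-value
# mechanism; residual land production (timber/hay margins net of foregone
# food margins) counts toward aggregate value but is never priced.
VALUE_CHANNELS: tuple[str, ...] = (
    "recreation",
    "carbon",
    "water_treatment",
    "flood",
    "river_ecology",
    "pollinated_crops",
    "wildflower",
    "residual_production",
)
N_CHANNELS = len(VALUE_CHANNELS)
PRICEABLE_CHANNELS: tuple[str, ...] = VALUE_CHANNELS[:7]
N_PRICEABLE = len(PRICEABLE_CHANNELS)

SPECIES_GROUPS: tuple[str, ...] = (
    "hoverflies",
    "bees",
    "lower_plants",
    "lichen",
    "gastropods",
    "arthropods",
    "fish",
    "shellfish",
)
N_GROUPS = len(SPECIES_GROUPS)

Q_COLS = tuple(f"q_{m}" for m in OUTCOME_METRICS)
V_COLS = tuple(f"v_{c}" for c in VALUE_CHANNELS)
B_COLS = tuple(f"b_{g}" for g in SPECIES_GROUPS)

EFFECT_COLUMNS = ("parcel_id", "option_id", "reservation_cost") + Q_COLS + V_COLS + B_COLS
PARCEL_COLUMNS = ("parcel_id", "cell_id", "farm_type", "area_ha")

# Scale of the full study: number of land decision units in the England
# case and the headline public budget.
FULL_SCALE_N_PARCELS = 59_648
FULL_SCALE_BUDGET = 1e9


@dataclass
class EconomicParams:
    """Scheme-wide economic conventions.

    discount_rate
        Annual discount rate used for every NPV (default 3.5%).
    horizon_years
        Appraisal horizon, years from the base year (default 100).
    markup
        Transaction-cost mark-up applied to landowner costs when forming
        reservation costs (default 15%).
    budget
        Public budget for the scheme in pounds (default 1e9, the
        full-scale commitment; use :func:`scaled_budget` for smaller
        landscapes).
    participation_epsilon
        Strictness margin: a landowner participates only when surplus
        exceeds this (guards the "payment must exceed cost" rule against
        floating-point ties).
    """

    discount_rate: float = 0.035
    horizon_years: int = 100
    markup: float = 0.15
    budget: float = FULL_SCALE_BUDGET
    participation_epsilon: float = 1e-3
    base_year: int = 2020

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if self.markup < 0:
            raise ValueError("markup must be >= 0")
        if self.budget <= 0:
            raise ValueError("budget must be > 0")
        if self.participation_epsilon <= 0:
            raise ValueError("participation_epsilon must be > 0")


def scaled_budget(n_parcels: int, full_budget: float = FULL_SCALE_BUDGET) -> float:
    """Budget pro-rated to a landscape smaller than the full 59,648-parcel case."""
    return full_budget * n_parcels / FULL_SCALE_N_PARCELS


MECHANISMS = ("activity", "outcome", "es_value")

_PRICE_LEN = {"activity": N_OPTIONS, "outcome": N_METRICS, "es_value": N_PRICEABLE}
_PRICE_LABELS = {
    "activity": OPTION_IDS,
    "outcome": OUTCOME_METRICS,
    "es_value": PRICEABLE_CHANNELS,
}


@dataclass
class PriceSchedule:
    """A posted-price schedule under one payment mechanism.

    mechanism
        ``activity``: flat rate pounds/ha for each of the 8 options.
        ``outcome``: pounds per unit of each of the 8 outcome metrics.
        ``es_value``: pounds per pound of value delivered in each of the 7
        priceable service channels (prices may legitimately exceed 1).
    biodiversity_prices
        Optional extension: pounds per additional (species, cell) presence
        delivered, one price per species group.
    """

    mechanism: str
    base_prices: np.ndarray
    biodiversity_prices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        self.base_prices = np.asarray(self.base_prices, dtype=float)
        if self.base_prices.shape != (_PRICE_LEN[self.mechanism],):
            raise ValueError(
                f"{self.mechanism} schedule needs {_PRICE_LEN[self.mechanism]} prices, "
                f"got shape {self.base_prices.shape}"
            )
        if np.any(self.base_prices < 0):
            raise ValueError("prices must be non-negative")
        if self.biodiversity_prices is not None:
            self.biodiversity_prices = np.asarray(self.biodiversity_prices, dtype=float)
            if self.biodiversity_prices.shape != (N_GROUPS,):
                raise ValueError(f"biodiversity prices need length {N_GROUPS}")
            if np.any(self.biodiversity_prices < 0):
                raise ValueError("biodiversity prices must be non-negative")

    @property
    def extended(self) -> bool:
        return self.biodiversity_prices is not None

    @property
    def price_labels(self) -> tuple[str, ...]:
        return _PRICE_LABELS[self.mechanism]


@dataclass
class SchemeResult:
    """Evaluation of a funded assignment against the scheme's objectives."""

    assignment: pd.DataFrame  # columns: parcel_id, option_id, payment
    spend: float
    aggregate_value: float
    value_for_money: Optional[float]  # None when spend == 0 (undefined)
    channel_decomposition: pd.Series  # pounds per value channel
    biodiversity_gain: pd.Series  # presences per species group
    budget_ok: bool
    target_attainment: Optional[pd.Series] = None  # bool per group
    monte_carlo_se: Optional[float] = None

    @property
    def n_funded(self) -> int:
        return len(self.assignment)


@dataclass
class Landscape:
    """Parcels plus the full parcel x option effects table.

    ``parcels`` has columns parcel_id, cell_id, farm_type, area_ha (and,
    when generated synthetically, cell coordinates x_km / y_km).
    ``effects`` has one row per applicable parcel x option with columns
    parcel_id, option_id, reservation_cost, q_*, v_*, b_*.
    """

    parcels: pd.DataFrame
    effects: pd.DataFrame
    baseline_prevalence: pd.Series  # per species group
    config: Optional[object] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        missing = set(PARCEL_COLUMNS) - set(self.parcels.columns)
        if missing:
            raise ValueError(f"parcels table missing columns {sorted(missing)}")
        missing = set(EFFECT_COLUMNS) - set(self.effects.columns)
        if missing:
            raise ValueError(f"effects table missing columns {sorted(missing)}")
        if self.parcels["parcel_id"].duplicated().any():
            raise ValueError("duplicate parcel_id")
        if len(self.parcels) and (self.parcels["area_ha"] <= 0).any():
            raise ValueError("area_ha must be > 0")
        if len(self.effects) and (self.effects["reservation_cost"] <= 0).any():
            raise ValueError("reservation_cost must be > 0")

    @property
    def n_parcels(self) -> int:
        return len(self.parcels)

    def total_value(self) -> pd.Series:
        """Aggregate monetized value of each parcel x option (sum of channels)."""
        return self.effects[list(V_COLS)].sum(axis=1)


@dataclass
class BiodiversityTargets:
    """Required prevalence gains per species group (same units as deltas)."""

    required_gain: pd.Series  # indexed by SPECIES_GROUPS
    tau: Optional[float] = None

    def __post_init__(self) -> None:
        self.required_gain = self.required_gain.reindex(list(SPECIES_GROUPS))
        if self.required_gain.isna().any():
            raise ValueError("targets must cover all 8 species groups")
        if (self.required_gain < 0).any():
            raise ValueError("targets must be >= 0")

    @property
    def values(self) -> np.ndarray:
        return self.required_gain.to_numpy(dtype=float)
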