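"""Shared fixtures: hand-built micro-landscapes and generator defaults."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pescheme.schema import (
    B_COLS,
    EFFECT_COLUMNS,
    Q_COLS,
    SPECIES_GROUPS,
    V_COLS,
    Landscape,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,  # read-only fixtures in property tests
    ],
)
settings.load_profile("ci")


def build_landscape(parcels, effects, baseline=None) -> Landscape:
    """Construct a Landscape from terse tuples.

    parcels: (parcel_id, farm_type, area_ha)
    effects: (parcel_id, option_id, reservation_cost, value, quantities, bio)
        where ``value`` is a scalar (placed in the carbon channel) or a
        dict {channel: pounds}; ``quantities`` and ``bio`` are optional
        dicts {metric: qty} / {group: delta}.
    """
    ptab = pd.DataFrame(
        {
            "parcel_id": [p[0] for p in parcels],
            "cell_id": [f"cell_{i}" for i in range(len(parcels))],
            "farm_type": [p[1] for p in parcels],
            "area_ha": [float(p[2]) for p in parcels],
        }
    )
    rows = []
    for entry in effects:
        pid, opt, cost, value = entry[0], entry[1], float(entry[2]), entry[3]
        quantities = entry[4] if len(entry) > 4 and entry[4] else {}
        bio = entry[5] if len(entry) > 5 and entry[5] else {}
        row = {c: 0.0 for c in EFFECT_COLUMNS}
        row["parcel_id"], row["option_id"], row["reservation_cost"] = pid, opt, cost
        if isinstance(value, dict):
            for ch, val in value.items():
                row[f"v_{ch}"] = float(val)
        else:
            row["v_carbon"] = float(value)
        for metric, qty in quantities.items():
            row[f"q_{metric}"] = float(qty)
        for grp, delta in bio.items():
            row[f"b_{grp}"] = float(delta)
        rows.append(row)
    etab = pd.DataFrame(rows, columns=list(EFFECT_COLUMNS))
    if baseline is None:
        baseline = pd.Series(100.0, index=list(SPECIES_GROUPS))
    return Landscape(ptab, etab, baseline)


@pytest.fixture
def three_parcel_flat():
    """Single option, 1 ha parcels, per-ha costs {100, 200, 320}, values
    {150, 400, 260}: the canonical breakpoint-pricing example."""
    return build_landscape(
        parcels=[("p1", "arable", 1.0), ("p2", "arable", 1.0), ("p3", "arable", 1.0)],
        effects=[
            ("p1", "sng_access_arable", 100.0, 150.0),
            ("p2", "sng_access_arable", 200.0, 400.0),
            ("p3", "sng_access_arable", 320.0, 260.0),
        ],
    )


@pytest.fixture
def mechanism_infeasibility_fixture():
    """Targets reachable by direct selection but by no posted price.

    One flat-priced option.  P1: cost 100, value 500, no biodiversity.
    P2: cost 300, value 10, 5 presences of lichen.  Budget 350, lichen
    target 5.  Any price enrolling P2 (>= 300) also enrols P1 and spends
    >= 600; selecting P2 alone costs 300 and meets the target.
    """
    return build_landscape(
        parcels=[("p1", "arable", 1.0), ("p2", "arable", 1.0)],
        effects=[
            ("p1", "sng_access_arable", 100.0, 500.0),
            ("p2", "sng_access_arable", 300.0, 10.0, None, {"lichen": 5.0}),
        ],
    )


@pytest.fixture(scope="session")
def small_default_landscape():
    """A seeded generator landscape shared across read-only tests."""
    from pescheme import LandscapeConfig, generate_landscape

    return generate_landscape(LandscapeConfig(n_parcels=120), seed=42)
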