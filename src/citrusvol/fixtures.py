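"""Field-trial reference tables shipped with the package.

Four tables from the 2015–2016 evaluation campaign in seven commercial
Clementine orchards in Valencia are transcribed verbatim as CSV files:

* T3 — orchard characteristics (spacing, canopy dimensions, apparent volume)
* T4 — sprayer set-up per application
* T5 — volume rates, reductions and product savings per application
* T6 — tank counts and refill-time savings per application

``*_printed`` columns hold the values exactly as published, including two
rows whose printed reduction disagrees with the recomputed one (orchard P6
on 12 Aug prints 20.81% where the volume rates give ≈50.9%, and P2 on
09 Sep prints 22.28% where they give ≈22.99%); they are preserved, not
corrected, and tests flag the discrepancy.  Dates are kept per-table as
published (P6's first application prints 13 June in T5 but 16 June in
T4/T6).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DatabaseError
from .savings import ApplicationRecord, Ingredient

_FILES = {
    "T3": "table3_orchards.csv",
    "T4": "table4_sprayer_setup.csv",
    "T5": "table5_applications.csv",
    "T6": "table6_refill_times.csv",
}

_SCHEMAS = {
    "T3": (
        ["orchard_id", "cultivar", "sp_row", "sp_tree", "h", "d_across",
         "d_along", "vt1_printed"],
        7,
    ),
    "T4": (
        ["orchard_id", "date", "pest", "pressure_bar", "forward_speed_kmh",
         "air_volume_m3h", "nozzles_vc", "nozzles_va"],
        14,
    ),
    "T5": (
        ["orchard_id", "date", "pest", "ingredient", "concentration_pct",
         "vc", "va", "reduction_printed", "savings_printed"],
        36,
    ),
    "T6": (
        ["orchard_id", "date", "tank_capacity", "tanks_vc", "tanks_va",
         "savings_h_1ha", "savings_h_10ha", "savings_h_100ha"],
        14,
    ),
}


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load one of the trial tables (``"T3"``–``"T6"``), schema-validated."""
    table_id = table_id.upper()
    if table_id not in _FILES:
        raise DatabaseError(
            f"unknown fixture {table_id!r}; available: {sorted(_FILES)}"
        )
    path = Path(str(resources.files("citrusvol").joinpath(
        "data", "fixtures", _FILES[table_id]
    )))
    df = pd.read_csv(path, dtype={"orchard_id": str})
    columns, nrows = _SCHEMAS[table_id]
    if list(df.columns) != columns:
        raise DatabaseError(
            f"fixture {table_id} columns {list(df.columns)} != expected {columns}"
        )
    if len(df) != nrows:
        raise DatabaseError(f"fixture {table_id} has {len(df)} rows, expected {nrows}")
    if df.isna().any().any():
        raise DatabaseError(f"fixture {table_id} contains missing values")
    return df


def application_records() -> list[ApplicationRecord]:
    """The 14 trial applications as :class:`ApplicationRecord` objects.

    Volume rates and ingredient concentrations come from T5; tank
    capacities are joined in from T6 by orchard (capacity is constant per
    orchard, so the date discrepancy between the tables does not matter).
    """
    t5 = load_fixture("T5")
    t6 = load_fixture("T6")
    capacity = t6.drop_duplicates("orchard_id").set_index("orchard_id")[
        "tank_capacity"
    ]
    records = []
    for (orchard, date, pest), grp in t5.groupby(
        ["orchard_id", "date", "pest"], sort=False
    ):
        vc, va = float(grp["vc"].iloc[0]), float(grp["va"].iloc[0])
        ingredients = tuple(
            Ingredient(name=r.ingredient, concentration_pct=float(r.concentration_pct))
            for r in grp.itertuples()
        )
        records.append(
            ApplicationRecord(
                orchard_id=orchard,
                date=date,
                pest=pest,
                vc=vc,
                va=va,
                tank_capacity=float(capacity[orchard]),
                ingredients=ingredients,
            )
        )
    if len(records) != 14:
        raise DatabaseError(f"expected 14 applications, built {len(records)}")
    return records
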