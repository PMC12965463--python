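"""Plant-level analysis dataset built from generator-level records.

Mirrors the EIA-860 workflow: plants are aggregates of generators; the
plant's first operation date is the earliest generator start, a plant is
retired only when all its generators have retired (retirement date = last
generator to retire), the primary fuel is the fuel holding the majority of
nameplate capacity with a fixed tie-break priority, and peaker status is
derived from fuel and prime-mover composition.  Inclusion rules restrict the
registry to fossil plants (with a biomass exception in the pre-1940
baseline) and drop plants retired before 1939 from the baseline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FOSSIL_FUELS",
    "FUEL_PRIORITY",
    "PERIODS",
    "derive_first_operation",
    "derive_retirement",
    "classify_primary_fuel",
    "flag_peaker",
    "assign_period",
    "build_plant_registry",
    "apply_inclusion_rules",
    "attach_emissions",
]

FOSSIL_FUELS = ("coal", "petroleum", "natural_gas")

#: Tie-break priority for equal capacity shares: coal, petroleum products,
#: natural gas, then any other energy source (fixed order for determinism).
FUEL_PRIORITY = (
    "coal",
    "petroleum",
    "natural_gas",
    "biomass_liquid_solid",
    "nuclear",
    "other_renewable",
    "other",
)

PERIODS = ("pre1940", "1940_1969", "1970_1999", "2000_2019")

POLLUTANTS = ("nox_tons", "so2_tons", "pm25_tons")


def derive_first_operation(generators: pd.DataFrame) -> int:
    """Earliest first_operation_year across a plant's generators."""
    if len(generators) == 0:
        raise ValueError("plant has no generators")
    return int(generators["first_operation_year"].min())


def derive_retirement(generators: pd.DataFrame):
    """Plant retirement year: max generator retirement, or None while any
    generator remains operable (no retirement year)."""
    if len(generators) == 0:
        raise ValueError("plant has no generators")
    ret = generators["retirement_year"]
    if ret.isna().any():
        return None
    return int(ret.max())


def classify_primary_fuel(generators: pd.DataFrame) -> str:
    """Fuel reported for the majority of the plant's nameplate capacity.

    Exact capacity ties are broken by ``FUEL_PRIORITY``.  If every generator
    has zero capacity the fuels tie at equal (zero) shares and the priority
    order decides, with a log record.
    """
    if len(generators) == 0:
        raise ValueError("plant has no generators")
    shares = generators.groupby("energy_source")["nameplate_capacity_mw"].sum()
    if shares.sum() == 0:
        logger.warning(
            "plant %s: all generator capacities zero; primary fuel by priority order",
            generators["plant_id"].iloc[0] if "plant_id" in generators else "?",
        )
        candidates = list(shares.index)
    else:
        top = shares.max()
        candidates = list(shares[shares == top].index)
    return min(candidates, key=FUEL_PRIORITY.index)


def flag_peaker(generators: pd.DataFrame, primary_fuel: str) -> bool:
    """True for plants primarily burning oil, and for combustion-turbine
    plants primarily burning natural gas (majority of capacity is CT;
    an exact 50/50 prime-mover split is not a peaker)."""
    if primary_fuel == "petroleum":
        return True
    if primary_fuel != "natural_gas":
        return False
    total = generators["nameplate_capacity_mw"].sum()
    if total == 0:
        return False
    ct = generators.loc[
        generators["prime_mover"] == "combustion_turbine", "nameplate_capacity_mw"
    ].sum()
    return bool(ct > 0.5 * total)


def assign_period(first_operation_year: int) -> str:
    """Map a first-operation year onto the four analysis periods."""
    year = int(first_operation_year)
    if year < 1850:
        raise ValueError(f"implausible first operation year {year}")
    if year > 2019:
        raise ValueError(f"first operation year {year} beyond the 2019 study snapshot")
    if year <= 1939:
        return "pre1940"
    if year <= 1969:
        return "1940_1969"
    if year <= 1999:
        return "1970_1999"
    return "2000_2019"


def _aggregate_plant(gens: pd.DataFrame) -> dict:
    first_op = derive_first_operation(gens)
    retirement = derive_retirement(gens)
    fuel = classify_primary_fuel(gens)
    return {
        "first_operation_year": first_op,
        "retirement_year": np.nan if retirement is None else retirement,
        "primary_energy_source": fuel,
        "total_nameplate_mw": gens["nameplate_capacity_mw"].sum(),
        "is_peaker": flag_peaker(gens, fuel),
        "period": assign_period(first_op),
        "operable_2019": retirement is None or retirement >= 2019,
    }


def build_plant_registry(
    generators: pd.DataFrame, locations: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate generator rows into one registry row per plant.

    ``generators`` needs columns plant_id, nameplate_capacity_mw,
    energy_source, prime_mover, first_operation_year, retirement_year
    (NaN while operable).  ``locations`` maps plant_id to planar x, y (and
    optionally state).  Inclusion flags are added by
    :func:`apply_inclusion_rules`.
    """
    required = {
        "plant_id",
        "nameplate_capacity_mw",
        "energy_source",
        "prime_mover",
        "first_operation_year",
        "retirement_year",
    }
    missing = required - set(generators.columns)
    if missing:
        raise ValueError(f"generator table missing columns: {sorted(missing)}")
    if (generators["nameplate_capacity_mw"] < 0).any():
        raise ValueError("negative nameplate capacity")

    records = []
    for plant_id, gens in generators.groupby("plant_id", sort=True):
        rec = _aggregate_plant(gens)
        rec["plant_id"] = plant_id
        records.append(rec)
    plants = pd.DataFrame.from_records(records)

    loc_cols = ["plant_id", "x", "y"] + (["state"] if "state" in locations else [])
    plants = plants.merge(locations[loc_cols], on="plant_id", how="left", validate="1:1")
    if plants["x"].isna().any():
        bad = plants.loc[plants["x"].isna(), "plant_id"].tolist()
        raise ValueError(f"plants missing locations: {bad[:5]}")
    return apply_inclusion_rules(plants)


def apply_inclusion_rules(plants: pd.DataFrame, drop_states=("AK", "HI", "PR")) -> pd.DataFrame:
    """Flag each plant as included or excluded-with-reason.

    Rules: non-fossil primary fuel excluded, except biomass plants in the
    pre-1940 baseline; plants retired before 1939 excluded from the
    baseline; plants in Alaska, Hawaii or Puerto Rico excluded when a state
    column is present.  Post-1940 plants are retained irrespective of
    retirement date.  No plant is silently dropped.
    """
    plants = plants.copy()
    reasons = pd.Series("", index=plants.index, dtype=object)

    if "state" in plants.columns:
        geo = plants["state"].isin(drop_states)
        reasons[geo] = "excluded_geography"

    fossil = plants["primary_energy_source"].isin(FOSSIL_FUELS)
    baseline_biomass = (plants["primary_energy_source"] == "biomass_liquid_solid") & (
        plants["period"] == "pre1940"
    )
    nonfossil = ~fossil & ~baseline_biomass
    reasons[nonfossil & (reasons == "")] = "non_fossil_fuel"

    early_retired = (plants["period"] == "pre1940") & (plants["retirement_year"] < 1939)
    reasons[early_retired & (reasons == "")] = "retired_before_1939"

    plants["included"] = reasons == ""
    plants["exclusion_reason"] = reasons
    n_exc = int((~plants["included"]).sum())
    if n_exc:
        logger.info(
            "excluded %d plants: %s",
            n_exc,
            plants.loc[~plants["included"], "exclusion_reason"].value_counts().to_dict(),
        )
    return plants


def attach_emissions(plants: pd.DataFrame, emissions: pd.DataFrame) -> pd.DataFrame:
    """Attach 2019 NOx/SO2 and 2018 PM2.5 annual tons to operable plants.

    Missing pollutant values — including plants absent from the emissions
    table entirely — are set to zero with a logged count.  Plants not
    operable in 2019 carry NaN burdens (they contribute to siting outcomes
    only).  Duplicate plant ids in the emissions table are an error.
    """
    if emissions["plant_id"].duplicated().any():
        dupes = emissions.loc[emissions["plant_id"].duplicated(), "plant_id"].tolist()
        raise ValueError(f"duplicate plant ids in emissions table: {dupes[:5]}")
    if (emissions[list(POLLUTANTS)] < 0).any().any():
        raise ValueError("negative emissions values")

    out = plants.merge(
        emissions[["plant_id", *POLLUTANTS]], on="plant_id", how="left", validate="1:1"
    )
    operable = out["operable_2019"].to_numpy(dtype=bool)
    n_zeroed = {p: int(out.loc[operable, p].isna().sum()) for p in POLLUTANTS}
    if any(n_zeroed.values()):
        logger.info("zero-imputed missing emissions (operable plants): %s", n_zeroed)
    for p in POLLUTANTS:
        vals = out[p].fillna(0.0)
        vals[~operable] = np.nan
        out[p] = vals
    return out
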