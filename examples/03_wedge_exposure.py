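"""Wind-directed wedge exposure on a three-neighbourhood toy world.

A plant 2 km west of a neighbourhood, with wind blowing towards the east,
exposes that neighbourhood through the E-wedge of its 5 km buffer; the
other neighbourhoods are out of reach.
"""

import pandas as pd
from shapely.geometry import box

from redwind import build_exposure_table, downwind_wedge, is_exposed

areas = pd.DataFrame(
    {
        "area_id": ["west", "middle", "east"],
        "grade": ["C", "D", "C"],
        "geometry": [
            box(-30_000, 0, -20_000, 10_000),
            box(0, 0, 10_000, 10_000),
            box(30_000, 0, 40_000, 10_000),
        ],
    }
)
registry = pd.DataFrame(
    {
        "plant_id": ["P1"], "x": [-2000.0], "y": [5000.0],
        "period": ["1940_1969"], "primary_energy_source": ["coal"],
        "is_peaker": [False], "operable_2019": [True], "included": [True],
        "nox_tons": [120.0], "so2_tons": [45.0], "pm25_tons": [8.0],
    }
)
wind = pd.DataFrame({"plant_id": ["P1"], "predominant_direction": ["E"]})

wedge = downwind_wedge((-2000.0, 5000.0), "E", 5000.0)
print("wedge area (quarter disc of 5 km):", round(wedge.area / 1e6, 2), "km^2")
for _, area in areas.iterrows():
    print(f"  {area.area_id:>6} exposed:", is_exposed(area.geometry, wedge))

table = build_exposure_table(areas, registry, wind, radius_km=5.0)
cols = ["area_id", "any_fossil_1940_1969", "n_fossil_1940_1969", "nox_burden"]
print(table[cols].to_string(index=False))
# only "middle" is downwind and within 5 km, so it carries the single
# 1940-1969 coal plant and its full 120 t/yr NOx burden.
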