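"""Generator-to-plant aggregation rules on a hand-built EIA-860-like table.

A plant's first operation date is its earliest generator start; it is
retired only when every generator has retired; its primary fuel holds the
majority of nameplate capacity (capacity ties broken coal > petroleum >
natural gas > other); oil plants and gas combustion turbines are peakers.
"""

import numpy as np
import pandas as pd

from redwind import (
    assign_period,
    classify_primary_fuel,
    derive_first_operation,
    derive_retirement,
    flag_peaker,
)

plant = pd.DataFrame(
    {
        "plant_id": ["P1"] * 3,
        "nameplate_capacity_mw": [50.0, 50.0, 50.0],
        "energy_source": ["coal", "coal", "petroleum"],
        "prime_mover": ["steam", "steam", "steam"],
        "first_operation_year": [1955, 1948, 1972],
        "retirement_year": [1990.0, 2005.0, np.nan],
    }
)

first = derive_first_operation(plant)
fuel = classify_primary_fuel(plant)
print("first operation:", first, "->", assign_period(first), "period")
print("retirement:", derive_retirement(plant), "(one generator still operable)")
print("primary fuel:", fuel, "(two of three equal-capacity generators burn coal)")
print("peaker:", flag_peaker(plant, fuel))

# the 50/50 capacity tie is decided by the fixed fuel priority order
tie = pd.DataFrame(
    {
        "plant_id": ["P2"] * 2,
        "nameplate_capacity_mw": [80.0, 80.0],
        "energy_source": ["natural_gas", "coal"],
        "prime_mover": ["combustion_turbine", "steam"],
        "first_operation_year": [1960, 1960],
        "retirement_year": [np.nan, np.nan],
    }
)
print("50/50 coal vs natural gas ->", classify_primary_fuel(tie))
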