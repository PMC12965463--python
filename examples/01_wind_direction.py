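"""Leeward angles and predominant wind direction from monthly u/v winds.

The leeward angle is the direction the wind blows *towards*: atan2(v, u) in
degrees, binned into N/E/S/W quadrants; the mode over twelve months defines
the predominant direction at a location.
"""

from redwind import categorize_direction, leeward_angle, predominant_direction, wind_speed

# one year of monthly (u, v) components, m/s, at a single site:
# mostly westerly flow (wind blowing towards the east) with two northerly months
months = [
    (3.1, 0.4), (2.8, -0.2), (3.5, 0.9), (0.4, 3.2), (2.9, 0.1), (3.3, -0.5),
    (2.2, 0.3), (0.2, 2.9), (3.0, 0.0), (2.7, 0.6), (3.4, -0.1), (2.5, 0.2),
]

for u, v in months[:4]:
    ang = leeward_angle(u, v)
    print(
        f"u={u:+.1f} v={v:+.1f}  speed={wind_speed(u, v):4.2f} m/s  "
        f"leeward angle={ang:6.1f} deg  sector={categorize_direction(ang)}"
    )

print("predominant direction over 12 months:", predominant_direction(months))
# 10 of 12 months blow towards the east, so the modal sector - and the
# direction used to pick each plant's downwind wedge - is E.
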