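"""Compute heat-stress indices for a year of daily weather.

Builds one deterministic year of Mediterranean-type weather, derives the
THI (temperature-humidity) and THIWS (wind- and radiation-adjusted)
indices, and prints the July climatology and the index quantiles used as
low/median/high stress scenarios.
"""

import deerheat as dh

weather = dh.add_indices(dh.generate_weather(2005, 1, seed=0, noise_scale=0.0))
july = weather[weather["date"].dt.month == 7]

print("July means:")
print(july[["t_mean", "hr", "wind", "solar", "thi", "thiws"]].mean().round(2))

summer = weather[weather["date"].dt.month.isin([6, 7, 8, 9])]
q_thi = dh.index_quantiles(summer["thi"], [0.1, 0.5, 0.9])
print("\nTHI stress scenarios (0.1/0.5/0.9 quantiles over summer days):")
print(q_thi.round(1))
# The three quantiles bracket low, typical and high heat stress; a THI
# in the low 70s marks the hottest conditions a late-summer calf meets.
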