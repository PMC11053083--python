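"""Assess collective heat exposure for one synthetic day at one corner.

Generates a day of 30-second temperature/humidity samples and hourly
pedestrian counts, bins both onto the hourly grid, and prints the
per-hour temperature-humidity index (THI), its risk band, and the
collective index CTHI = THI x passersby.
"""

import pandas as pd

from heattwin import (
    CountGenConfig,
    MeteoGenConfig,
    exposure_table,
    gen_counts,
    gen_meteo,
    resample_meteo,
)

samples = gen_meteo(MeteoGenConfig(location_id="11th"), days=1, seed=3)
counts = gen_counts(CountGenConfig(location_id="11th"), days=1, seed=3)
meteo = resample_meteo(samples, pd.Timedelta(hours=1))

table = exposure_table(meteo, counts)
print(table[["thi", "level", "count", "cthi"]].iloc[10:16].round(1))
print()
peak = table["cthi"].idxmax()
print(f"peak collective exposure at {peak:%H:%M}: "
      f"CTHI {table.loc[peak, 'cthi']:.0f} person-degF "
      f"({table.loc[peak, 'count']:.0f} people at THI {table.loc[peak, 'thi']:.1f})")
# The THI column is the heat-stress index in degF; CTHI weights it by how
# many people were actually exposed in that hour.
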