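"""Detect emigration from the natal territory by recursion analysis.

An animal is dispersed once it spends more than 14 consecutive days without
any fix inside a 7 km radius of its nest; the emigration instant anchors at
the last inside-radius fix before that absence.
"""

import numpy as np
import pandas as pd

from flyscape import detect_emigration

rows = []
t0 = pd.Timestamp("2021-03-01 06:00")
positions = [(1000.0, 0.0)] * 100 + [(45_000.0, 8000.0)] * 10 + [(1500.0, 500.0)] * 40 \
    + [(60_000.0, -20_000.0)] * 60
for day, (x, y) in enumerate(positions):
    for k in range(6):
        rows.append(("eagle01", t0 + pd.Timedelta(days=day, hours=2 * k), x, y))
track = pd.DataFrame(rows, columns=["individual_id", "timestamp", "x", "y"])

res = detect_emigration(track, nest=(0.0, 0.0), radius_m=7000.0, min_days=14.0)
print(f"status: {res.status}")
print(f"emigration: {res.emigration_time}  (the 10-day excursion at day 100 is a feint)")
weeks = res.week_of(track["timestamp"])
print(f"weeks since emigration span 1..{int(np.nanmax(weeks))} over the remaining track")
# Week-since-emigration becomes the ontogenetic covariate of the
# step-selection model: it indexes the bird's flight experience.
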