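"""Flight stability with and without visual cues.

Compares per-individual mean absolute heading change per second (the
turn-rate stability metric) and individual directedness r between an
oriented control cohort and a cohort flying without usable visual cues,
using rank-sum tests with Benjamini-Hochberg correction.
"""

import numpy as np
import pandas as pd

from tetherflight import (
    compare_groups,
    individual_vector_from_angles,
    mean_abs_turn_rate,
    scenario_preset,
    simulate_cohort,
)

rows = []
for preset in ("fall_control", "no_visual_cues"):
    scenario = scenario_preset(preset, n_individuals=20, seed=8)
    tracks, _ = simulate_cohort(scenario)
    for tr in tracks:
        rows.append(
            {
                "group": preset,
                "individual_id": tr.individual_id,
                "turn_deg_per_s": mean_abs_turn_rate(tr).mean_abs_turn,
                "r": individual_vector_from_angles(tr.azimuth_deg, tr.individual_id, "t").r,
            }
        )
df = pd.DataFrame.from_records(rows)

for metric in ("turn_deg_per_s", "r"):
    med = df.groupby("group")[metric].median()
    table = df.rename(columns={metric: "value"})[["group", "individual_id", "value"]]
    res = compare_groups(table, [("fall_control", "no_visual_cues", False)])
    row = res.table.iloc[0]
    print(f"{metric}: median control = {med['fall_control']:.3f}, "
          f"no cues = {med['no_visual_cues']:.3f}; "
          f"rank-sum p_adj = {row.p_adj:.2e}; letters {res.letters}")
print(
    "\nWithout visual cues the turn rate is several times higher and the\n"
    "directedness collapses: unstable flight, not a stable-but-random heading."
)
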