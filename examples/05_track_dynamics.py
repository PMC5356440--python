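"""Comet dynamics: recover growth speed and pause behaviour from tracks.

Simulated two-state trajectories (growth at 12 µm/min, pause) are split at
bends > 30°, classified into growth/pause events by a speed-threshold
run-length rule, and summarized per cell; the four speed groups are capped
at vmax = mean + 1 SD of the fastest cell.
"""

import pandas as pd

from mtcortex import (dynamics_summary, events_table, segment_events,
                      speed_groups, split_on_bend)
from mtcortex import synthetic as sy

tracks = []
for seed, (treatment, v) in enumerate([("control", 12.0),
                                       ("rac1_inhibited", 6.0)]):
    tracks += sy.simulate_dynamic_tracks(
        200, v_growth=v, v_sd=2.0, p_gp=0.1, p_pg=0.3,
        cell_id=f"cell_{treatment}", treatment=treatment, seed=seed)

split = [frag for t in tracks for frag in split_on_bend(t, theta_max=30.0)]
events = [segment_events(t, pause_speed_max=1.5, min_pause_frames=2)
          for t in split]
per_cell, per_treatment = dynamics_summary(split, events)
print(per_treatment[["treatment", "mean_growth_speed_um_min",
                     "mean_growth_length_um", "pct_events_pausing"]]
      .round(2).to_string(index=False))

growth = events_table(split, events).query("state == 'growth'")
tables = speed_groups(growth.rename(columns={"mean_speed_um_min": "speed"})[
    ["cell_id", "treatment", "speed"]])
print(f"\nvmax = {tables['control'].vmax:.1f} µm/min "
      "(fastest cell mean + 1 SD); speed-group shares (%):")
for name, tab in tables.items():
    shares = ", ".join(f"{lab} {pct:.0f}" for lab, pct in
                       zip(tab.labels, tab.percentages))
    print(f"  {name}: {shares}")
# Slowing growth shifts mass into the very-slow bin while the recovered
# control speed sits near the simulated 12 µm/min.
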