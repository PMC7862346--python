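"""Simulate a synthetic resting-state cohort with planted CAP dynamics.

Builds the default 8 WT + 10 TG cohort (32x16 grid, 600 frames at
TR 0.5 s, 7 recurring co-(de)activation states) and prints what was
planted: state occupancies and dwell structure per group.
"""

import numpy as np

from capstate import SimulationConfig, simulate_cohort
from capstate.config import Group

config = SimulationConfig(seed=1)
cohort = simulate_cohort(config)

print(f"cohort: {len(cohort)} subjects "
      f"({sum(r.group == Group.WT for r in cohort)} WT, "
      f"{sum(r.group == Group.TG for r in cohort)} TG)")
print(f"grid {config.grid_rows}x{config.grid_cols}, "
      f"{cohort[0].n_voxels} in-mask voxels, "
      f"{cohort[0].n_frames} frames at TR {config.tr_seconds} s\n")

for group in (Group.WT, Group.TG):
    recs = [r for r in cohort if r.group == group]
    pooled = np.concatenate([r.true_state_sequence for r in recs])
    occ = np.bincount(pooled, minlength=config.n_states) / pooled.size
    runs = []
    for r in recs:
        seq = r.true_state_sequence
        change = np.flatnonzero(np.diff(seq) != 0)
        runs.append(np.diff(np.concatenate([[0], change + 1, [seq.size]])))
    print(f"{group.value}: empirical state occupancies {np.round(occ, 3)}")
    print(f"    mean dwell {np.concatenate(runs).mean():.1f} frames "
          f"(configured {config.dwell_mean_frames})")

# The occupancies follow the configured geometric grading (dominant states
# recur more often) and dwell times average the configured mean, i.e. the
# hidden Markov dynamics downstream metrics assume are really in the data.
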