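"""Overlap between QPP occurrence windows and CAP labels.

Quasi-periodic patterns (QPPs) are recurring 3-second (6-frame)
spatiotemporal templates whose occurrence windows are consumed as input.
Here windows are synthesized around one planted state and each CAP's
incidence inside them is computed under both normalizations.
"""

import numpy as np

from capstate import SimulationConfig, make_qpp_windows, simulate_cohort
from capstate.metrics import average_caps_incidence, qpp_cap_incidence

config = SimulationConfig(seed=1)
rec = simulate_cohort(config)[0]
target = 0  # pretend the QPP rides on the dominant planted state

windows = make_qpp_windows(rec, target_state=target, window_len_frames=6)
print(f"subject {rec.subject_id}: {len(windows)} non-overlapping 6-frame windows "
      f"anchored on state {target + 1}")

per_qpp = qpp_cap_incidence(rec.true_state_sequence, windows, config.n_states)
per_total = qpp_cap_incidence(
    rec.true_state_sequence, windows, config.n_states, "per_total_frames"
)
print(f"incidence inside QPP windows (% of window frames): {np.round(per_qpp, 1)}"
      f"  (sums to {per_qpp.sum():.0f}%)")
print(f"incidence relative to whole scan (% of all frames): {np.round(per_total, 1)}")
print(f"mean incidence of CAPs 2+3 for this subject: "
      f"{average_caps_incidence(per_qpp, [1, 2]):.1f}%")

# The window-anchored CAP dominates the per-QPP-normalized incidences, as a
# QPP that rides on one co-activation state should; the per-scan
# normalization instead measures how much of the scan that overlap covers.
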