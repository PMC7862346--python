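"""Extract CAPs from a conditioned cohort and pick K by the elbow rule.

Runs the full conditioning chain, computes per-group explained-variance
curves for k = 2..10, applies the two-group fractional-gain elbow rule,
and prints the matched CAP pairs at the chosen K.
"""

import numpy as np

from capstate import GroupImageSeries, SimulationConfig, detect_elbow, ev_curve
from capstate.studies import extract_matched_caps, prepare_cohort, split_groups

config = SimulationConfig(seed=1)
cohort = prepare_cohort(config)
wt, tg = split_groups(cohort)

curves = []
for recs, tag in ((wt, "WT"), (tg, "TG")):
    series = GroupImageSeries.from_recordings(recs, group=tag)
    curve = ev_curve(series, 2, 10, seed=1, n_restarts=3)
    curves.append(curve)
    ev = np.array([c.explained for c in curve])
    gains = 100 * np.diff(ev) / ev[:-1]
    print(f"{tag}: EV(k=2..10) = {np.round(ev, 3)}")
    print(f"    fractional gains (%) = {np.round(gains, 1)}")

elbow = detect_elbow(curves)
print(f"\nelbow: first k with <10% gain in both groups -> K = {elbow.k} "
      f"(planted: {config.n_states})")

extraction = extract_matched_caps(cohort, elbow.k, seed=1)
print("\nHungarian-matched WT-TG CAP pairs (Pearson r of mean maps):")
for (i, j), r in zip(extraction.match.pairs, extraction.match.pair_correlations):
    kept = "kept" if r >= 0.5 else "dropped (r < 0.5)"
    print(f"  WT CAP {i + 1} <-> TG CAP {j + 1}:  r = {r:.2f}  [{kept}]")

# The explained variance rises while real structure is being resolved and
# saturates at the planted state count; matched pairs correlate strongly
# because both groups share the same underlying spatial states.
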