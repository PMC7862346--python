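"""Subject-level CAP metrics and the WT-vs-TG group comparison.

Uses the strong-effect preset (TG positive activation shifted rightward,
dominant state boosted), computes occurrence, duration and hemispheric
laterality per subject and CAP, and runs the rank-sum + BH-FDR
comparison over the matched pairs.
"""

import numpy as np

from capstate import SimulationConfig
from capstate.group_stats import compare_partition
from capstate.studies import (
    cohort_metric_tables,
    extract_matched_caps,
    prepare_cohort,
)

config = SimulationConfig.strong_effect(seed=1)
cohort = prepare_cohort(config)
k = config.n_states
extraction = extract_matched_caps(cohort, k, seed=1)
tables_wt, tables_tg = cohort_metric_tables(cohort, extraction, k)

lat_wt = np.nanmedian(np.array([t["laterality_pos"] for t in tables_wt]), axis=0)
lat_tg = np.nanmedian(np.array([t["laterality_pos"] for t in tables_tg]), axis=0)
print("median positive-activation laterality per CAP")
print("  WT:", np.round(lat_wt, 3))
print("  TG:", np.round(lat_tg, 3))
print("  (negative = right-lateralized; the TG shift pushes activation right)\n")

comparisons = compare_partition(tables_wt, tables_tg, extraction.match, k)
print(f"{len(comparisons)} comparisons (retained pairs x metrics), "
      f"BH-FDR per metric within the partition:")
for c in comparisons:
    if c.significant:
        print(f"  SIGNIFICANT  {c.metric:<14} WT CAP {c.pair[0] + 1} vs TG CAP "
              f"{c.pair[1] + 1}: medians {c.median_wt:+.3f} / {c.median_tg:+.3f}, "
              f"p_adj = {c.p_adjusted:.4f}")

# With the planted rightward shift, laterality of co-activations is the
# metric that separates the groups, mirroring how spatial CAP properties
# carry the disease signature while occurrence/duration differ little.
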