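# capstate

Co-activation pattern (CAP) analysis of resting-state fMRI frame series,
built for the question of whether transient brain states separate
amyloidosis-model (TG2576) mice from wild-type littermates. The package
implements the full frame-wise pipeline — simulation of test cohorts,
signal conditioning, correlation-distance clustering with
explained-variance model selection, between-group CAP matching,
temporal/spatial CAP statistics, and supervised disease-state
classification — as an importable Python library with a thin CLI.

It is aimed at researchers analyzing single-slice rodent resting-state
BOLD recordings (or anyone who wants a tested, reproducible CAP
implementation), and ships a synthetic-cohort generator with planted
state dynamics so every stage can be validated without access to animal
data.

## The method

Every time frame of a group-level image-series is treated as one
observation `z_j` (a V-voxel map). Frames are clustered with k-means++
under correlation distance `d(z, c) = 1 − r(z, c)` (Pearson), realized
by centering each frame at its spatial mean, scaling to unit norm, and
running Lloyd iterations (squared Euclidean distance between such
normalized maps equals `2 d`). The number of clusters K is chosen by an
explained-variance elbow: with cluster means `c_k`, sizes `n_k` and
grand mean `c = Σ (n_k/N) c_k`,

    V_W = (1/N) Σ_k Σ_{j∈k} d²(z_j, c_k)        (within-cluster)
    V_B = Σ_k (n_k/N) d²(c_k, c)                (between-cluster)
    EV  = V_B / (V_W + V_B)

evaluated in the normalized-map geometry, where `V_W + V_B` equals the
total variance exactly; K is the smallest k ≥ 3 whose fractional EV gain
`(EV(k) − EV(k−1))/EV(k−1)` drops below 10% in **both** groups.

Cluster frames are voxel-averaged into CAPs and tested voxel-wise
against zero (two-tailed one-sample T, Bonferroni over in-mask voxels).
WT and TG CAPs are paired by the Hungarian method on `1 − r` and pairs
below a 10,000-shuffle surrogate correlation threshold are dropped. Per
subject and CAP the pipeline computes the occurrence fraction, mean
duration (frames), and a hemispheric laterality index over significant
voxels of one sign,

    LI = (⟨T⟩_left − ⟨T⟩_right) / ⟨T⟩_brain  ∈ [−1, +1],

compared between groups with two-sample rank-sum tests under
Benjamini–Hochberg FDR within each partition. Classification uses
L2-regularized logistic regression over repeated random 14/4
train/validation splits, with features that are either temporal
(occurrence + duration per matched pair), spatial (subject mean BOLD at
significant-voxel unions), or voxel variances as a control; a
training-set-only scheme re-extracts CAPs from training animals each
trial and represents every subject by correlation-peak-seeded projected
WT-like/TG-like CAPs, so validation animals never influence CAP
extraction.

## Worked example

`examples/02_extract_caps_elbow.py` simulates the default 8 WT + 10 TG
cohort (7 planted states), conditions it, and selects K:

```
WT: EV(k=2..10) = [0.017 0.026 0.033 0.038 0.042 0.045 0.049 0.051 0.053]
    fractional gains (%) = [57.1 25.2 14.5 12.2  6.3  8.3  4.9  3.6]
TG: EV(k=2..10) = [0.02  0.03  0.038 0.042 0.046 0.049 0.051 0.053 0.055]
    fractional gains (%) = [53.  24.6 11.8  8.8  8.1  3.9  3.8  4. ]

elbow: first k with <10% gain in both groups -> K = 7 (planted: 7)

Hungarian-matched WT-TG CAP pairs (Pearson r of mean maps):
  WT CAP 1 <-> TG CAP 7:  r = 0.90  [kept]
  ...
```

The EV curve saturates at the planted state count and matched pairs
correlate strongly because both groups share the same spatial states.
With the strong-effect preset (half of each template's positive mass
moved to the right hemisphere in TG animals),
`examples/03_cap_metrics_and_stats.py` finds the planted effect where it
belongs — in the laterality of co-activations:

```
median positive-activation laterality per CAP
  WT: [ 0.102  0.019 -0.058  0.004 -0.066 -0.02  -0.024]
  TG: [-0.07  -0.17  -0.223 -0.181 -0.139 -0.259 -0.262]
  SIGNIFICANT  laterality_pos WT CAP 1 vs TG CAP 7: medians +0.102 / -0.262, p_adj = 0.0003
  ...
```

and `examples/04_classification.py` reaches 100% mean validation
accuracy with spatial CAP features under both schemes, against a ~45%
shuffled-label chance level. The remaining examples cover cohort
simulation (`01`) and QPP-window/CAP overlap (`05`).

A one-command synthetic run of the whole pipeline, with NIfTI/TSV/JSON
outputs and per-stage logs:

```bash
capstate run --seed 1 --out out/
```

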