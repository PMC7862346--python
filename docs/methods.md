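# Methods

This note documents the models, numerical choices and known limits of
`capstate`. It is written for a reader who wants to know exactly what
the package computes and why, and what its synthetic validation does and
does not demonstrate about real data.

## The synthetic cohort generator

The generator emulates a single-slice rodent resting-state experiment:
8 wild-type and 10 transgenic animals, one 2D slice (default 32×16
desk-scale grid with an elliptical brain-like mask; the modelled
experiment's 128×64 is available through the config), T frames at
TR 0.5 s, and a hidden sequence of recurring spatial states.

**Spatial templates.** Each of the `n_states` (default 7) states is a
sum of positive and negative Gaussian blobs placed in the left
hemisphere and mirrored exactly across the column midline, scaled to
unit peak amplitude. States are organized as moderately anti-correlated
pairs — the odd member of a pair is `−0.5 × base + √0.75 × fresh
pattern` — plus one unpaired state when `n_states` is odd. This mirrors
how CAPs behave on real frame series, where patterns come in
co-activation/co-deactivation counterparts with mutual correlations
around −0.4 rather than −1, and it gives the explained-variance curve
its realistic concave, saturating shape. Pairwise template correlation
is kept below 0.9 by construction (redraw on violation).

**Dynamics.** States are visited by a first-order Markov chain with
self-transition probability `1 − 1/dwell_mean_frames` (default mean
dwell 10 frames = 5 s) and off-diagonal transitions proportional to the
target occupancies. Occupancies default to a mild geometric grading
(ratio 0.9, dominant state ~19%, rarest ~10%); the stationary
distribution of this chain deviates from the configured occupancies by
less than 0.01 at the default grading. Frames are the active state's
template plus i.i.d. Gaussian sensor noise, `noise_sd` default 2.0 in
template-peak units. That noise level was chosen so that the
*post-conditioning* single-frame correlation with the underlying
template lands in the range seen on real frame series (individual
frames are weak, noisy expressions of the pattern; group CAP averages
are crisp), which is also the regime in which the explained-variance
elbow behaves as reported for real data.

**Group effects.** Two planted effects are available and default to
zero: `tg_lateral_shift` moves that fraction of every template's
left-hemisphere positive mass to the right hemisphere for TG animals
(mass-conserving; the "strong effect" preset uses 0.5), and
`tg_occurrence_boost` multiplies the dominant state's occurrence
probability (preset 1.5×). Motion regressors are smooth low-frequency
random walks; they exercise the nuisance regression but do not corrupt
the signal.

**What the generator does not emulate:** hemodynamic convolution,
scanner drift, physiological noise, spatial noise correlations, 3D
volumes, or anatomical differences between groups. Passing the
package's studies therefore shows the *pipeline* is correct and has the
claimed power under controlled conditions — not that real mouse data
will separate this cleanly.

## Signal conditioning

Fixed order: motion regression (OLS residuals on intercept + 6 motion
parameters) → spatial smoothing (mask-normalized Gaussian kernel;
constant images are preserved and nothing bleeds across the mask
boundary) → zero-phase FIR band-pass (windowed-sinc Hamming taps,
0.01–0.2 Hz; the default order is 4× the slowest passband period in
samples, capped so forward–backward filtering stays valid for the
series length — short series therefore get a gentler low-frequency
roll-off, which is logged) → quadratic detrend → per-voxel unit-variance
normalization (population variance; zero-variance voxels stay zero and
are counted) → transient trimming (default 20 frames each end). Global
signal regression is deliberately absent. The desk-scale studies use a
smoothing σ of 0.5 px because the 32×16 grid is four times smaller than
the 128×64 slice for which the conventional σ = 2 px applies; the
`PreprocessConfig` default remains 2 px.

## Clustering and explained variance

Correlation-distance k-means is implemented directly: frames are
centered at their spatial mean and scaled to unit norm, k-means++
seeding (scikit-learn's `kmeans_plusplus`) is followed by Lloyd
iterations with renormalized mean centroids, the best of `n_restarts`
runs (default 10) by summed correlation distance is kept, and empty
clusters are repaired by splitting the largest cluster (the farthest
member becomes the empty cluster's centroid; repairs are logged).
Seeded runs (user-supplied initial centroids) are deterministic single
descents, which the subject-projection scheme relies on.

The variance decomposition is evaluated in the same normalized-map
geometry the clustering uses: `d²` is the squared Euclidean distance
between spatially normalized maps (twice the correlation distance for
unit vectors), `c_k` are the plain cluster means of the normalized
frames and `c` their size-weighted grand mean. In this form
`V_W + V_B` equals the total variance exactly (the classical ANOVA
identity), `EV = V_B/(V_W+V_B)` rises from near zero and saturates when
the real structure is exhausted, and the <10% fractional-gain elbow is
meaningful. Evaluating the same formulas with `d = 1 − r` against
*renormalized* centroids breaks the identity: on any noisy data the
k = 2 centroids come out anti-correlated, `d²` terms approach 4, and the
curve starts high and flat, so no elbow rule can work — which is why
the package commits to the ANOVA-consistent reading. A degenerate
series (all frames identical up to scale) reports EV = 0 with a flag.

## Matching and the surrogate threshold

Equal-k CAP sets are paired by `scipy.optimize.linear_sum_assignment`
on `1 − r` between mean maps (ties resolve to the lowest first-set
index). The chance threshold shuffles each group's frame labels
independently (cluster sizes preserved), recomputes surrogate CAP
means, evaluates r for the fixed original pairing, pools all pairs over
shuffles, and takes the empirical upper quantile at `p` (nominal
p = 1e-4 with 10,000 shuffles, i.e. at the pooled maximum; both the
nominal and attained quantile are logged). Pairs are additionally
filtered at r ≥ 0.5 for classification feature building. Degenerate
surrogate correlations (constant maps) enter the pool as 0.

## Subject-level metrics

Occurrence fractions and mean run lengths are computed within each
subject's own label sequence only (runs never merge across subject
boundaries; a CAP a subject never visits has occurrence 0 and *absent*
duration). Subject T-maps require at least two frames in the CAP.
The laterality index averages the T statistic per significant voxel of
the requested sign within each hemisphere — columns strictly left of
the grid midline are "left", with a flag to flip for radiological
order — and normalizes the left–right difference by the mean over all
significant voxels of that sign; an empty hemisphere contributes 0, so
the endpoints are exactly +1 (all left), −1 (all right) and 0
(mirror-symmetric). Co-deactivations use |T| so the sign convention
matches the positive case. Infinite-T sentinels (zero-variance voxels)
are clamped to the largest finite |T| present before averaging. For
pathological T distributions the per-significant-voxel average can in
principle leave [−1, 1]; the endpoints are what the definition pins
down.

## Group statistics

Metric comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney)
test, exact permutation null for combined tie-free samples up to 20,
tie-corrected normal approximation otherwise; subjects with absent
metrics are excluded per comparison (counts logged). BH-FDR is applied
per metric family *within* a partition, never across partitions, since
partitions of the same series are not independent hypotheses.
Prototype grouping across partitions — the cross-partition idea of
collecting spatially similar significant CAPs — is not given an
algorithm anywhere authoritative, so the package makes an explicit
choice: greedy agglomeration seeded at the candidate whose r ≥ r_min
(default 0.7) neighbourhood spans the most partitions, absorbing the
best-correlated candidate from each other partition, each CAP used at
most once.

## Classification

The classifier is scikit-learn logistic regression with L2 penalty
(two classes, so the multinomial model reduces to binary). The
regularization knob defaults to inverse strength C = 10, with a flag to
read it as penalty weight instead; predictions use maximum posterior
with exact ties going to the majority class (TG). Features are z-scored
per column with parameters fit on the training rows only, each trial.
Splits are random 14/4 by rounding, without class stratification.
Chance levels shuffle subject labels while preserving the 8/10 group
sizes (expected chance ≈ 44%, the majority-class rate).

The training-set-only scheme extracts WT and TG group CAPs from the
training animals only, then projects them into every subject: each
group CAP is correlated with the subject's frames, strict positive
local maxima of the correlation series are voxel-averaged into one
seed centroid per CAP (falling back to the single best frame, flagged,
if no positive peak exists), and one seeded correlation-distance
k-means over all frames assigns every frame to a CAP-like cluster.
Seeding *all* k clusters jointly matters: a lone two-cluster split
cannot isolate one pattern among seven — its "pattern" cluster is an
unstable mixture of roughly half the scan — and with it the scheme's
accuracy collapses; the jointly seeded version keeps cluster
composition aligned with the group CAPs. The single-CAP two-cluster
projection remains available (`subject_projected_caps`) for the case of
one pattern against background, where it is well posed.

Two properties of the schemes are worth knowing. First, the all-subject
scheme is optimistically biased by construction: every subject's
features are built from its own group's partition, so even cohorts with
*no* planted effect classify well above chance (~90% in the null
study). That selection bias is exactly why the training-set-only scheme
exists, and the null study asserts the unbiased scheme — not the
all-subject one — sits in the chance band. Second, subject-level
projected CAPs need scan length: at 600 frames per subject the unbiased
scheme loses several percent of accuracy through thin-margin splits,
while at the modelled experiment's 2400 frames it is stable; the
classification studies therefore simulate 2400-frame subjects.

## Study scales and determinism

The validation studies run at desk scale: elbow recovery uses 10 fresh
default cohorts (600 frames/subject) with EV curves for k = 2..10 and 3
k-means restarts per fit; the classification studies use 2400-frame
cohorts, 100 all-subject trials, 50 training-set-only trials with 3
restarts inside each trial's extraction; the null study uses 50 trials.
Every stochastic component is driven by an explicit integer seed
(NumPy `default_rng`/`SeedSequence`), and rerunning any stage with the
same config and seed is bit-identical.

## Known limitations

- Single 2D slice; no volumetric or multi-slice support.
- The surrogate-null loop recomputes cluster means per shuffle; at
  10,000 shuffles on large series it is the slowest stage (~minutes).
- The elbow rule needs at least two EV points below threshold inside
  the scanned k range; if none qualify, k_max is returned with a
  warning flag rather than an error.
- QPP windows are consumed or synthesized, never detected; the package
  takes no position on QPP detection.
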