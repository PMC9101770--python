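# Methods

## The recognition problem

A hip-worn motion sensor reports its absolute orientation as a **unit
quaternion time series** (uQTS) sampled every Δt = 10 ms: q(t_ℓ) = w + xi +
yj + zk with w² + x² + y² + z² = 1.  The task is to label every time point
of a free-living recording as *walking* (1) or *non-walking* (0), online if
needed, so that downstream gait analyses receive only genuine walking
phases.  Orientation values themselves are arbitrary (they depend on how the
sensor was mounted and where the wearer is facing); what distinguishes
walking is the *rate and regularity of orientation change*.

## Feature space

The transform chain reduces each trial to two real-valued predictors:

1. **Finite differences.**  Δq_ℓ = q_ℓ⁻¹ q_{ℓ+1} is the incremental rotation
   between consecutive samples (length P−1).  During steady activity it is
   close to the identity; at activity transitions and during gait it moves
   away from it.
2. **Distance series (QDTS).**  d_ℓ = 2·arccos Re(q_ℓ⁻¹ q_{ℓ+1}) is the
   geodesic distance on the unit 3-sphere, i.e. the rotation angle in
   radians between consecutive samples.  The double cover is *not* folded:
   values live in [0, 2π], and a `fold_double_cover` switch maps d ↦
   min(d, 2π−d) for users who want the SO(3) distance instead.  In practice
   consecutive 10 ms hip samples are nearly aligned and d stays far below π,
   so the choice is immaterial for this application.
3. **Windowed circular statistics.**  With a *left-hand* window of h past
   samples plus the current one (truncated, never padded, at the series
   start), the **local circular mean** is atan2(Σ sin d_m, Σ cos d_m) and
   the **local circular SD** is sqrt(−2 ln R̄) of the already-smoothed
   series, where R̄ is the mean resultant length with the actual (possibly
   truncated) window length as divisor.  Left-hand windows make the features
   causal: the streaming extractor reproduces the batch output exactly with
   O(h) memory, which is what makes on-chip, on-the-fly use feasible.

Default h = 50 (0.5 s at 100 Hz) — about one gait cycle at a brisk cadence,
long enough to average over the within-step angle oscillation, short enough
to keep transitions sharp.

Features are z-scored (population SD) with statistics frozen from the
training split; at prediction time the training statistics are re-applied,
never re-estimated.

### Numerical choices

- The geodesic distance is evaluated as 2·atan2(‖vec(a*·b)‖, Re(a*·b)),
  which is algebraically identical to 2·arccos of the clipped real part but
  stable near zero distance; bit-identical inputs return exactly 0.
- With h = 0 the circular mean returns its input verbatim (the atan2 form
  would wrap angles above π into (−π, π]) and the circular SD is identically
  zero (a one-angle window has R̄ = 1 exactly).
- Circular-SD windows are re-centred on their first angle before summing —
  R̄ is rotation-invariant, so the value is unchanged, but constant windows
  then yield exact zeros and batch and streaming paths agree bit for bit.
- A window whose resultant length is below 1e-15 (antipodal angles) has
  infinite circular SD; it is replaced by the largest finite value in the
  series (or a user-supplied cap) with a warning.  This cannot occur on
  distance series of physically contiguous orientations.
- atan2 output lies in (−π, π]; distance series are non-negative and tightly
  clustered, so no re-wrapping is applied to window means.

## Classifiers and tuning

Four standard families operate on the normalized 2-D feature space, each
predicting time points independently (fitted via scikit-learn):

| family | hyper-parameters | grid |
|---|---|---|
| CART decision tree | cost_complexity, tree_depth | 10⁻¹⁰…10⁻¹ × 1…10 |
| RBF SVM (kernel exp(−σ‖u−v‖²)) | cost, rbf_sigma | 2⁻⁵…2⁵ × 10⁻¹⁰…10⁰ |
| k-NN (triangular distance weights) | neighbors, dist_power | 1,3,…,67 × {1,2} |
| logistic (unpenalized) | probability threshold | 0.05…0.95 |

Tuning runs under **trial-grouped 5-fold cross-validation** (folds partition
trials, never time points, so temporally correlated samples never straddle a
fold) and selects one grid point by a six-step cascade:

1. grid point whose mean detection prevalence (TP+FP)/total is closest to
   the actual walking prevalence of the training data;
2. keep points within one standard error (SE of the optimum, SD across
   folds / √5) of that optimal detection prevalence;
3. highest mean precision TP/(TP+FP) among survivors;
4. keep points within one SE of it;
5. the same filter for accuracy (TP+TN)/total;
6. remaining ties go to the simplest model: smallest cost_complexity then
   depth (tree), smallest cost (SVM), fewest neighbors (k-NN), highest
   threshold (logistic); for smoothing, highest η then smallest τ.

Prevalence matching comes first because a detector that calls walking far
more or less often than walking occurs is useless for monitoring, whatever
its precision.  Undefined fold metrics (zero denominators) propagate as NaN
and such grid points drop out of the step that needs them.

The decision tree's minimum-node-size parameter is left at the engine
default; only cost_complexity and tree_depth are tuned.

## A posteriori smoothing

Raw per-point predictions ignore time. The smoothing pass restores temporal
coherence: (i) change points are indices where the raw label flips; (ii) a
single left-to-right sweep discards any change point closer than τ seconds
to the previously *retained* one (trial boundaries are not change points and
never cause a discard); (iii) each interval between retained change points —
including the leading and trailing runs — is relabelled walking iff its
fraction of raw walking predictions strictly exceeds η.  τ = 0 with pure
runs is the identity. The (τ, η) grids are 0:0.05:3 s and 0.05:0.05:0.95;
τ is capped at 3 s because scripted activities are separated by 3 s pauses,
beyond which two change points are never "too close".  The strict η gate
makes η a conservative brake on declaring walking.

## Evaluation

Manual change-point annotation is only trusted to ±25 ms, so every true
change point plus the 12 samples on each side is masked out before any
metric is computed.  Time-point metrics (precision, accuracy, detection
prevalence, prevalence) come from the masked confusion counts.  Segment
metrics recode each point by its (true, predicted) pair into TP/FP/FN/TN,
run-length encode the result (masked points are removed first; runs
separated only by a masked gap merge iff their classes match) and count
*segments* per class — each session counts once regardless of duration.  A
duration-weighted variant exists behind a flag but is not the default.

## Synthetic data

The study's raw recordings are not deposited, so the simulator generates
the study conditions: 100 Hz trials of 90 s alternating walking activities
(straight line, curved line, stairs) and non-walking ones (3 s pauses,
sit/stand holds), 28 trials over 3 subjects, walking prevalence 41/90 ≈
0.456.  During walking, hip orientation composes (a) a slow drift about a
fixed random axis at 0.01 rad/s, (b) a sinusoidal sway of 0.15 rad at the
cadence frequency (1.8 steps/s) about a body axis that differs between
straight and curved/stair walking, with a 0.25 s raised-cosine on/off ramp
so bouts start and stop smoothly, and (c) per-sample jitter rotations of
0.002 rad composed multiplicatively, which keeps the series exactly on the
unit sphere.  Pauses and holds see only drift + jitter.  Subjects perturb
cadence and sway by ±10%; all randomness derives from one seed.  Presets:
`easy` (defaults) and `hard` (5× jitter, half the sway).

What this emulates is the *signal structure* the features rely on — a
sustained, periodic orientation-change rate during walking, quasi-static
orientation otherwise, with exactly known labels.  It does not emulate
biomechanics: no stance/swing asymmetry, no double-cover sign flips, no
sensor-fusion transients, no between-trial mounting variation.  Passing
tests therefore demonstrate that the pipeline recovers planted structure
under realistic noise scales, not field performance on real gait.

## Experiment protocol and problem sizes

`run_experiment` mirrors the study protocol end to end: 28 simulated trials
(~252k time points) split 75/25 by trial (21 train / 7 test), grouped
5-fold CV on the training trials, full decision-tree grid (100 points), then
the full smoothing grid (1159 points) tuned on the tuned classifier's
per-fold raw predictions, a final fit on all training trials, and
margin-filtered evaluation on the held-out trials.  One run takes about two
minutes on a single CPU.  The smaller grids used in some tests exercise the
identical code path at reduced cost.

## Known limitations

- Global (training-set-wide) normalization; per-trial normalization might
  suit heterogeneous sensors better.
- The one-SE bands use the optimum's SE; the per-candidate-SE variant would
  retain slightly different sets.
- Segment metrics count sessions equally; a single mislabelled sample
  splitting a long run changes counts by one segment.
- The simulator's difficulty presets bound, but cannot replace, validation
  on real recordings.
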