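# Methods

## The model

The Kinematic Deviation Index treats a movement trial as a multivariate
time series of tracked marker coordinates and asks one question: how far
does this trial's trajectory, embedded in a low-dimensional space, sit
from the animal's own best performance? The design rests on three
assumptions:

1. **The baseline-success consensus is the optimum.** Trained animals'
   successful baseline trials sample a stereotyped movement; their
   multidimensional average is taken as the best performance that animal
   can produce, and every other trial is referenced to it. The index is
   therefore *within-subject*: KDI values are comparable across trials of
   one animal, and across animals only in the sense of "deviation from
   own baseline".
2. **Per-trial PCA is meaningful.** Each trial's 100 × p matrix is
   decomposed independently, so a trial's embedding reflects its own
   covariance structure. The price is rotational indeterminacy between
   trials, which is exactly what the Procrustes machinery corrects.
3. **Three components suffice.** J = 3 retains the dominant
   reach–advance–grasp–withdraw structure; it is configurable.

### Pipeline

Per trial: standardize columns → SVD → keep J loadings (deterministic
sign: largest-magnitude entry of each column positive) and scores.
Per animal: GPA over baseline-success loadings (rotation-only,
reflections allowed — PC signs are arbitrary; no scaling or translation
because loading scale and origin are meaningful). Consensus = mean of
rotated loadings, iterated to tolerance 1e-8 (max 100 iterations); the
alternating scheme's objective — the summed squared Frobenius distance
of rotated loadings to the consensus — is non-increasing by
construction. The reference trajectory is the per-sample mean of the
baseline trials' *rotated score* trajectories (we define the reference
in score space, consistent with measuring the distance there; an
alternative of projecting an averaged data matrix through the consensus
loadings is not used). Scoring: rotate the trial's loadings to the
consensus via orthogonal Procrustes (R = UVᵀ from the SVD of
sourceᵀ·target), project, and accumulate per-sample Euclidean distances
in trajectory order n = 1..100.

### Consensus orientation

GPA determines the consensus only up to one global J × J rotation
(any rotation applied to the consensus and all per-trial rotations
leaves the objective unchanged). KDI is invariant to this freedom, but
stored reference matrices would depend on input order. We therefore
finish GPA by rotating the consensus (and all rotations) to best align
with the element-wise mean of the raw, sign-fixed loadings — an
order-independent anchor. This makes references reproducible under
permutation of baseline trials without affecting any score.

### Standardization

Default is z-scoring each column of X_i (per trial), so markers with
large pixel excursions do not dominate the embedding; constant columns
receive scale 1. A `center_only` mode is provided: it is the natural
choice when all variables share units, and it is the mode in which KDI
is provably invariant to a common orthogonal transform of the variable
space (z-scoring is coordinate-wise and breaks that symmetry).
Standardization statistics always come from the trial being scored, not
from the reference — each trial's PCA is self-contained.

### Variable set

X_i contains x and y per included marker. Derived variables (digit
span = distance between first and last digit markers; paw angle = the
orientation of that vector) can be appended behind a config flag but
are off by default: they complicate interpretation without changing the
index's character. For the single-pellet task, the recommended analysis
configuration excludes the pellet marker from X_i: the pellet is a
static landmark, so after per-trial z-scoring its columns are amplified
pure tracking noise. Empirically this matters — with the pellet
included, the baseline KDI noise floor is an order of magnitude higher
and graded perturbations an order of magnitude below it become
undetectable. The library itself is marker-agnostic; the exclusion is
an analysis choice expressed through `include_markers`/`exclude_markers`.

## Preprocessing

Fixed order: spatial → temporal → time normalization.

- **Spatial coherence** (default quantile 0.92): per marker pair, the
  per-frame Euclidean distance distribution over all frames yields a
  threshold at the quantile; a point is removed when it violates a
  strict majority of its pairs' thresholds in that frame. Per-pair
  thresholds (default) respect that different pairs have different
  typical separations (digit–digit vs digit–pellet); a pooled mode is
  available. Majority voting attributes the incoherence to the single
  displaced marker rather than blanking both members of every violated
  pair. Pairs with fewer than 10 jointly observed frames are skipped.
  The quantile rule removes up to 8% of each pair's distances by
  construction, which on clean data costs little: flagged points are
  re-imputed from the smooth fit in the next stage.
- **Temporal coherence**: Friedman's supersmoother (implemented in
  `smoothing.py`: three running local-linear smoothers with spans 0.05 /
  0.2 / 0.5 of the data, per-point span selection by smoothed
  leave-one-out absolute residuals, interpolation between bracketing
  fits; bass enhancement available, default 0) is fit per marker per
  coordinate against frame index. Residuals larger than
  `residual_k` × robust σ (1.4826 × MAD; default k = 3, MAD chosen over
  s.d. because the outliers being hunted would inflate an s.d.) are
  replaced. Replacement and imputation values come from a refit that
  excludes the detected outliers, so the substitute is not biased by the
  very point it replaces. A small absolute floor (1e-7 × trace range)
  prevents noiseless traces from self-flagging. Traces with fewer than
  10 observed points fall back to linear interpolation; an all-missing
  trace is unrecoverable and raises.
- **Time normalization**: each variable is linearly interpolated onto
  `n_out` = 100 points at t_k = first + (k−1)/(n_out−1) × (last−first),
  so sample k represents 1% steps of trial duration and both endpoints
  are preserved exactly. Normalization is idempotent at these nodes.
  One pass only: flagged points are not re-detected iteratively.

## Synthetic data

The generator emulates a mouse single-pellet reach recorded at
720 × 540 px (image convention, y down), nominal 327 fps: a clamped
cubic spline through five paw waypoints (rest, lift, slot, pellet
contact, withdraw end — a loop, not a retrace), four digit markers at
fixed offsets modulated by a smooth grasp-aperture profile, and a
static pellet. Trial durations are drawn uniformly from 200–500 frames
(animal templates) with ±15% per-trial jitter, exercising time
normalization across unequal lengths. Tracking noise is isotropic
Gaussian, default σ = 1.5 px — a realistic figure for good markerless
tracking of small features. Perturbation amplitudes are expressed in
multiples of this baseline σ and keep their physical size even on
noiseless renders (so locality can be verified exactly):

- `truncate_reach` — geometric: no digit ever attains the pellet's
  x-coordinate (a reach failure);
- `grasp_alteration` — smooth displacement after pellet contact (a
  grasp failure: target attained, grasp disturbed);
- `tremor_noise` — windowed sinusoidal displacement (4 cycles) along a
  fixed direction;
- `amplitude_scale` — movement extent shrunk toward the start;
- `slowing` — a monotone time warp inside the segment.

All perturbation windows are sin² bumps supported exactly on their
segment. Cohort scenarios (`endpoint_validity`, `chronic_injury`,
`silencing`) assemble these per animal with subject-specific waypoint
jitter (σ = 6 px) for individual movement strategies. Everything is
deterministic given a seed, to the byte for files on disk.

What the generator does *not* model: autocorrelated tracking error,
marker identity swaps, occlusion structure (missingness is i.i.d.),
biomechanical constraint coupling between digits, camera distortion,
or session-level drift. Passing tests therefore demonstrate the
pipeline's algebraic contracts and its sensitivity/discrimination
behaviour under controlled corruption — not performance on any real
dataset.

## Validation experiments

The acceptance script and the behavioural test suite measure, at seeds
supplied by the caller:

- **Self-reference zero**: a trial scored against a reference built from
  itself alone yields KDI < 1e-10 (numerical round-off only).
- **Endpoint discrimination**: 10 baseline-success reference trials;
  20 trials per endpoint class. Success must have the lowest median KDI
  and success-vs-reach-fail AUC > 0.9.
- **Amplitude sensitivity**: tremor amplitudes {0, 0.5, 1, 2, 4} × σ,
  30 trials each, *paired by seed across amplitudes* (common random
  numbers — the standard design for dose-response curves, isolating the
  amplitude effect from trial-to-trial variability). Medians must rise
  strictly; pooled Spearman ρ(amplitude, KDI) > 0.8.
- **Corruption recovery**: spikes of 20 × σ on 5% of points plus 2%
  missing; ≥ 90% of spikes must be flagged or replaced and the RMSE to
  noiseless ground truth at least halved.

Problem sizes (10 reference trials, 20–30 per group, single animals
per experiment) keep each experiment in seconds while leaving the
statistical margins wide (observed: AUC ≈ 1.0, ρ ≈ 0.92, recovery
100%, RMSE reduction ≈ 88%).

## Numerical choices and edge cases

- All linear algebra in double precision; KDI accumulated left-to-right
  over n = 1..100, so `kdi == sum(kd_trajectory)` exactly as stored.
- PCA sign convention applied before any Procrustes step; ties in the
  largest-magnitude loading entry are broken by first index.
- Rank-deficient trials embed with zero-variance trailing components
  and a logged warning; explained variances are fractions of total
  variance and non-increasing.
- Procrustes of a zero matrix is refused (degenerate geometry);
  GPA of a single matrix returns it unchanged in one iteration.
- A reference may be built from a single baseline trial (with a
  warning below three): its reference trajectory is then that trial's
  own scores.
- Manifest endpoint labels are matched case-insensitively against
  {success, grasp_fail, reach_fail}; anything else becomes `unknown`
  with a warning. Unknown-endpoint trials are scored normally; they are
  simply never used for references.
- Readers never impute; missing cells stay missing until the smoothing
  stage. Matrix CSVs round-trip at ≥ 15 significant digits.

## Known limitations

- Time is normalized away: two trials differing only in speed profile
  score nearly identically unless the warp changes the sampled shape.
  Duration is recorded (`original_n_frames`) for downstream use.
- The reference is within-subject; no population-level reference is
  provided.
- Spatial flagging is a single pass (no flag → smooth → re-flag
  iteration), and gap length is ignored during imputation — long gaps
  are filled as confidently as short ones, limited only by the
  smoother's span.
- Inferential statistics (mixed models, spline trajectories) are out of
  scope by design; the per-trial KDI table and long-format
  KD-trajectories are the hand-off to any stats package.
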