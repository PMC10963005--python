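# Methods

This note documents the models, conventions, parameter choices, and
limitations behind `tandemtrap`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and sampling conventions

Coordinates are millimetres, y up, origin arbitrary per recording;
readers expose `flip_y` for image-origin sources.  Headings are radians
CCW from +x in [0, 2π); missing headings are NaN and are estimated from
centroid displacements (direction of the step t → t+1 when at least
`min_step_mm` long, otherwise carried forward; leading gaps back-filled).
Frame indices are 0-based; intervals are half-open.  Analysis runs at
1 FPS after integer-ratio downsampling, mirroring common practice for
slow-moving insects; entry/escape frames snap to the nearest kept frame
at or after the original.

Body length (BL) is the head-to-abdomen-tip length.  Per-frame distance
is normalised by the mean of the two body lengths, so "1 BL" is about
one animal length; the *interaction filter* instead uses the sum of the
two body lengths ("twice a termite body length") as the strict upper
bound on the raw distance, because that is how the threshold is defined
operationally.  Speeds are forward differences at the analysis rate, in
units of the focal animal's own BL per second.

## Synthetic tandem generator

The generator emulates the study conditions and provides ground truth
for parameter-recovery and calibration tests.

**Leader** — correlated random walk: per-step speed ~ Normal(2.0, 0.5)
BL/s truncated at zero; heading increments ~ Normal(0, 0.4·√dt) rad.
The defaults reproduce natural tandem speeds near 2 BL/s.

**Follower** — pursues the contact point `contact_dist_bl` (default 1.0)
mean body lengths behind the leader's centroid *along the
follower-to-leader line*, relaxing toward it at rate `follower_gain`
(default 20 /s); its heading is its own displacement direction.  A
centroid-to-centroid offset of one body length corresponds to
head-to-tip contact for two touching bodies.  The pursuit target is
deliberately not pinned to the leader's instantaneous body axis: a
target attached to the diffusing heading axis sweeps laterally at a rate
growing like `contact·turn_sd/√dt`, which would make the follower's path
length depend on the integration step.  With saturating gain and zero
noise the follower locks exactly onto the contact point (the fixed-point
contract tested in the suite).  A consequence of pursuit is mild corner
cutting: the follower's mean speed is ~2 % below the leader's.

**Entrapment** — an 80 mm square sticky patch centred in a 221 × 114 mm
arena.  The pair starts outside the patch aimed at it; `entry_frame` is
the first frame with the leader's centroid inside the square.  On the
patch all speeds are multiplied by `trap_speed_factor` (default 0.03,
giving trapped speeds near 0.06 BL/s) and the leader cannot leave.  The
follower keeps following, and once it is on the patch and within 1.3×
the contact distance it *settles*: with probability `heading_mix_w`
(default 0.5) it takes the leader's heading, otherwise the opposite, at
a lateral offset of 0.25 BL and an along-axis offset of −0.7 BL
(same-heading) or 0 (opposite-heading), which keeps the follower's head
near the leader's abdomen tip in both configurations.  These settling
constants are stand-ins for unquantified behaviour on sticky surfaces,
not claims about termites.  With `trap_speed_factor = 1` the surface has
no adhesion and the natural update law continues (degenerate-case
contract).  Escape times are drawn per individual from an exponential
with rate `escape_hazard_per_min` (default 0.021 /min, placing the
expected both-trapped fraction at 10 minutes near exp(−2·0.021·10) ≈
0.66); an escapee resumes free walking and its escape frame is recorded,
censoring encoded as missing.

**Postures** — head, pronotum-border and abdomen-tip points placed
collinearly along each animal's heading axis through the centroid at
proportions (0.0, 0.15, 1.0) of the head-to-tip span, plus isotropic
Gaussian noise; the head-to-tip distance equals the body length exactly
at zero noise.

**Reproducibility** — one seed per event; all substreams (leader,
follower, observation noise, event geometry) derive deterministically
from it, so identical seeds and parameters give bit-identical output.
Rarely the leader misses the patch; the simulator then retries with a
substream derived from (seed, attempt), preserving determinism.

**What the generator does not emulate** — arena walls during natural
runs; pauses and speed autocorrelation (step speeds are white, so the
1-FPS speed SD is smaller than for real animals whose slow fluctuations
survive averaging); antenna-mediated contact dynamics; re-entry after
escape; any resin-specific physics (engulfment, viscosity).  Passing
tests therefore demonstrate that the *analysis* recovers the structure
the generator encodes, not that the generator is a faithful termite.

## Randomized-pairing null

Per replicate a derangement σ of male indices is drawn by rejection
from uniform permutations; female i is paired with male σ(i) after the
male's trajectory is rigidly rotated-then-translated so its first
position and first resolvable heading match male i's (an isometry — all
within-trajectory distances preserved).  Unequal lengths after swapping
are truncated to the shorter series.  Self-pairing is excluded because
it would reproduce the real pair and contaminate the null.  The null is
scoped to a single condition.

Two comparison routes are reported:

* **Pooled-frames test** (KS or rank-sum on all per-frame values, real
  vs null).  Frames within a trajectory are autocorrelated, so this
  test treats dependent observations as independent and is
  anticonservative; it is reported because distribution-level contrasts
  are the conventional summary.
* **Monte-Carlo placement** of the real replicate-level mean within the
  null distribution of replicate means, as a mid-rank quantile
  q = (k + 0.5)/(n_rep + 1) and two-sided p = 2·min(q, 1−q).  Under a
  true null (independent walks) q is approximately uniform — the
  calibration the acceptance suite verifies.  One finite-ensemble
  caveat, characterised during development: a null replicate never
  shares a pair with the real identity pairing, while two replicates
  can share pairs, so with very few events (~8) the real mean's rank is
  mildly over-dispersed (95 % band coverage ≈ 0.91 instead of 0.96).
  At study-scale ensembles (≥ 20 events) coverage is nominal.

## Posture features and role classification

Each frame yields two feature vectors: for each focal individual, the
Euclidean distances from its head to the partner's head, pronotum
border, and abdomen tip, divided by a normalising body length
(`mean_bl` of the pair by default; `partner_bl` and `none` are exposed
because the choice is not canonical and matters when comparing across
species of different size — e.g. scoring a 6.5/5.5 mm fossil pair with
a model trained on 8 mm animals).  Features are invariant to rigid
motions of the frame and to uniform scaling when the normaliser scales
likewise.

Training rows are labelled by the known role of the focal sex in the
training species (female leads in the training tandems; the generator
can produce male-led tandems for robustness checks).  The classifier is
an unregularised logistic regression on the three centred, unit-variance
distances (deterministic given data; perfect separation produces a
warning and coefficients bounded by the optimiser tolerance).  A PCA of
the same standardised matrix (correlation-style, since the three
distances have unequal spreads) is kept purely for visualisation, with
unit-norm loadings and explained-variance fractions summing to 1.  A
snapshot is scored by presenting each individual as focal once;
p(leader) + p(follower) = 1 per individual, and the two individuals'
probabilities are not constrained to be complementary.

Training pools frames across events.  Frame-level pooling overstates
effective sample size for inferential statements (frames are
autocorrelated), which is acceptable for the classifier (a point
predictor) but means the paired-t statistic on tip–head distances grows
with recording length; per-event aggregation is available via the
feature table.

## Inferential tests

The rank-sum statistic is W = Σᵢⱼ 1[xᵢ > yⱼ] + ½·1[xᵢ = yⱼ].  For
n₁+n₂ ≤ 20 without ties the two-sided p is exact, from the Mann–Whitney
counting recursion (doubling the smaller tail, capped at 1); ties in
exact mode are refused unless a permutation flag is set (full
enumeration over the observed values), otherwise the normal
approximation with continuity and tie corrections applies.  KS uses the
asymptotic two-sample distribution; the paired t raises on
zero-variance differences rather than reporting an infinite statistic.

## Pipeline and problem sizes

`run_pipeline` is deterministic given the config and writes the resolved
config, metric tables, density maps, null comparison, role model,
snapshot classification, and a versioned summary JSON.  The acceptance
script runs 12 natural + 16 trapped events of 12 minutes at the study
recording rates with a 200-replicate null — sizes chosen so the whole
reproduction completes in well under a minute on one CPU while keeping
every estimate's Monte-Carlo error small relative to the effects
measured; the test suite uses smaller ensembles per check on the same
principle.  The synthetic fossil-like snapshot is exactly that —
synthetic, labelled as such in outputs — standing in for a real
preserved pair: the final settled frame of a male-led trapped
simulation at the fossil body lengths.

## Known limitations

* The settling geometry and follower re-contact behaviour on the trap
  are stand-ins; their constants should not be read as measurements.
* The pooled-frames KS/rank-sum p-values ignore within-trajectory
  autocorrelation; use the Monte-Carlo placement for calibrated
  inference.
* Reproduction mode (reading deposited trajectory/posture tables)
  exercises the same code paths as the synthetic route but is only as
  good as the supplied tables; no video tracking or pose estimation is
  performed here.
* Escape is modelled as memoryless and independent between partners;
  real escapes may be correlated (one partner freeing the other is not
  modelled).
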