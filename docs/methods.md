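# Methods

## Signal model and representation

A pre-segmented sign gesture is observed through one wristband per
forearm: four surface-EMG channels sampled at 1000 Hz (millivolts) and
a 3-axis accelerometer (g units) plus 3-axis gyroscope (deg/s) at
100 Hz.  One-handed signs carry only right-hand signals; two-handed
signs carry both, processed by independent per-hand classifiers.  The
recognition target is not the raw signal but a 13-tuple of discrete
subclass indices: hand shape, orientation, axis and rotation evaluated
in three temporal stages — begin = the first 25 % of samples, middle =
the 20–80 % span, end = the last 25 % (half-open intervals
`[floor(a·L), floor(b·L))`, computed independently on the 1000 Hz and
100 Hz grids) — plus a single whole-gesture trajectory element.  The
begin/end stages deliberately overlap the middle stage.

## Component features

* **Hand shape** — per overlapped sEMG window (default 128 ms window,
  64 ms increment; configurable) and per channel: mean absolute value,
  4th-order autoregressive coefficients (Burg's method, sign convention
  `x(n) = w(n) − Σ a_k x(n−k)`), zero crossings and slope sign changes
  (amplitude threshold 0.05·std of the frame, computed per frame and
  channel), and waveform length — a 32-vector per frame.  A constant
  frame yields zero AR coefficients with a warning rather than aborting
  the gesture; a flat neighbourhood is never counted as a slope change
  even when the degenerate threshold is zero.
* **Axis** — per stage, channels are mean-removed; the features are the
  three channel standard deviations and the three signed co-energy
  ratios `r_ij = |S_i·S_j| / Snorm · sign(S_i·S_j)` with
  `Snorm = Σ_i ‖S_i‖`.  Note the *shared* normalisation: r is not a
  Pearson correlation and grows with the square root of the window
  length.  An identically-zero stage maps to the zero vector.
* **Orientation** — the per-stage channel means of the ACC (the gravity
  direction for a quasi-static hand attitude).
* **Rotation** — the axis features applied to the GYRO.
* **Trajectory** — each ACC and GYRO channel linearly resampled to 64
  points spanning the whole gesture (endpoints preserved exactly),
  stacked 64×6.

## Subclass discovery

Per component, each reference gesture contributes one point per stage
(repetitions averaged): stage-averaged 32-vectors for hand shape, the
static vectors for orientation/axis/rotation, and for the trajectory a
normalised flattening of the 64×6 curves (fuzzy c-means needs
fixed-length vectors).  The trajectory normalisation divides the gyro
channels by 250 deg/s per g (unit balancing) and detrends each of the
three stage segments per channel by removing its mean, its first three
within-stage Fourier harmonics, and level-shift regressors at the
centers of the two stage-overlap zones.  The removed smooth baseline is
exactly the content described by the orientation (per-stage gravity
offset) and axis/rotation (per-stage oscillatory burst) features; what
survives is the transient fine structure of the path.  The same
normalised sequences are the observations of the trajectory HMM.

Clustering is fuzzy c-means (fuzzifier m = 2, Euclidean metric,
k-means++ seeding, five restarts keeping the lowest objective,
convergence at center shift < 1e-5).  The alternating updates make the
objective `Σ u_ik^m d_ik²` non-increasing; fixed seeds give
bit-identical results.  The initial cluster count k0 is an analyst's
overestimate (roughly the expected count plus a margin; e.g. 20 initial
hand-shape clusters collapsing to 11 true patterns).  Afterwards,
clusters with fewer than `min_members = 2` hard-assigned points are
discarded (points fall to the nearest surviving center) and center
pairs closer than `merge_dist` merge into their member-weighted mean,
repeated to a fixed point.  By default `merge_dist` is 0.25 × the
median inter-center distance *of the current surviving centers*,
re-evaluated on every pass — evaluating it once on the over-provisioned
initial centers would let their duplicate pairs depress the median.
Both knobs are configurable.  Subclass assignment for new data is
nearest-center in the same space.

## Component classifiers

Sequence components (hand shape frame sequences; normalised 64×6
trajectories) use one continuous HMM per subclass: five left-to-right
states with self-loops, three diagonal-covariance Gaussian mixture
components per state.  Initialisation segments every training sequence
uniformly into five blocks and runs per-state k-means over the pooled
block frames; mixture variances are floored at
`max(1e-6, 1e-3 · pooled variance)` per dimension.  Baum–Welch then
refines transitions and emissions (the start state stays fixed and the
left-to-right zeros are preserved by EM); the full log-likelihood trace
is stored and is non-decreasing.  If EM ever produces non-finite
parameters on a degenerate pool, the moment-based initial model is kept
with a warning.  Scoring uses the scaled forward recursion in the log
domain.  Hand-shape training pools the begin/middle/end stage sequences
labelled by their stage's subclass.

Static components (orientation, axis, rotation) use one multivariate
Gaussian per subclass, pooled over stages: sample mean and
ridge-regularised sample covariance.  The default ridge is 1e-3 × the
mean pooled per-dimension variance of the training set (floor 1e-9),
which keeps near-singular subclass covariances from dominating the
likelihood comparison when Θ is small.  The log-density is the standard
full d-dimensional multivariate normal — the constant is
class-independent at fixed d, so the argmax is unaffected by the choice
of normalising convention.  Ties break to the lowest subclass index
with a warning.

## Encoding and matching

With `n_c` subclasses per component, element value i maps to an
`n_c`-bit one-hot segment (bit 1 leftmost); the 13 segments concatenate
in canonical element order.  Reference codes have popcount 13; distinct
words may legitimately share all 13 components, so duplicate codes are
logged, not rejected, and matching returns the earliest duplicate.  At
recognition time both the maximal- and submaximal-probability subclass
bits are set per element (popcount ≤ 26) to absorb execution
differences between users; the submaximal bit is always added.  The
match is `argmax_i popcount(x AND C_i)`, ties to the earliest table
entry with a warning.  The score is at most 13 and reaches 13 exactly
when every element's reference subclass is among the test code's bits.

## Training sets and evaluation protocol

The covering training set is built per component by greedy set cover
over the reference representations (pick the gesture covering the most
uncovered subclasses, ties by lexicographic id); the union of the five
component sets is T and obeys `size(T) ≤ Σ_c size(T_c)`.  Θ > 1 adds,
subclass by subclass in sorted order, further gestures until each
subclass occurs in `min(Θ, available)` distinct gestures — the sets are
nested in Θ.  A new user's training recordings are labelled with the
*reference* representations (decoded from the code table, which is
bijective with the one-hot codes); a subclass with no training data
raises an error naming the component and index.

Evaluation splits each trained gesture's repetitions 4:1 (at least one
held out; seeded permutation): TA = held-out repetitions of T's
gestures, TB = all repetitions of gestures outside T, TC = TA ∪ TB.
Reported per Θ: split accuracies, per-element component accuracies
(top-1 subclass vs reference), per-gesture accuracies, and paired
t-tests between adjacent Θ levels (descriptive only).  Everything is
reproducible bit-exactly under a fixed seed.

## The synthetic-data generator

The generator exists so that every stage — features, clustering,
classifiers, code matching, and the untrained-gesture claim — can be
tested against planted ground truth.  Its defaults define the study
conditions used by the test suite and the acceptance script: subclass
counts (6, 4, 3, 3, 6), 40-gesture vocabularies with 5 repetitions,
moderate sensor noise (`NOISE_MODERATE = 0.35`; `NOISE_LOW = 0.1`
approaches the clean limit).

* Durations are drawn uniformly from 2.0–2.6 s so that, under the
  default 128/64 ms windows, even the begin stage yields at least six
  sEMG frames — enough for a five-state left-to-right HMM.  All motion
  waveforms are parameterised in cycles per stage, making the resampled
  64-point curves duration-invariant.
* **Hand shape**: band-limited (20–450 Hz) Gaussian noise, a standard
  surrogate for interference-pattern EMG, amplitude-modulated per stage
  by a 4-channel signature (0.1–1.0 mV, mutual separation ≥ 0.3).
* **Orientation**: unit gravity per stage from a compact direction set
  (the palm-down pole plus a 40°-tilted ring); orientations within a
  gesture change by moderate wrist rotations, not full flips, and the
  hand-over occurs at the centers of the stage-overlap zones so each
  analysis window sees at most half an overlap zone of a neighbouring
  attitude.
* **Axis / rotation**: Hann-enveloped two-cycle-per-stage bursts along
  the subclass direction (3 g on ACC, 100 deg/s on GYRO).  The envelope
  vanishes at stage edges (no bleed into overlapping windows) and
  confines the burst spectrum to within-stage harmonics 1–3, which the
  trajectory normalisation removes exactly.
* **Trajectory**: per stage, each channel receives exactly one Gabor
  wavelet (six-cycle carrier, Gaussian envelope σ = 0.125 stage;
  0.6 g on ACC, 20 deg/s on GYRO) whose time-slot-to-channel
  permutation is the subclass signature.  Equal
  per-channel-per-stage wavelet power means the axis/rotation standard
  deviations see a subclass-independent offset; the carrier band lies
  above the burst band, keeping the cross-channel r values clean.
* The noise knob scales additive sensor noise (0.25 g, 25 deg/s,
  0.03 mV at noise = 1), amplitude jitter, carrier phase jitter and
  wavelet timing jitter together.

Sampled vocabularies are distinct 13-tuples seeded with two covering
blocks, so every subclass occurs in at least two gestures (a singleton
subclass could not survive small-cluster pruning).  `world_inventory`
measures ground-truth centers from a noiseless calibration batch.

What the generator does **not** emulate: motor-unit-level EMG
physiology, sensor drift and axis misalignment, inter-subject execution
differences (a "new user" differs from the reference only by fresh
noise draws), co-articulated or unsegmented gesture streams, and the
natural correlation between a sign's trajectory and its axis/orientation.
Passing tests therefore demonstrate the *mechanics* of the framework —
exact encoding, faithful clustering, classifier consistency,
extensibility through code matching — not field performance on human
recordings.

## Numerical choices and limitations

Tolerances: c-means tol 1e-5 on center shift; EM tol 1e-3 with 25
iterations by default; variance floor as above; Gaussian ridge as
above.  Degenerate inputs: zero stages map to zero features; constant
frames give zero AR vectors; duplicate c-means centers are jittered
deterministically; likelihood and match ties break to the lowest
index/earliest entry with warnings.  Problem sizes in the test suite
(40-gesture vocabularies; three reference repetitions, five user
repetitions per gesture; 20 recovery seeds; 10 protocol seeds) were
chosen to exercise the full protocol at desk scale.  Known limitations:
the r features' window-length dependence makes the static-component
spaces stage-sensitive for very long gestures; code matching is
unweighted, so words sharing 12+ components are inherently confusable
(the collision is logged); and one-handed processing covers the
dominant hand only — the 13-element representation does not encode
left-hand components, although left-hand classifiers are trained for
two-handed recordings.
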