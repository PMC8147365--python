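# Methods

This note documents the models, the synthetic data, the numerical
choices, and the limits of what the tests demonstrate.

## 1. The sensing model and its simulator

The physical platform watches one subject with a webcam (face-centroid
pixel coordinates u, v via cascade detection plus correlation tracking)
and a three-receiver ultrasonic array (chest range, cm) covering
0.4–5 m, with detection triggered inside 2 m. The simulator
(`fallwatch.sensor_sim`) replaces the hardware with a generative model
of one *fall event*: the subject rotates in place inside the trigger
zone, staggers, falls, and ends lying on the floor.

Stage kinematics are piecewise linear in the image row v and the range
z, with per-frame slopes:

| stage      | v slope (px/s)            | z slope (cm/s)              |
|------------|---------------------------|-----------------------------|
| normal     | 0 (rotation in place)     | 0                           |
| transition | 80 · s_t                  | −30 · s_t                   |
| fall       | 250 · s_f · ramp(t)       | −80 · s_f · ramp(t)         |
| lying      | 0                         | 2 · sin(2π·0.3 t) breathing |

where s_t, s_f ~ clip(1 + 0.3·N(0,1), 0.3, 2) are independent per-event
scalings (subjects fall in different ways), and ramp(t) rises linearly
over the 0.6 s active descent (a falling body accelerates). Position is
integrated with the *left-endpoint* slope of each frame interval so that
a central finite difference evaluated at the last frame of a stage still
recovers that stage's own velocity — without this, one boundary frame
per event mixes two stages and the noiseless limit cannot be exact.

Defaults are the canonical study conditions: 140 events, 7 subjects of
height 164.2 ± 12 cm cycled deterministically, 40 raw frames per event
at 5 Hz, stage fractions (0.3, 0.1, 0.6), Gaussian sensor noise
(2 px image, 3 cm ultrasonic), 5 % per-frame face-detection dropout,
and a ×5 noise gain once the subject is down — a prone body returns
erratic ultrasonic echoes and the face tracker drifts, which is also why
the platform shuts tracking off 5 s after detecting a fall. The 30
retained points per event then hold 10 normal, 4 transition and 16 fall
samples, making normal motion the minority class (33 %), consistent
with the reference confusion counts in which true negatives are ~29 %
of points. After windowing, 140 × 30 = 4,200 model-input points.

The stage mix, slopes and noise scales were chosen to reproduce the
qualitative map geometry the platform reports — a dense, intense normal
cluster; a falling cluster with a visibly larger scattering region; and
sparse transition points between them — and the ~0.7 s alarm lead time
scale (the transition lasts 0.8 s here). `SimConfig.noiseless()` zeroes
*every* stochastic term (sensor noise, dropout, per-event kinematic
jitter, sway, and the subject-height spread); the deterministic
breathing micro-motion remains, because a prone body is never a true
point mass and the clustering step must not be asked to distinguish two
exact point masses.

What the simulator does **not** emulate: real tracker failure modes
(occlusion, identity switches, re-detection latency beyond Bernoulli
dropout), multipath or crosstalk between ultrasonic channels, diverse
fall biomechanics (it is piecewise-linear kinematics, not physics), and
non-fall confounders such as sitting down or bending over. Passing
tests therefore show the *pipeline* is correct under the stated
statistical structure; they are not evidence about detection rates on
real subjects.

## 2. Fusion and normalization

The three ultrasonic channels are fused per frame by the median of the
valid readings, restricted to the readings that decreased relative to
the previous fused value whenever any did (the "approaching subject"
principal-signal rule); with no valid reading the previous value is
held. Face dropouts hold the last valid centroid. Speeds are central
finite differences (one-sided at the ends; second-order accurate on the
uniform sampling). Events are windowed to the 30 samples at 1-based raw
indices 3..32 — the stated retained count (30) and total (4,200) fix the
off-by-one in "3rd to the 33rd", which spans 31 indices.

Because pixels and centimetres are dimensionally incompatible, model
inputs are decorrelated and whitened (ZCA, C^{−1/2} with a 1e−9·tr(C)/d
ridge) using statistics fitted on training folds only. Two whitenings
exist with different jobs: a 4-feature (x, y, z, speed) whitening as the
interchange normalization for trajectory data, and the fall map's own
2-feature whitening of its projected pair. The map projects the **raw**
(z, speed) pair and then whitens in 2D: whitening the full 4D space
first and then taking two axes would let the decorrelation subtract the
image-row component from z — precisely the shared fall signal — and
collapse the cluster separation (measured as a drop of full-scale CV
accuracy from 0.88 to 0.63).

## 3. DDFT clustering

Density: full-covariance Gaussian mixture (scikit-learn EM; n_init = 5
restarts, tol = 1e−6, covariance floor 1e−6, best restart by
log-likelihood, deterministic given the seed). Energy functionals, on
the fitted density ρ:

* kinetic t = 2π²ρ; potential u(r) = ½ Σᵢ ρ(rᵢ′)/‖r−rᵢ′‖ with
  coincident points (distance ≤ 1e−9 in normalized units) excluded;
* γ = ½⟨u⟩/⟨t⟩; H = γ²t + γu; L = γ²t − γu.

Identities used as tests: t = 2π²ρ, H+L = 2γ²t, H−L = 2γu pointwise,
and ⟨H⟩ = ¾⟨u⟩²/⟨t⟩ = −3⟨L⟩ over the points that define γ.

**Cluster number.** For K = 1..K_max (default 6) the mixture is refitted
and ⟨H⟩ over the data recorded (γ recomputed per K, since each K defines
its own density; the mean over points is used as the per-K scalar for
sample-size invariance). The selected K* is the smallest K from which
every later curve gap |⟨H⟩(K′+1) − ⟨H⟩(K′)| stays within ε = 0.05 of the
first gap |⟨H⟩(2) − ⟨H⟩(1)| — the slope-stabilization ("turning") point.
A curve that never settles returns K_max with a warning.

**Boundaries.** Cluster boundaries are the marching-squares zero
contours of L on a padded grid over the data bounding box (default
200×200, 10 % padding). Two numerical choices matter here. First, the
γ used for the boundary map is the global average of u and t over the
*map domain*, not over the data points: averaged over the data alone,
γ²t never reaches γu anywhere for Gaussian-shaped clusters (the fitted
density at a cluster peak is at most about twice its data average, while
the potential at the peak exceeds its own), so the balance set would be
empty and no boundary could exist. The energy surfaces and the
Hamiltonian curve keep the data-point γ, which the mean identities
require. Second, that domain average is taken on a fixed internal
97×97 quadrature so the zero set does not drift when the display grid is
refined; contours enclosing less than two grid cells are discarded as
discretization speckle.

## 4. The fall map and alarm

The map carries a two-component mixture in the whitened (z, speed)
plane (if K* ≠ 2 the two most-weighted components are kept, with a
warning). States: Mahalanobis distance ≤ 1.5 to the normal component →
normal; else ≤ 1.5 to the fall component → fall; else transition. The
priority order (normal > fall > transition) resolves measure-zero ties;
1.5 standard deviations is read as a per-component Mahalanobis ellipse,
the only multivariate reading that gives each cluster a closed region.
Note the designed trade-off: a Gaussian cluster keeps ~32 % of its own
mass outside its 1.5-SD ellipse in 2D, so some normal samples always
land in the transition zone — false alarms are preferred to misses.

Cluster roles: when the training events are available, the component
whose mean is nearest the centroid of the events' first samples is
"normal" (streams begin in normal motion). This supersedes the
intensity/scatter asymmetry (normal = higher density peak, smaller
generalized variance), which remains the fallback for deserialized
models without event context: with a terminal lying-at-rest cluster,
both indicators can agree on the wrong component when the data are
nearly noiseless.

Alarm machine per event stream: transition or fall → alarming; the
first fall latches; normal silences an unlatched alarm; the machine
turns off 5 s after the latch (the platform's shutoff rule). Lead time
is true fall onset minus first alarm; alarms arriving after the onset
are excluded from the mean and counted as late.

## 5. Evaluation

Positive class = {transition, fall}; negative = {normal}. Metrics:
accuracy (TP+TN)/n, sensitivity TP/(TP+FN), precision TP/(TP+FP); zero
denominators are flagged undefined, never reported as 0. The default
cross-validation is a seeded 10-fold partition of *events* (14 test
events per fold, each event tested exactly once); fusion is per-event
and stateless, and both whitenings and the fall map are refitted per
training fold, so no test statistic reaches training. A `repeated_cv` mode
instead draws 10 random test events per repetition for 10 repetitions,
matching the platform's described protocol, which with 140 events
cannot cover every event in 10 folds. Pooled (micro-averaged) counts
are primary; per-fold and macro-averaged metrics are reported alongside.

## 6. Problem sizes in the test suite

The acceptance tests run the canonical 140-event dataset for the
cluster-number checks (including 20 seeded replicates), a 40-event
dataset for the energy-identity and boundary-stability checks, and a
30-event noiseless dataset for the end-to-end exactness check; unit
tests use ~20-event datasets. These sizes keep the full suite within a
few minutes while leaving every statistical margin intact (the 20
replicates at full scale are the binding cost).

## 7. Known limitations

* The DDFT boundary map is descriptive; classification uses the 1.5-SD
  ellipses, and the two region definitions are not identical.
* The Hamiltonian-curve rule depends on ε and on the GMM fits; on data
  whose in-between band is dense rather than sparse, the curve keeps
  gaining after K = 2 and selection honestly reports a larger K.
* Lead times on synthetic data reflect the configured transition
  duration, not human biomechanics.
* The simulator emits one subject per stream; multi-person scenes and
  non-fall activities are out of scope.
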