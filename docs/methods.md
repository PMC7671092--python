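# Methods

`skullkin` models the kinetic skull of a suction-feeding fish — specifically
a channel-catfish-like configuration of the mandibular arch, hyoid arch and
pectoral girdle — as a spatial multi-loop ("parallel") linkage, and provides
the analyses that such a model supports: joint-model fitting, mobility
accounting, sequential DoF-freezing model selection, and classification of
cranial expansion waves together with the food motion they produce.

## The mechanism model

Rigid skeletal elements are links; articulations are ideal lower-pair joints
of four types: revolute (1 DoF), universal (2), spherical (3) and prismatic
(1). Compliant soft tissues that tie the loops together — the left and right
interoperculomandibular (IOM) ligaments and the sternohyoideus muscle — are
struts: two half-links joined by a prismatic slider with a spherical joint
at each end, so a strut transmits position but leaves its length and
long-axis spin as explicit coordinates.

The bundled skull fixture has 14 skeletal elements (neurocranium fixed,
urohyal, and left/right suspensorium, mandible, operculum, hyoid,
post-temporal, cleithrum) plus the three struts. Counting each strut's
prismatic pair as a single link — the convention used when such mechanisms
are tallied in the comparative literature; the sliding DoF then rides on a
composite ball-and-slide end joint — the census is 17 links and 21 joints
with summed joint DoFs 49, five independent loops, and spatial
Chebychev–Grübler–Kutzbach (CGK) mobility 6(17−1−21)+49 = 19. The merge is
exactly neutral: the structural view (20 links, 24 joints) gives the same
loop count and the same mobility, and the constraint-Jacobian nullity at
the reference (and at perturbed, generically posed) conformations is also
19, so the formula is not being rescued by a counting convention.

The per-articulation joint types are this fixture's own assignment (the
literature prints only the totals): revolute suspensorium and girdle
suspensions, universal jaw, opercular and midline-girdle joints, spherical
interhyal and hyoid–urohyal joints. Two structural consequences are worth
flagging because they are decisions, not derivations:

* **The pectoral girdle loop is a rigid frame.** The
  neurocranium–post-temporal–cleithrum ring sums to exactly six joint DoFs,
  so at generic conformations it contributes no mobility — consistent with
  the heavily sutured catfish girdle and with the absence of girdle labels
  in the 19-parameter set. Both midline-joint axes must leave the
  midsagittal plane: with in-plane axes the loop's symmetric constraint
  block is structurally rank-deficient and the build refuses the geometry.
* **There is no mandibular symphysis joint** (it would break the joint
  census). The left and right jaws couple only through the loops, so the
  asymmetric-jaw parameter C is invisible to left-side-only markers; it
  behaves as a zero-cost flat direction in unilateral fits, analogous to a
  ligament length with no discernible effect.

### Parameterization

The 19 mobility DoFs carry labels A–S, grouped as 3 soft-tissue lengths
(A, B, L — left IOM, sternohyoideus, right IOM, in mm), 4 asymmetric
midline motions (C–F), 4 opercular rotations (G, H left; M, N right),
mandibular depression I, suspensorial abduction J, hyoid depression K, and
5 long-axis spins (O–S: left/right hyoid plus the three struts — precisely
the links with spherical joints at both ends). Every parameter is a linear
functional of the 49 joint coordinates (symmetric/antisymmetric pairs of
mirrored joints, raw coordinates, or rest-length offsets), which keeps the
input map exactly linear and lets the build verify, by rank, that the 19
pins are independent of the 30 loop-closure constraints.

Signs follow anatomy: positive I/K depress, positive J/G abduct, positive H
flares out; mirrored joints store sign-flipped axes so equal left/right
coordinate values produce bilaterally symmetric motion.

## Numerics

**Loop closure.** A spanning tree rooted at the neurocranium poses all
links; each of the five chord joints contributes a 6-vector residual
(axis-angle rotation expressed in the chord child's frame — invariant to
common-mode motion of the two branches, which is what makes the analytic
screw-axis Jacobian accurate to second order in the residual — plus
translation in mm). Forward kinematics solves the 49 coordinates under the
19 linear pins by damped Newton with a least-squares step (so redundantly
constrained loops, e.g. a planar four-bar written spatially, are handled
transparently), a 0.5-step trust cap, and continuation: if a parameter step
cannot be tracked, the step is bisected along the straight parameter path
from the warm start. Branch selection is therefore by continuation, never
global search. Closure tolerance is 1e-10 (rad / mm mixed residual).

Soft-tissue lengths can be left *free* in a forward solve: they settle to
whatever closure requires, which is how the synthetic generator lets
ligaments and the sternohyoideus follow the skeleton instead of being
driven. This matters: holding all three lengths at rest is kinematically
infeasible beyond small hyoid depression — shortening under hyoid
depression is precisely the sternohyoideus' job.

**Mobility oracle.** `numeric_mobility` computes the nullity of the
30×49 closure Jacobian (SVD, relative threshold 1e-8). It equals the CGK
value on the fixture and on generic single-loop mechanisms, and disagrees
exactly where CGK is known to be misled (planar four-bar in the spatial
formula: CGK −2, true mobility 1), which the tests assert as a feature.

**Frame fitting.** Fitting input parameters to one motion frame minimizes
the RMS distance between model-animated and observation-animated fit points
(three landmarks on each scored element). All 49 coordinates are optimized
together by Levenberg–Marquardt with closure and frozen-parameter pins as
quadratic penalties annealed over weights (1e3, then 1e5), each stage
warm-starting the next. The graded penalty is deliberate: a heavily
restricted model (e.g. soft-tissue lengths frozen at their means) can sit
*exactly at its feasibility boundary*, where a hard constrained solve
stalls; the annealed penalty approaches the boundary smoothly and leaves
closure violations near 1e-6 mm — far below any reported error. Noise-free
self-fits recover parameters to machine precision.

**Joint-model fitting.** For an articulated pair, revolute, universal and
spherical models are fit to the observed relative poses by nonlinear least
squares over center and axes with five seeded restarts; the per-frame joint
coordinates are solved in closed form (revolute: an atan2 expression;
spherical: Kabsch; prismatic: projection) or by coordinate descent over two
revolute solves (universal). Initialization uses the classic fixed-point
estimate for the center and the principal directions of the relative
rotation vectors for axes. Model selection takes the lowest-DoF model whose
fit RMS is within 1.5× tracking precision or within 1.10× the spherical
RMS (both configurable); ties go to the lowest DoF.

**Sequential freezing.** Starting from the measurable parameter set (the
five spins and three right-side parameters are frozen a priori — they are
not observable from unilateral bone markers), the scan repeatedly
trial-freezes each remaining free DoF at its trajectory mean, refits a
fixed sample of maximally disparate frames (greedy maximin selection,
deterministic, 15 frames by default), and permanently freezes the DoF with
the smallest increase in the pooled error statistic, down to the zero-DoF
akinesis model. The statistic is the median by default, matching how freeze
curves are drawn as box plots; the tests use the mean because with five
scored elements a localized single-element effect can vanish entirely in
the median of a 15-point distribution. Ties resolve in label order, making
runs reproducible. Errors are reported pointwise (3 points × 5 elements ×
15 frames = 225 measures per step) in mm and as % of head length.

Three benchmarks judge the curve: tracking precision (RMS deviation of
intra-element marker configurations from their consensus over 50 random
frames), inter-individual variation (RMS landmark deviation from a
Procrustes consensus, scaling off so values stay in mm), and a percent
scale spanning the median errors of the highest- and lowest-parameter
models. `sufficient_dofs` returns the smallest free-DoF count whose error
passes a chosen criterion and also reports the bilateral-equivalent count:
a unilateral model keeping G and H free while their unmeasured twins M and
N are frozen corresponds to a bilateral model with two more DoFs (5 → 7).

## Wave classification

Event windows of 0.5 s are centered on peaks of gape (mandibular
depression) and/or opercular flaring out; peaks closer than half a window
merge into one event. Classification is an explicit quantitative surrogate
for expert labeling, with thresholds collected in one config object:
amplitude-dominance ratio 0.1, peak-order margin 5 ms, slow-open rise time
250 ms. Per-DoF peak times are estimated as the centroid of the contiguous
above-60%-of-peak region rather than a raw argmax — for broad bumps seen
through noise this cuts peak-time jitter well below the inter-stage lags
the rules compare. Rules, in order: slow-open (dominant gape, rise time above
threshold, where a gape already elevated at the window edge counts as
"at least window-long"); compressive (minimal gape, hyoid elevation before
peak flaring); rostrocaudal (substantial gape, mandible peaks first,
opercular rotations last); caudorostral (flaring first, mandible last);
otherwise unknown. The rules use only ratios and time differences, so
classification is invariant to uniform amplitude scaling and time shifts.
Aligned events (gape peak for rostrocaudal/slow-open, flaring peak for
caudorostral/compressive) are resampled to a common relative grid and
aggregated as mean ± standard error, optionally with the prey's
rostrocaudal velocity (low-pass smoothed central differences of the
rostrocaudal coordinate; positive = caudally directed; events overlapping
excluded prey frames are dropped).

## Synthetic data

The generator emulates a 300 Hz X-ray motion-capture study: Gaussian
bump-train trajectories on the five primary DoFs (bump width 80 ms,
inter-stage lag 20 ms, per-event timing jitter 4 ms and amplitude jitter
8%), four built-in class templates whose peak orders and prey-velocity
pulses encode the qualitative contrasts between wave types (sharp caudal
prey pulse at peak gape for rostrocaudal; slower, broader rostral pulse
~100 ms after peak flaring for caudorostral; an order-of-magnitude weaker
caudal pulse for compressive), forward-kinematics-consistent marker
observations on a unilateral eight-element marking scheme (4 markers per
element by default) with iid Gaussian noise (0.08 mm default, the precision
of good biplanar fluoroscopy) and Bernoulli missingness, and per-frame
ground truth that includes the settled soft-tissue lengths. Per-DoF
amplitudes (tens of degrees for mandibular/hyoid motion, less for opercular
rotations) are order-of-magnitude choices; no published numeric trace
values stand behind them. All randomness flows from one seed through named
substreams (markers, noise, missingness), so recordings are bit
reproducible.

What the generator does *not* emulate — and hence what passing tests do not
establish about real recordings: soft-tissue compliance beyond ideal
struts, non-rigidity of skeletal elements, calibration drift or
heteroscedastic tracking error, genuinely asymmetric behavior, and prey
that interacts mechanically with the skull rather than following a
prescribed velocity template.

## Scales used in the shipped analyses

The bundled tests and the pipeline default to desk-scale problem sizes
chosen to exercise every code path at full numerical strictness: freeze
scans over 4–15 sampled frames starting from 5–8 free DoFs, recordings of
one to four events, and classification corpora of 200 events. The same
code paths run unchanged at larger sizes.

## Known limitations

* Euler-angle spherical coordinates can in principle approach gimbal
  alignment in extreme poses; the shipped geometry keeps working ranges
  far from it, but user-supplied geometries are not checked for this.
* The greedy freeze order is a heuristic; like any greedy selection it can
  differ from the globally optimal freezing set when candidate effects are
  strongly coupled.
* The unilateral identifiability flag is computed from the observation
  Jacobian's null directions at a conformation; a parameter that is only
  *weakly* observable (small but nonzero column) is not flagged.
* Restricted models at their feasibility boundary are solved to a closure
  violation of ~1e-6 mm rather than exactly; reported errors are insensitive
  to this at the 1e-4 mm level.
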