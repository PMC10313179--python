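# Methods

This note documents the models, parameter choices and numerical conventions
behind `flytrax`, and what the synthetic test substrate does and does not
establish about real data.

## Coordinate and unit conventions

All geometry is in image coordinates: origin at the top-left, x rightward,
y downward, pixel units, 0-based frame indices. Headings are an exception:
they are reported in a y-up mathematical frame (image y negated), in
(−π, π], so that 0 points right and +π/2 points up on screen. Every unit
conversion goes through `ArenaConfig`: pixel distances × `mm_per_px` give
millimetres, frame counts ÷ `fps` give seconds, and per-frame pixel
displacements × `mm_per_px` × `fps` give speeds in mm/s. The default
`fps` is 30 (the standard group-assay frame rate) and the default chamber is
a 4 cm diameter circle, the standard group-courtship arena, converted to
pixels through `mm_per_px`.

## Tracking: greedy distance-sort

The linker assumes a closed chamber with a fixed population. IDs 1..k are
assigned in the first populated frame in ascending (y, x) of the body
centroid — the ordering itself is arbitrary, but it must be deterministic
for reproducibility. In each subsequent frame all candidate
(track, detection) pairs with centroid distance ≤ `gate_px` (default 30 px)
are sorted ascending by distance (ties broken by track id, then detection
(y, x)) and accepted greedily while both sides are unmatched. This global
sort is order-independent and deterministic, unlike per-track nearest
neighbor in file order.

A track with no match emits a *coasting* point: identical geometry to its
last observed point, flagged unobserved, indefinitely — there is no coasting
timeout, so a fly that disappears keeps its ID parked at its last position
until something reappears within the gate. Under `fixed_population`
(default) surplus detections are dropped with a log entry rather than
opening new tracks; every input body detection is either attached to exactly
one track point or logged as dropped, so counts reconcile exactly.

Greedy matching is provably identical to per-frame optimal (Hungarian)
assignment whenever every fly's nearest detection is its own continuation —
guaranteed when the minimum inter-fly gap exceeds twice the maximum
per-frame displacement. The test suite verifies this equivalence against
`scipy.optimize.linear_sum_assignment` on 100 simulated 13-fly, 1,000-frame
scenarios built to satisfy that regime, and verifies that one scripted
crossing which defeats greedy matching is fully repaired by a single
pairwise ID swap. Corrections are pairwise swaps from a frame onward — the
minimal invertible primitive (each correction is an involution), chosen
because richer review-GUI semantics reduce to sequences of such swaps.

Heads are assigned to the body track with the largest head-box overlap
fraction (ties to the nearest centroid), requiring at least
`head_overlap_min` = 0.25 of the head box area; the heading is the angle of
the body-centroid → head-centroid vector.

## Behavior events

Two event routes exist and produce the same `BehaviorEvent` records
(half-open frame intervals, typed chase / wing_ext / mount, actor and
optional target):

* **Detector attribution**: behavior boxes from a trained detector are
  attributed to the two best-overlapped tracks (one for wing extension).
  For chases and mounts the actor is the member whose heading points toward
  the other; a singing fly's optional target is the nearest fly inside its
  heading cone (half-angle 30°). Boxes covering fewer tracks than required
  are dropped and logged.
* **Kinematic classification**: for pipelines without a trained event
  detector, a chase is declared per (actor, target, frame) when the gap is
  ≤ `d_max_mm` (5 mm), the actor moves at ≥ `v_min_mm_s` (2 mm/s), and the
  actor's heading is within `align_max_rad` (30°) of the bearing to the
  target. A fly is the actor of at most one chase per frame (smallest gap
  wins, then smallest alignment angle). Runs are bridged over gaps of
  ≤ `merge_gap_frames` (5) and kept at ≥ `min_frames` (15, i.e. 0.5 s at
  30 fps). Frames without a head-derived heading fall back to the velocity
  direction; stationary headingless frames are unclassifiable as actor.

The kinematic thresholds are package conventions, chosen at the scale of a
2.5 mm fly walking at a few mm/s (one to two body lengths of pursuit
distance, a speed floor above idle jitter, a pursuit cone generous enough
for curved paths); all are exposed on the CLI and in `ChaseParams`. They
are not measured constants, and the frame-level recovery the tests
demonstrate is on noiseless scripted pursuit, not on real trajectories.

## Chaining

The chaining criterion — two or more chase relations meeting in one group of
at least three flies — is formalized per frame on the directed chase graph:
weakly connected components with ≥ 2 collapsed edges and ≥ 3 flies are chain
components, and the frame's chain count is B(d) = Σ (|component| − 1).
This formalization simultaneously (a) counts two chasers of one target as a
chain, (b) matches the group-assay definition of at least three flies
engaged in courtship, and (c) yields B(d) = N − 1 = B(max) for a single
path or ring through all N flies. Duplicate edges collapse first, and a
mutual chase within one pair (1→2 and 2→1) is deliberately not chaining:
it has only two flies. Whether a per-frame chain "event" should instead be
counted per component or per edge is ambiguous in common usage; the
component-sum definition above is used consistently everywhere, and the
per-frame series is exported losslessly for rug plots.

## Indexes and metrics

`Index = B(d)/B(max) × 100%` is evaluated per frame and averaged
arithmetically over the observation (snapshot counts generalize to long
recordings only through a time aggregate; the per-frame series is retained).
B(max) is N for chasing and singing and N − 1 for chaining, so groups need
N ≥ 2. Event counts exceeding B(max) — possible with noisy detector input —
are capped with a warning so the index stays in [0, 100] by construction.

Undefined ratios are reported as missing (`None`/JSON null), never 0: a
male that never courts has no preference index, and zero observed frames
give no courtship index. Zero is a meaningful measured outcome and must
remain distinguishable.

Descriptive-metric thresholds (all configurable, `MetricParams`): neighbor
radius 5 mm; encounter = pair within 5 mm for ≥ 15 frames; foraging visit =
≥ 30 frames (1 s) inside the food region, with excursions < 15 frames
bridged, while dwell time counts all in-region frames regardless of visit
gating; locomotion cutoffs 0.5 and 10 mm/s between resting / walking /
running, and a jump is a single-frame displacement ≥ 4 body lengths
(body length default 2.5 mm). These defaults are package conventions at
fly scale, not measured constants. Speeds use forward differences (frame f
to f+1; the last frame reuses the previous step) and coasting frames are
classed as resting, since a coasting track reports no real motion.

## Synthetic arena

The simulator emulates the *output of a detector watching a chamber*, not
fly biomechanics: axis-aligned 12×6 px body boxes (≈ 2.5 mm at the default
0.05 mm/px) and 6×6 px head boxes centred 4 px ahead of the centroid along
the heading. That head geometry guarantees at least one third of the head
box overlaps its own body box at every orientation, so head assignment
never starves; a smaller or farther head box would have zero body overlap
for whole orientation ranges.

Undirected flies perform a Gaussian random walk (σ = `step_sigma_px`,
reflective chamber wall) with the step norm clipped at 3σ. The clipping
gives a hard per-frame displacement bound, which is what lets scripts
guarantee the "minimum gap > 2 × maximum step" regime of the tracking
equivalence tests by construction. Scripted directives overlay behavior:
chases put the target on a circular orbit (radius 2 × gap) at a constant
walking speed with the actor riding the same orbit one chord of the gap
behind, heading locked on the target, so the gap, speed and alignment of
the pursuit geometry are exact in every frame; rings rotate all members on
a common circle, each chasing the next; `goto_food` walks a fly into the
food region; `decapitated` pins a fly in place; `tether` confines a fly's
walk to a disc. Orbits without an explicit centre anchor at the target's
position when the chase starts, avoiding positional jumps; directives with
an explicit centre reposition their flies at the start frame, so
tracking-oriented scripts should start such directives at frame 0.
Detection noise is optional per-fly-frame dropout and Gaussian centroid
jitter. All randomness flows from a single seeded generator
(`numpy.random.default_rng`), and outputs are byte-identical for the same
script and seed.

The two bundled worked-example scenarios are fully scripted (no random
motion): five simultaneous chase pairs on orbit centres spread 250 px from
the chamber centre — spacing chosen so distinct pairs always stay farther
apart than the 5 mm chase gate, making the per-frame chase count exactly 5 —
and a ten-fly ring. Through the full pipeline they give chasing indexes of
exactly 50% and 100%.

What passing these tests shows: the linking rule, event logic, chaining
formalization and metric arithmetic are correct on inputs whose ground
truth is known exactly. What they do not show: robustness to real detector
noise statistics (correlated misses, box drift, identity-confusing
occlusions), real fly kinematics, or the accuracy of any particular trained
detector. The kinematic chase classifier in particular is a surrogate for a
detector-based event stream, with its own thresholds.

## Problem sizes and numerical choices

The test suite runs at desk scale: 13-fly groups (the standard group assay
size), 100–1,000 frame clips, 100 tracking-equivalence scenarios, 1,000
random digraphs and 1,000 random point configurations for the oracle
comparisons; the acceptance script simulates 300 frames (10 s at 30 fps)
per worked example, enough for the per-frame index to be constant over the
whole clip. Nearest-neighbor and neighbor-count comparisons against the
O(N²) brute-force oracle are exact (same elementary distance operation);
headings round-trip through files at 6 decimal places (≈ 10⁻⁶ rad);
tie-breaks everywhere are documented and deterministic (ascending distance,
then id, then (y, x)). File writers emit rows in a canonical sort order so
identical in-memory objects always produce byte-identical files.

## Known limitations

* Chase attribution assumes at most one behavior box per (pair, frame);
  overlapping boxes of the same class at the same frame merge into one
  interval.
* The kinematic classifier cannot see wing extension or mounting; those
  types come only from detector boxes.
* Corrections are pairwise swaps; three-way identity rotations need two
  corrections.
* The simulator's dropout is independent per fly-frame; real detectors miss
  in bursts.
* Rendering asserts on numeric tables; PNG bytes depend on the raster
  backend and are not part of any contract.
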