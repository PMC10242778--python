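# Methods

This note documents the models, parameters and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Data model

A localization table is the native unit: one row per fluorophore blink
event, with a 1-based acquisition frame index, x/y coordinates in
nanometres (as exported by ThunderSTORM-style reconstruction software; no
pixel↔nm conversion is performed here), and optionally an intensity on the
photon-count scale and a localization uncertainty. Operations never assume
rows are sorted by frame. Row-level filters follow fixed boundary
conventions: the intensity filter keeps values equal to the threshold
(strictly-lower values are discarded), and frame restriction is inclusive
on both ends, with surviving frames re-indexed to `1..n` so that the
detection statistics normalize over the analyzed range only.

## Fiducial detection

Beads are identified by stable emission. Candidates are seeded as every
localization of the densest frame (ties broken to the lowest frame index
for determinism); each candidate is scored over the `n` analyzed frames by
the mean and population variance (divisor `n`, zero-count frames included)
of its per-frame neighbor count within radius `r`, using a strict `< r`
Euclidean criterion. Neighbor search uses a KD-tree; because scipy's
ball query is boundary-inclusive, points at exactly `r` are explicitly
excluded to preserve the strict inequality (the unit tests pin KD-tree ==
brute-force equality).

Parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `r` | 100 nm | neighborhood tolerance = bead diameter |
| `mt_min` | 0.5 | minimum mean per-frame neighbor count |
| `vl_max` | 0.25 | maximum count variance across frames |
| `frame_first/last` | full range | analysis window, for late-bleaching beads |

The MT/VL pair is discriminative because a blinking structure bright
enough to reach `MT ≥ 0.5` has approximately Poisson frame-to-frame counts,
hence variance ≈ mean ≥ 0.5 > 0.25, while a constant emitter has
Bernoulli-level variance `p(1−p) ≤ 0.25`.

Two post-processing choices are this package's own. First, one physical
bead seeds several passing candidates (every one of its localizations in
the seeding frame), so candidates within `r` of a kept candidate are merged,
keeping the highest-MT one (ties: lowest VL, then lowest x, then lowest y —
a deterministic total order). Second, the kept position is refined to the
centroid of all in-radius localizations over the analyzed frames, giving a
bead-centre estimate with standard error ~ `σ/√support` instead of
single-frame jitter `σ`.

**Known limitation.** An emitter that is off in the seeding frame cannot
be detected at all — no candidate is placed near it. With always-on beads
this never happens; with beads on in 95% of frames and structured signal
contributing Poisson counts to the frame totals, the densest frame lacks
some bead in roughly 10% of simulated fields. This is an inherent property
of densest-frame seeding, visible as sub-100% sensitivity on real
recordings, and is why the sensitivity guarantee in the test suite is
stated for constant emitters.

## Cluster mode

Without beads, landmarks are the densest localization clusters: every
localization is ranked by its neighbor count within `r_c` (default 750 nm)
pooled over all frames (the count includes the localization itself), and
the top `k = 25` are retained. A literal top-k would take all `k` points
from the single densest cluster, which cannot anchor a rigid fit, so by
default candidates within `r_c` of a higher-ranked selection are
suppressed, yielding up to `k` spatially distinct cluster landmarks;
`suppress=False` reproduces the literal ranking. Note the retained landmark
is a member localization, not a centroid: when `r_c` is much larger than
the cluster extent all members have near-identical counts, so the landmark
sits at a single-draw distance (~ the cluster σ) from the true centre.
Cluster-scale landmark noise is handled downstream by the ICP outlier
rejection and only limits registration accuracy to the tens-of-nm scale.

## Rigid registration

The channel misalignment model is rigid: rotation θ about the coordinate
origin followed by translation (tx, ty), det R = +1, no scaling or shear.
`estimate_rigid` solves the landmark least-squares problem in closed form:
subtract centroids, form the 2×2 cross-covariance `H`, take
`θ = atan2(H01 − H10, H00 + H11)` (the planar Kabsch/Procrustes solution,
which cannot produce a reflection), and recover the translation from the
centroids. Degenerate inputs (fewer than 2 pairs, or all moving points
coincident) raise instead of returning an arbitrary rotation.

ICP iterates: nearest reference neighbor for each moving landmark
(moving → reference direction), outlier rejection, rigid fit on the
inliers, update. The accumulated transform is composed exactly across
iterations (angles add; translations compose through the rotation), never
re-fit from scratch, and maps original moving coordinates to reference
space. Convergence is declared when the inlier mean distance changes by
less than 1 nm between consecutive iterations; a 100-iteration cap guards
against oscillation (reaching it emits a warning and `converged=False`).

Outlier rejection discards pairs with distance above mean + 1 SD of the
current round's distances. Two refinements make this rule robust when
20–50% of landmarks exist in only one channel:

1. **Recursion.** After discarding, mean and SD are recomputed on the
   survivors and the rule re-applied until stable. A single pass is not
   enough: spurious-pair distances are heavy-tailed, and one very distant
   pair inflates the SD so that moderately distant spurious pairs stay
   inside the cut and drag the fit into a contaminated equilibrium.
2. **Materiality and majority guards.** A pair is only discarded if its
   distance is also at least twice the surviving mean (and above an
   absolute 1e-6 nm floor), so a unimodal distance distribution — early
   iterations, or pure numerical noise after convergence — is never
   trimmed; and trimming keeps at least max(3, n/2) pairs, so the fit
   always follows the majority correspondences rather than chasing a
   small low-distance minority.

Identity initialization is used: pre-registration misalignment on real
instruments (≲ 1.3 µm) is small against typical landmark spacing. The
documented failure mode is misalignment exceeding half the landmark
spacing, where the first nearest-neighbor assignment can lock onto wrong
correspondences.

## Evaluation metrics

**TRE** is the Euclidean distance between index-matched landmark
coordinates in two channels, summarized as mean ± sample SD (divisor
n − 1, matching the usual mean ± SD reporting). Manual annotations are
snapped to the nearest localization of their channel before computing TRE
(ties to the lowest row index), removing hand-click jitter.

**NCC** correlates pixel intensities of two images rendered on the same
grid: each localization deposits a unit-integral 2-D Gaussian (pixel-
integrated via the error function over a ±5σ support window; σ = 0 gives a
plain histogram). Default render σ is a fixed 20 nm rather than
per-localization uncertainties, which may be absent from the input. The
default field padding is 6σ so that total intensity equals the in-bounds
localization count to well below 1e-4 relative error. NCC uses population
standard deviations, is clipped to no range (mathematically in [−1, 1]),
raises on zero-variance images, and is invariant to affine intensity
rescaling.

**Significance** of TRE change uses the two-sided Wilcoxon signed-rank
test (exact null distribution at these sample sizes, via scipy), with the
conventional 0.05 level reported alongside. All-zero differences return
p = 1 with a warning rather than an error.

## Synthetic data

The generator emulates what this pipeline consumes, not the microscope:
fiducials emit per-frame Bernoulli(on_prob) with isotropic Gaussian
localization jitter; filaments and clusters emit Poisson-distributed
blinks per frame (uniform along a polyline / Gaussian around a centre);
all coordinates are mapped by a per-channel rigid misalignment; optional
exponential bleaching thins localizations with probability
`2^(−frame/half_life)`. Defaults: a 33.28 µm square field (256 pixels at
130 nm), 2000 frames, beads on in 95% of frames with 10 nm jitter, beads
placed by dart-throwing with ≥ 1 µm spacing (10 bead diameters) so landmark
correspondences are unambiguous. Tests shrink to 300–500 frames where the
statistics are scale-free in the frame count.

Not emulated: dye photophysics (switching kinetics, duty-cycle variation),
camera noise and PSF-fitting artifacts, within-channel drift, chromatic
magnification differences (a non-rigid effect), and intensity-dependent
localization precision. Passing tests therefore demonstrate the
correctness of detection, fitting and metrics under the stated noise
model — not robustness to every real-world artifact; on real data the
practical accuracy limit is set by bead stability and annotation quality.

The end-to-end test conditions: transform recovery uses 5–20 beads, jitter
σ ∈ {0, 10, 30} nm, misalignment up to 2 µm and 0.02 rad, with 20–50%
spurious beads per channel; detection sensitivity/precision fields use
constant emitters ≥ 3r apart with bright blinking filaments (30
blinks/frame, making the VL criterion load-bearing near filament
crossings); cluster-mode fields use ten 50 nm-σ clusters at ~2 blinks per
frame each. Problem sizes keep the full suite under a minute of compute
while leaving every statistic in its asymptotic regime.

## CLI

The `smlm-register` tool exposes the pipeline as `simulate`, `detect`,
`register`, `evaluate` and `run` (a YAML job list mirroring batch
registration sessions: per-job reference, moving channels and parameter
overrides; jobs are isolated, and the exit code is 0 only if all succeed).
Corrected tables are written in the input's own CSV dialect so they remain
re-importable by the upstream reconstruction software.
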