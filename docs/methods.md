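# Methods

`knottrack` segments and tracks a single fluorescently labeled
filament whose 2-D projection self-intersects ("knots") during a
motor-driven gliding assay with one end clamped. This note documents
the models, algorithms, parameters, and design choices.

## Problem setting

A clamped filament driven by surface motors bends into traveling
waves. When the bending is strong enough the projected contour crosses
itself, and a thinned binary skeleton of the image acquires branch
points. Ordering skeleton pixels into a contour is then ambiguous: at
each junction the walk can continue onto either strand. The package
resolves the ambiguity with a graph representation of the skeleton and
template matching against the previous frame's resolved contour.

## Synthetic ground truth and image formation

Real assays give no per-pixel ground truth, so the package ships an
image-formation model that emulates them.

**Traveling-wave filament.** The tangent angle along arc length `s`
(pixels) at time `t` is

    psi(s, t) = theta0 + c0 * s / L + A * (s / L) * sin(2*pi*(s/lambda - t/T))

with clamp orientation `theta0`, static curl `c0` (total tangent
rotation of the rest shape; pinned filaments rarely relax straight,
and a nonzero curl breaks the mirror symmetry of the beat so the
end-to-end distance oscillates at the beat period rather than twice
it), peak amplitude `A` (radians, reached at the free tip via the
linear ramp `s/L`), spatial wavelength `lambda`, and period `T`.
Positions come from midpoint-rule integration of `(cos psi, sin psi)`
at 0.5 px arc steps, so the contour is inextensible by construction
(arc length conserved to well under 1%). Defaults: 120 frames at 10 s
intervals (a 20 min movie), 0.1 um pixels, lengths 5-50 um supported.
The amplitude needed for self-intersection under this ramp is about
3 rad; below ~2.5 rad the contour stays simple.

**Loop-closure scenario.** Knot-resolution accuracy is exercised on a
dedicated two-frame "hook" sequence (`generate_loop_closure`): a
straight tail, a circular arc whose total turn grows between frames,
and a straight exit strand. At full closure (turn 3*pi/2) the exit
crosses the tail transversally at 90 degrees — the canonical
template-then-knot test case. The perpendicular crossing is a
deliberate choice: skeletonizing the fused blob of a shallow crossing
biases the medial axis toward the wedge bisector by ~2 px, which no
downstream step can undo (see Limitations).

**Image formation.** Ground-truth curves are rasterized (dense samples
rounded to the grid, then thinned to an 8-connected one-pixel-wide
skeleton; every lit pixel lies within 0.71 px of the continuous
curve), dilated with a radius-2 diamond structuring element (13-pixel
footprint), convolved with a normalized 3x3 Gaussian point-spread
function of sigma 2 — reproducing the unusually large sigma-to-support
ratio as printed in the source workflow — and rescaled to [0, 1].

**Noise.** The Gaussian model defines the SNR: `P_signal` is the
variance of the clean image, `SNR_linear = 10^(SNR_dB/10)`,
`P_noise = P_signal / SNR_linear`, and the additive noise is
`sqrt(P_noise) * N(0, 1)`. Noise is left unclipped so the realized
noise power matches the request exactly (empirically within 0.5 dB);
segmentation re-normalizes intensities anyway. Salt-and-pepper noise
(a fraction of pixels forced to 0 or 1 with equal odds) is also
provided; the Gaussian model is the default because it is the one
with a defined SNR relation.

## Segmentation

Per frame: saturate the top and bottom 1% of intensities, rescale to
[0, 1], median-filter with a 3x3 window; threshold by Otsu's method
(or a user-supplied normalized threshold); keep the largest
8-connected component (single-filament assumption; noise specks are
smaller); refine with a two-phase piecewise-constant active contour
(morphological Chan-Vese) seeded by the threshold mask; skeletonize
with the medial-axis transform.

Parameter mapping for the active contour: `ac_iterations` is the
iteration count (default 10); `smooth_factor` (default 0.2) times ten
gives the morphological smoothing passes per iteration;
`contraction_bias` re-weights the inside/outside data terms
(lambda1 = 1 + b, lambda2 = 1 - b) so positive values favor
shrinkage. If the evolution empties the mask the seed is returned —
the refinement can only add information, never destroy the frame.
`medial_axis` is called with a fixed RNG so segmentation is
deterministic.

Two post-processing steps clean the raw medial axis:

- **Spur pruning** (`prune_len`, default 5 px ~ the PSF footprint):
  terminal branches shorter than the threshold that end at a branch
  pixel are deleted, iteratively. This is an addition over the bare
  transform; without it boundary roughness seeds false junctions.
- **Tip restoration** (`tip_extend`, default on): the medial axis of a
  round-capped tube stops about one half-width short of the cap, so
  each endpoint is extended along its outward tangent until the ray
  leaves the refined mask, constrained to a single-pixel chain. The
  active-contour boundary sits at the true tip to sub-pixel accuracy
  across the tested SNR range (5-30 dB), making the restored tips
  accurate to ~0.5 px where the raw skeleton was 1.5-2.5 px short.
  Tip position is the binding constraint on the Frechet distance of a
  resolved contour (endpoints must couple to endpoints).

## Skeleton topology

A lit pixel is a **branch pixel** when its 3x3 Moore-neighborhood sum
(center included) is at least 4, i.e. it has three or more lit
neighbors. **Endpoints** have exactly one lit neighbor. Unbranched
skeletons are ordered directly by geodesic (along-skeleton,
Euclidean-weighted Dijkstra) distance from the start endpoint.

Branched skeletons become an undirected multigraph: 8-connected groups
of branch pixels are junction vertices (Vb), the remaining 8-connected
groups are filament-segment vertices (Vf), and an edge joins a segment
to a junction for each segment end adjacent to it — a segment whose
both ends touch the same junction (a self-merge loop) contributes two
parallel edges. Direction is imposed at traversal: walks leave the
start vertex (the segment holding the tracked tip) and terminate at
the end vertex (the segment holding the far endpoint), when one
exists.

**Junction consolidation** (`junction_merge_len`, default 14 px):
thinning a shallow X-crossing yields a "bowtie" — two Y-points joined
by a short sliver that the filament really traverses twice, which
would make the physical path inadmissible under the edge rules.
Segments of at most the threshold size touching two or more distinct
junction groups are folded into a single junction group. The default
is about twice the imaged tube width; crossings closer than that are
one junction at this resolution.

## Knot resolution

Candidate walks are enumerated depth-first under the physical
traversal rule: every segment vertex exactly once (the filament covers
each segment once), junction vertices revisitable, each edge used at
most once per direction. Expansion is template-greedy — children among
the three key vertices (lowest mean pixel distance to the template)
are tried first — and beam-capped at 10 children per expansion
(`path_cap`) to avoid exponential growth; at most `max_paths` (100)
complete walks are scored. Graphs without an end vertex terminate a
walk once all segments are visited. If full segment coverage is
impossible (imaging artifacts can strand a segment), walks that merely
reach the end vertex are accepted as a fallback; if none exist the
frame raises an unresolvable-frame error for manual override.
Duplicate walks that differ only in which parallel edge leaves a
junction (same entry ports, hence the same contour) are removed.

**Contour assembly.** Each visited segment's pixels are ordered by
geodesic distance from its entry port. Junction pixels are inserted
once per crossing: the crossing is modelled by a Catmull-Rom bridge
from the last points of the incoming segment to the first points of
the outgoing one, and junction pixels within a 1.5 px corridor of the
bridge are kept, ordered along it. This attributes each junction pixel
to the strand it lies on and keeps both passes monotone; inserting all
junction pixels on every pass (the naive reading) costs several pixels
of Frechet error at consolidated junctions. No pixels are invented:
the contour is a subset of skeleton plus junction pixels.

**Scoring.** Every candidate contour is compared with the template by
dynamic time warping: cumulative cost
`D(i,j) = d(S_i, R_j) + min(D(i-1,j-1), D(i-1,j), D(i,j-1))` with
Euclidean local cost, first row/column accumulating, `D(0,0)` the
first pair's distance; the score is the final cell. The implementation
is vectorized row-wise via a prefix-sum identity
(`D(i,j) = S_j + min_k<=j (a_k - S_{k-1})`) and agrees with the
exhaustive warping-path minimum (oracle-tested). The minimum-score
path wins; ties break to the first in enumeration order, so resolution
is deterministic.

**Tracking loop.** Frame 0 must be unbranched or carry a manual
override. After each success the template becomes that frame's contour
(config switch `template_mode="last_unbranched"` restricts updates to
unbranched frames; the last-resolved default is required when knots
persist across consecutive frames). The next frame's start is its
skeleton endpoint nearest the previous start. Frames that fail without
an override are flagged and skipped with the template retained. Manual
overrides are programmatic records (frame index plus ordered vertex
labels); labels are stable because vertices are numbered segments
first, then junctions, in raster scan order. A label sequence cannot
distinguish the two orientations of a loop (both traverse the same
vertices); the orientation is chosen by port proximity.

## Contour geometry and dynamics

Resolved contours are smoothed coordinate-wise with a Savitzky-Golay
filter (window 11, polyorder 3 by default; window and order are not
prescribed by the source workflow and are exposed in the API;
polynomial edge handling so low-order curves are reproduced exactly).
Tangent angle `psi = atan2(y', x')` (central differences, unwrapped
along arc length) and curvature
`kappa = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2)` follow the planar
Frenet-Serret relations. The tip angle is `psi` at the free end, in
absolute image-frame radians (a flag subtracts the base angle). Per
frame the summary is: arc length, tip angle, end-to-end distance.
Tip-angle time series are unwrapped in time, mean-subtracted, and
transformed with a one-sided FFT amplitude spectrum on the grid
`k/(N*dt)`; for the default synthetic beat (T = 200 s, dt = 10 s,
N = 120) the peak falls exactly on the 5 mHz bin. The tangent-angle
kymograph resamples `psi` onto uniform normalized arc-length bins per
frame; base-to-tip phase propagation shows as a positive
cross-correlation lag between proximal and distal angles.

## Evaluation metrics

- **Tolerance Dice.** A detected pixel within 2 px (the PSF scale) of
  any truth pixel is a true positive; remaining detections are false
  positives; truth pixels with no detection within tolerance are false
  negatives; Dice = 2TP / (2TP + FP + FN). The degenerate all-empty
  case is defined as 1 (with a warning) so batch summaries total.
- **Discrete Frechet distance.** Dynamic program over monotone
  couplings minimizing the maximum pointwise distance;
  order-sensitive (a non-palindromic curve and its reversal are far
  apart), zero exactly for duplicate curves; oracle-tested against
  exhaustive coupling search.
- **Position error.** Per detected pixel, distance to the nearest
  truth pixel; summarized by mean and SD (the parameters of a normal
  fit to the unbinned errors).

## Problem sizes used in tests and the acceptance script

Sub-pixel accuracy is measured on 20-frame oscillation series
(12 um filament, amplitude 2.2 rad, curl 0.6 rad) at SNR 5, 10, 20 and
30 dB; parameter recovery on a 120-frame series at SNR 20; the paired
Dice comparison on 10 frames at SNR 5; knot resolution on the
two-frame loop-closure pair, noiseless and at SNR 10. These sizes give
stable statistics (position-error means pool thousands of pixels per
condition) while keeping a full run in tens of seconds.

## What the synthetic data does and does not emulate

It reproduces the geometry (curved, self-intersecting, inextensible
contours with a clamped base), the imaging chain (finite tube width,
PSF blur, controlled SNR), and the temporal structure (periodic beat,
template continuity between frames). It does not emulate motor
binding/unbinding stochasticity, photobleaching, uneven illumination,
background structures, or neighboring filaments. Passing tests
therefore demonstrate the correctness of the resolution algorithm and
the noise robustness of the segmentation chain, not performance on
arbitrary experimental footage — in particular, real data can present
the shallow-crossing and tip-fusion geometries listed below.

## Known limitations

- **Shallow crossings.** When two strands cross at a small angle the
  dilated tube fuses over a long region and the medial axis follows
  the wedge bisector, 2-3 px off either strand; resolved contours
  inherit that bias (Frechet 2-3 px measured at a 46-degree crossing
  versus 1-1.4 px at 90 degrees). Sub-pixel re-localization from the
  intensity profile would fix it but is out of scope.
- **Tip fusion.** A tip that lands on or glides along the filament
  body disappears into the fused mask; the resolved contour then ends
  at the junction. The manual-override mechanism exists for exactly
  these frames.
- **Near-tangency frames.** Just before a loop closes, the strands
  almost touch and segmentation may or may not report a junction;
  resolution of such frames is inherently ambiguous. The synthetic
  sequences sample closure so that frames fall on either side of the
  tangency.
- Single filament per region of interest; crossings between different
  filaments are out of scope, as are 3-D stacks.
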