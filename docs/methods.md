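# Methods

This note documents the models, parameter choices, and numerical decisions
behind `vcaseg`, and what the synthetic-data experiments do and do not show.

## Problem setting and working representation

Inputs are 2-D en-face angiogram rasters (PNG/TIFF/JPEG, 8- or 16-bit, gray
or RGB). Color is collapsed with Rec. 601 luma weights (0.299 R + 0.587 G +
0.114 B) — the standard, deterministic choice — and intensities are
normalized to [0, 1] floats immediately after reading; every threshold in
the package is expressed on that scale. Coordinates are 0-based (row, col)
with the origin at the top-left. The region of interest is always caller
supplied (`io.roi = top,left,height,width`); the package never guesses one.

## Segmentation pipeline

**Effective pixels.** A pixel takes part in vessel detection when its
intensity is at or above a threshold. By default that threshold is the Otsu
value of the ROI; it can be overridden with a number
(`effective_intensity`). Otsu's threshold is computed from a 256-bin
histogram over [0, 1]; every interior bin edge is a candidate, foreground is
`intensity >= threshold`, and ties are broken toward the lowest qualifying
edge. A constant image has no meaningful split and raises a degenerate-
histogram error; the pipeline treats that case as "nothing to segment" and
returns empty outputs.

**Starting-point detection.** Around each effective pixel, `n_directions`
(default 4: horizontal, vertical, both diagonals; 2 and 8 are supported)
centered probe lines of odd length `line_length` (default 7 px) are
examined. A line is *empty* when it contains no effective pixel other than
the center; positions outside the image count as not effective. The pixel is
a starting point iff the fraction of empty lines is strictly below
`empty_line_proportion_max` (default 0.5). The scan order is a boustrophedon
(Z-shaped) raster, but the decision is per-pixel, so the implementation
evaluates it as four correlations; an exhaustive per-pixel oracle in the
test suite confirms exact agreement.

**Connectivity growth.** The vascular network is the closure of the starting
points under the relation "effective pixel within Euclidean distance
`d_max` of a network member". `d_max = 2.0` by default, so the admission
neighborhood is the 5×5 window minus its four corners. Growth iterates
full-image sweeps until a fixed point, which makes the result independent of
traversal order; the fixed point equals breadth-first expansion, and the
test suite asserts exact set equality against an independently written BFS.
Sweeps are hard-bounded by the pixel count (each sweep either adds a pixel
or terminates). Starting points remain in the output unconditionally.

**Rotation merging.** Detection and growth are repeated on the image rotated
by 0°, 90°, 180°, and 270° (lossless quarter turns only; arbitrary angles
would interpolate and corrupt the set semantics), each result is mapped back
through the exact coordinate bijection, and the four sets are unioned.
With order-independent growth the four runs coincide up to the bijection, so
the merge also serves as a built-in equivariance check; the merged network
satisfies `extract(rot90(I)) == rot90(extract(I))` exactly.

**Binarization.** The Otsu threshold is computed on the full ROI histogram —
not on network pixels only, which would couple the threshold to the growth
parameters — and the binary mask is the grown network intersected with
`intensity >= threshold` (`binarize.manual_threshold` overrides). Interior
holes of at most `binarize.fill_holes_max_area` px² (default 10) are then
filled: multiplicative speckle occasionally drops single interior pixels
below threshold, and thinning would turn each pin-hole into a spurious tiny
ring. The filled mask is the working mask for all downstream stages, so the
skeleton remains a subset of the mask it is measured against.

**Skeletonization.** Thinning uses Zhang's algorithm (scikit-image). Its
directional sub-iterations are not rotation-equivariant, so the mask is
first brought to a canonical orientation — the quarter turn whose raster
bytes are lexicographically smallest — thinned there, and rotated back.
Quarter-turn rotating the input therefore rotates the skeleton exactly, and
all derived metrics are invariant, at no cost to the thinning result's
quality (one orientation of the standard output is simply chosen
deterministically).

**Skeleton graph.** Neighbor counts use 8-connectivity. A *bifurcation
point* has ≥ 3 skeleton neighbors; a *breakpoint* (endpoint) has exactly 1.
Branches are maximal paths between nodes, traced from every node along
unvisited edges through degree-2 pixels; each branch includes both terminal
nodes, so junction pixels are shared between branches and the sum of branch
lengths can exceed the component pixel count (never undershoot it). Pure
cycles (every pixel degree 2) are recorded as a single cyclic branch;
isolated pixels as a degenerate 1-px branch. Non-thin input (a fully set
2×2 block, which Zhang thinning leaves behind occasionally at junctions)
produces a warning, not an error, and the graph is still built.

**Piece-by-piece filter.** Two rules, in a fixed order:

1. *Branch pruning.* Terminal branches — those with at least one end of
   degree ≤ 1 — shorter than `filter.min_branch_length` (default 5 px) are
   deleted, keeping any junction end pixel; the graph is rebuilt and the
   pass repeats until stable. Isolated single pixels are degenerate terminal
   branches and are removed here.
2. *Length-per-node rule.* A component with
   `total_length / (n_bifurcations + n_breakpoints) < filter.min_ratio`
   (default 3.0) is deleted entirely. Components with no nodes at all —
   genuine closed loops, every pixel degree ≥ 2 — are kept: the ratio is
   undefined for them, and a large anastomotic loop is plausible anatomy.

Pruning runs before the ratio rule so that short spurs cannot inflate a
noise component's node count in its favor. The composite filter never adds
pixels and is idempotent (both properties are asserted in tests). Speckle
blobs and tail remnants yield short, node-dense skeletons and are removed by
one rule or the other; the defaults are declared package defaults, exposed
in configuration, not values inferred from any publication.

**Final mask and morphometry.** The pre-skeleton binary mask is restricted
to 8-connected components containing at least one surviving skeleton pixel.
Length is the surviving skeleton pixel count, area the surviving mask pixel
count, width their ratio — plain pixel accumulation, chosen so length and
area are counted on the same footing. Note the known bias of pixel-count
length: a diagonal unit-width segment counts ~1/√2 of its Euclidean length,
so widths of diagonal vessels read up to √2 wider; a diagonal-weighted
length (√2 per diagonal step) is available behind
`quantify.diagonal_weighted` but is not the default. Units are pixels
throughout; `io.calibration_mm_per_px` is an optional reporting-time scalar.

## Monitoring statistics

Per-day cross-subject mean and standard deviation (sample, n−1 denominator)
of length and width; percent change of the final-day mean relative to the
reference-day mean ((current − reference)/reference × 100, negative =
reduction); and an unpaired two-tailed t-test with Welch's correction
between the two days for each parameter. Welch's form is used
unconditionally — switching between pooled and Welch based on a variance
pre-test would make the analysis data-dependent. Degrees of freedom follow
Welch–Satterthwaite; the p-value comes from the Student-t survival function
(scipy). Significance labels: `**` for p < 0.01, `*` for p < 0.05, `ns`
otherwise. "Average" always means the arithmetic mean. The day-vs-day
comparison is unpaired by default even though subjects repeat; a paired
variant (`stats.paired`) is provided for repeated-measures use. If either
compared day has fewer than two observations the test is skipped with an
explicit "insufficient groups" note rather than failing the run. Two
degenerate cases are defined explicitly: identical constant groups raise an
error (t is 0/0), and constant groups with different means report t = ±inf,
p = 0.

## Synthetic angiogram generator

The generator emulates the phenomenology of en-face OCTA: bright branching
vessel trees of varying caliber on a darker background, multiplicative
speckle, elongated tail smears leaking downward beneath vessels, and
isolated bright noise clusters. Defaults (the package's standard test
conditions): 256×256 px, 3 trees, calibers 3–7 px, step 3 px, per-step
heading SD 0.25 rad, branch probability 0.08/step, speckle σ = 0.15
(moderate), tail strength 0.4 with 3–10 px exponentially decaying smears,
6 clusters of radius ≤ 3 px, background 0.15, vessel intensity 0.85.

Trees are random walks from border roots heading inward (normal plus
jitter), so the zero-tortuosity limit is exactly axis-aligned; caliber
tapers linearly from the sampled base width to the minimum at the tip, and
the mask is the union of rasterized disks along the centerline. Ground-truth
*length* is the centerline pixel count — deliberately the same pixel
accumulation the pipeline reports, so comparisons are apples-to-apples.
Two deliberate simplifications keep the truth unambiguous: trees are
mutually disjoint (a branch terminates when it nears a foreign centerline;
en-face crossing/projection overlaps are not modeled), and branches that
would die within their first four steps leave no pixels (no sub-resolution
stubs). Noise clusters are placed with centers ≥ 10 px from the vessel mask
so "isolated cluster removed" is a well-defined event. Speckle is
Gaussian-multiplicative (1 + σN(0,1), clipped), not a physical Rayleigh
model — the stages under test are distribution-agnostic. Images are
quantized to the 16-bit grid at generation time so the written PNG round
trip is lossless. All randomness flows from one integer-seeded PCG64
generator (`numpy.random.default_rng`), giving bit-identical output across
runs and platforms.

Passing the synthetic-recovery tests therefore shows the pipeline recovers
pixel-accurate truth under speckle, tails, and clusters of this kind; it
does not certify performance on real OCTA, whose artifacts (projection
doubling, motion lines, signal-strength falloff, vessel crossings) are
richer than this model.

The longitudinal simulator (`make_study`) gives each of `n_subjects` a base
centerline-length budget (700–1100 px) and shrinks it linearly across the
study days to `1 − decline_fraction` of baseline (default −40%), with
multiplicative Gaussian noise (SD 5%) per image; widths are left untouched.
Problem sizes used by the shipped checks — 100 random 64×64 images for the
threshold oracle, 50 maps/skeletons for the growth and graph oracles, 20
default-condition angiograms for recovery, and a 14-subject × 4-day study
(56 segmentations) for trend recovery — were chosen so the whole suite runs
in well under a minute per block on one CPU.

## Numerical and degenerate-input decisions

- Histogram binning: 256 bins over [0, 1]; thresholds applied with `>=`.
- Threshold ties: lowest qualifying bin edge wins (argmax takes the first).
- Growth admission uses a strict Euclidean disk (d² ≤ d_max²); the footprint
  is precomputed once.
- `monitor` sorts rows canonically (day, then subject) before reducing, so
  floating-point summation order — and hence every reported statistic — is
  independent of input row order.
- Empty masks, empty networks, and constant images all short-circuit to
  empty outputs with `defined = false` metrics rather than raising.
- CLI atomicity: all computation happens before any output file is written,
  so a failing run leaves no partial artifacts. Exit codes: 0 success,
  2 validation, 3 I/O, 4 internal.

## Known limitations

- Pixel-count length underestimates Euclidean arc length of diagonal runs
  (and correspondingly inflates width) by up to √2; mitigated in practice by
  heading diversity, and quantifiable via the diagonal-weighted option.
- A spur's junction pixel survives pruning, so each pruned spur can leave
  one extra skeleton pixel at the junction.
- The piece-by-piece thresholds are global; images mixing very different
  noise scales may need per-image configuration.
- Vessels thinner than ~2 px fragment under speckle and are largely removed
  by the filter; the generator's minimum caliber (3 px) reflects that.
- The monitoring module models no within-subject correlation (unpaired test
  by default) and applies no multiple-testing correction across the two
  parameters.
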