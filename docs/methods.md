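# Methods

This note documents the model, the numerical conventions, and the design
choices behind `los3d`, at the level of detail needed to reproduce or audit
its behavior.

## Conventions

All voxel grids are indexed `(z, y, x)`, 0-based, voxel centers at integer
coordinates. Physical spacing `(dz, dy, dx)` in μm/voxel is metadata only:
it converts voxel volumes and centroids to physical units in the feature
table, while every geometric operation (distance transforms, neighborhoods,
visibility sampling, clustering) runs in voxel units. This is deliberate:
all the method's length parameters (Otsu radius 18, opening radius 5,
prominence 0.1, 18 nearest neighbors) are defined in pixels/voxels, and
mixing them with anisotropic physical distances would silently change their
meaning. An anisotropy-aware distance transform is intentionally not
offered; strongly anisotropic stacks should be resampled first.

Binary masks are plain boolean arrays; label grids ("component matrices")
are non-negative integer arrays with 0 as background, labels compacted to
`1..m`.

## Binarization

Foreground extraction must survive depth-dependent signal decay and uneven
illumination, so thresholding is local: per z-slice, each pixel is compared
against Otsu's threshold computed over the disk of radius `otsu_radius`
(default 18 voxels — approximately one nucleus radius, the one parameter
worth adapting to a new dataset) centered on it; a pixel is foreground iff
its value strictly exceeds the local threshold. Windows containing a single
distinct value have no Otsu threshold and are defined background; this
guards against the degenerate all-foreground answer in empty image regions.
Rank-filter thresholding runs on 8-bit data; other dtypes are linearly
rescaled to 8 bits first (a monotone mapping, so thresholding is affected
only by quantization).

The initial binary then passes through three 3D repairs:

* **ROI masking** — a maximum filter with a Euclidean ball of radius
  `roi_radius` (default 25, ~1.5× the Otsu radius; the source text says only
  "a large radius") over the initial binary, AND-ed back onto it. This
  removes detections far from the specimen.
* **Hole filling** — background cavities (6-connected) not reaching the
  grid border become foreground.
* **Opening** — erosion then dilation with the Euclidean ball of radius
  `opening_radius` (default 5), removing objects smaller than the
  structuring element and smoothing the rest.

Ball erosion/dilation/maximum filters are computed via Euclidean distance
transforms (erode = EDT-to-background > r with zero-padded borders; dilate
= EDT-to-foreground ≤ r), which is exact for ball structuring elements and
much faster than explicit convolution at radius 25; equivalence with
explicit `binary_erosion`/`binary_dilation` is oracle-tested.

Only the per-slice thresholding is 2D; everything downstream is fully 3D.

## Divisible-part counting

Each connected component (26-connectivity, cropped to its bounding box,
padded by one background layer so box faces count as background) gets a
Euclidean distance transform. The number of nuclei in the clump is
estimated as the number of regional maxima with prominence ≥ 0.1 (the
`min_prominence` parameter), computed as h-maxima of the EDT under
26-connectivity: a peak counts only if every path leaving it descends by at
least 0.1 before reaching a higher voxel.

The prominence gate is stated in the underlying method as "maxima that
exceed adjacent voxels by at least 0.1", but a literal per-neighbor test is
ill-posed on a discrete EDT: adjacent values of a large convex body can
differ by far less than 0.1 (√76 − √75 ≈ 0.057), so the literal rule
rejects the true center of any sufficiently large nucleus, and equal-valued
plateau voxels (e.g. the flat EDT top of an even-sided cube) can never
qualify at all. The h-maxima formulation is the standard well-posed reading
of the same intent: it merges plateaus into single maxima and suppresses
sub-voxel EDT ripple while keeping every genuinely prominent peak. Digital
balls of radii 3–15 give exactly one maximum; fused pairs and chains give
one per ball. Any non-empty clump yields k ≥ 1 (the global maximum counts
if reconstruction flattens everything).

Clumps with k = 1 pass through unchanged. The literal "< 1000 voxels" gate
on decomposition candidates is exposed as optional config
(`clump.min_clump_voxels` / `max_clump_voxels`) but disabled by default: a
hard 1000-voxel cap would leave typical multi-nucleus clumps (a single
radius-8 nucleus already holds ~2100 voxels) unsplit.

## LoS decomposition

A clump with k ≥ 2 is split by clustering mutually visible surface-point
pairs:

1. **Surface points**: foreground voxels with a background face-neighbor
   (6-adjacency), in lexicographic order.
2. **Sampling**: with n surface points, the sample rate is 10 % for
   n < 1000, 3 % for 1000 ≤ n ≤ 100 000, 2 % above; m = max(2, round(r·n))
   points are drawn uniformly without replacement with the per-clump seed,
   and all C(m, 2) pairs are formed.
3. **Visibility**: each segment is probed at t = 0, 0.001, …, 1 of its
   length; every probe, rounded to the nearest voxel, must be foreground.
   Rounding (rather than sub-voxel interpolation) is the chosen membership
   test; its one artifact is that a segment touching a background voxel's
   cell corner at exactly half-integer coordinates may be accepted — kept
   lines never cross the *interior* of a background cell, which is the
   soundness property the tests assert under 10×-finer re-probing.
4. **Clustering**: the surviving Lines-of-Sight are merged bottom-up by
   Ward's method (the Lance–Williams update applied directly to the given
   dissimilarities, as implemented by `scipy.cluster.hierarchy.linkage`)
   until exactly k clusters remain. The dissimilarity between two lines is
   the chessboard (Chebyshev) distance between them as *unordered* endpoint
   pairs: the smaller, over the two ways of pairing their endpoints, of the
   larger endpoint-to-endpoint Chebyshev distance. The line feature was a
   genuinely open design point; ordered-endpoint 6-vectors under any fixed
   canonical ordering (lexicographic, principal-axis) leak the arbitrary
   ordering into the geometry — two nearly identical cross-neck lines can
   be ordered oppositely and land far apart — and measurably degrade
   two-ball recovery (29/50 for lexicographic vs 41–43/50 for the unordered
   pairing on the benchmark below). Cluster labels are renumbered 1..k by
   the lexicographic order of cluster centroids so labelling is independent
   of merge history.
5. **Surface labelling**: each sampled point takes the majority label of
   its incident lines; ties are drawn uniformly with the per-clump
   generator. A cluster whose lines all lose their local majorities keeps
   its strongest-voting point as an anchor, so every cluster can form a
   part. Points without incident lines stay unlabelled for the next step.
6. **Label optimization**: every surface point is reassigned the majority
   label among the labelled ones of its 18 nearest surface points
   (Euclidean, self excluded, distance ties broken by lexicographic
   coordinate order; majority ties to the smallest label). Because only
   the sampled points carry labels initially, this synchronous pass is
   iterated until the labelling is complete and stable (capped at 50
   passes): labels grow outward from their anchors, which keeps the rule
   local. The alternative — one pass over the 18 nearest *labelled* points
   — is effectively a global vote when anchors are sparse and
   deterministically erases any cluster holding fewer than ~10 anchors;
   it was measured and rejected.
7. **Voxel labelling**: every foreground voxel takes the majority label of
   its 18 nearest surface points (ties drawn with the seeded generator).
   Labels owning no voxels are compacted away.

Degenerate clumps (fewer than two surface points, or no surviving line)
are returned unsplit with a warning; if fewer lines than k survive, the
clump is clustered into min(k, #lines) parts with a warning.

### Determinism

Every random draw (point sampling, tie resolution) comes from a
`numpy` generator seeded per clump as
`SeedSequence([global_seed, *bounding_box_offset])`, so results are
bit-reproducible and independent of clump processing order. Two runs with
the same configuration and seed produce identical label volumes and feature
tables; the test suite asserts this end-to-end.

## Pipeline assembly and features

Decomposed clump labels are renumbered globally and placed back by
bounding-box offset (components are disjoint, so no conflicts). Objects
below `min_volume_voxels` (default 50 — the filter is named but not
quantified in the source; 50 voxels is far below any plausible nucleus at
these resolutions and removes only debris) are discarded and labels
compacted. Per-nucleus features are the centroid (arithmetic mean of member
voxel coordinates, voxel and μm), volume (voxel count and μm³ via
`dz·dy·dx`), and mean raw intensity.

## Evaluation

Segmented centroids are matched to ground-truth centroids greedily in GT
input order: each GT centroid claims the closest unmatched segmentation
centroid within a spherical radius (the average nucleus diameter in voxels,
supplied by the user); claimed centroids are consumed, so matching is
one-to-one. This is a deliberate simplification of the optimal assignment
problem; the greedy order only matters for pathological near-tie layouts.
From TP, FP = n_seg − TP and FN = n_gt − TP follow, and the four metrics
are computed with every 0/0 defined as 0. Reported values use half-up
rounding to two decimals. Volume summaries are mean ± sample standard
deviation (n − 1; zero when n = 1).

## Phantom generator

`PhantomSpec` renders ellipsoidal nuclei (semi-axes per axis, peak
intensity, default 200 on background 10) into a grid, scales foreground by
`depth_decay**z` (default 1.0; 0.995 in the dense suite scenario) to mimic
depth-dependent signal loss, adds Gaussian noise (default 5 % of peak in
noisy scenarios) and clips at zero. Ground truth assigns overlap voxels to
the nucleus with the smallest semi-axis-scaled (Mahalanobis) distance to
its center; truth centroids and volumes are computed from these label
supports, and clump membership from 26-connected components of the union.

Fused pairs are parameterized by a separation factor applied to the
*larger* radius (factor 1.2–1.6): this keeps each center outside the other
nucleus while the balls overlap — the regime of two distinguishable
touching nuclei. Factors applied to the radius mean can place one center
inside the other ball (engulfment, not touching) and were rejected for the
study conditions.

The fixed `standard_suite` battery covers: (a) five isolated radius-8
balls; (b) fused radius-8 pairs at factors 1.2/1.4/1.6; (c) a chain of
three fused radius-8 balls; (d) an unequal fused pair (radii 6 and 10);
(e) twenty nuclei of radii 6–8 packed as singles, pairs, triples and one
quadruple with depth decay and 5 % noise. Grids stay at or below ~90³ so
the full suite segments in well under a minute per run on one CPU.

What the phantoms do *not* emulate: optical blur (no PSF convolution),
non-ellipsoidal nucleus shapes, intensity texture within nuclei, and
anisotropic voxels. Passing phantom tests therefore validates the
geometric and statistical machinery — binarization robustness to noise and
decay, part counting, decomposition, bookkeeping — not performance on any
particular microscope's data.

## Known limitations

Boundary placement inside deeply fused clumps is sampling-limited. A fused
pair of radius 6–10 nuclei exposes ~1000–1600 surface points, which falls
in the 3 % sampling band: only ~30–45 sampled points anchor the whole
labelling, so the part interface is localized to roughly half the
inter-anchor spacing (±2–3 voxels). On the benchmark of 50 seeded fused
pairs (radii 6–10, separation factor 1.2–1.6, 5 % noise), 82–86 % split
into exactly two parts with both centroids within 2 voxels of truth; the
failures are interface misplacements of 2–6 voxels, concentrated where the
two balls' line populations are strongly imbalanced (the within-ball line
count scales with the square of the exposed surface ratio, and Ward's
variance criterion then prefers splitting the larger population).
Decomposing noise-free ground-truth masks directly scores no better, so the
limit is intrinsic to the sampling policy and clustering at this clump
scale, not to the preprocessing. Part volumes inherit the same sensitivity:
one voxel of interface offset moves ~5 % of a part's volume, more for small
parts. Surfaces below 1000 points (10 % sampling) and above ~5000 points
are markedly more robust.
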