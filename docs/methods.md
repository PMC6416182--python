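# Methods

This note documents the models, parameter choices and known limitations
behind `maizeskel`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A registered terrestrial-laser scan of a single potted maize plant is a
colored point cloud (~10⁴–10⁵ points, meters, z up). The quantities of
agronomic interest are one-dimensional: the stem axis and the midrib
(vein) curve of every leaf, and scalar traits read off those curves. The
package extracts a *curve skeleton* — one stem polyline plus ordered leaf
polylines attached at growth points — and computes six traits: leaf
length, leaf inclination angle, leaf top length, leaf azimuthal angle,
leaf growth height, and plant height.

## Pipeline stages and their assumptions

### Denoising

*Pot removal.* Pot pixels are matched against a short list of sampled pot
colors with D = 2·|max(η_i,η_j)/min(η_i,η_j) − 1|·θ, η the channel mean
and θ the angle between mean-centered chroma vectors rescaled so 90°
maps to 255; D < 0.1 removes the point. D is invariant to uniform
brightness scaling — shading does not defeat it — but degenerates to 0
for *any* two colors of equal brightness (gray points never match, and
equal-brightness hue flips are invisible). With 8-bit colors, brightness
quantizes to multiples of 1/3, so a sample whose channel sum collides
with plant colors would spuriously remove them; `sample_pot_colors`
therefore returns small swatch means at spread brightness quantiles,
conditioned to sit halfway between quantization levels. Pot samples must
not be pure gray.

*Scan-noise removal.* Clusters are connected components at linking radius
r = 0.012·l (l the bounding-box diagonal); clusters smaller than
n = 0.5·mean(density(p_i, r)) over `num` = 10 seeded random probes are
dropped. The partition equals brute-force connected components and is
traversal-order independent.

### Laplacian contraction

Per iteration the sparse least-squares system
[W_L·L; diag(W_H)]·P^{t+1} = [0; W_H·P^t] is solved via normal equations
(sparse LU). L is rebuilt each iteration: for every point, its k = 15
nearest neighbors are projected on the local PCA tangent plane, a 2D
Delaunay one-ring supplies cotangent weights (clamped to ±10⁴; uniform
weights for near-collinear neighborhoods), the matrix is symmetrized and
rows sum to zero. Updates: W_L ← min(3·W_L, 2048) and
W_H,i ← W_H,i⁰·S_i⁰/S_i^t with S_i the one-ring total edge length.
Initialization: W_H⁰ = 1, W_L⁰ = 1/(5·mean one-ring edge length).
Iteration stops when the total one-ring length shrinks by less than 1 %
(the printed ratio test on W_L alone cannot fire, since W_L grows by a
constant factor) or after 20 iterations. After full collapse the one-ring
graph is rebuilt over near-collinear points and its total length can
rebound; that rebound is precisely what triggers the stop, so the
monotone-shrinkage property holds up to the stopping measurement.

Free ends (stem base/top, leaf tips) creep inward under contraction — a
known systematic that the calibration stage corrects. On a denoised
10,000-point plant contraction converges in ~10–15 iterations.

### Adaptive sampling

Greedy sphere absorption: the unabsorbed point with most unabsorbed
neighbors seeds a key point; it absorbs everything within the joint
radius (0.007·l) if it sits at a junction, else the branch radius
(0.015·l), and emits the absorbed set's centroid. These radii yield
100–300 key points on a grown plant. Junctions are flagged when the
directionality degree l(v) = λ₂/Σλ of the covariance *over the sampling
sphere* falls below 0.9; the covariance must be taken at the sphere scale
because a fixed-k neighborhood on a densely contracted cloud spans
millimeters and never sees the meeting branches. Note the geometric
orientation: neighbors spreading over several directions *lower* λ₂'s
share, so low l(v) ⇒ junction; l(v) = 1 exactly on collinear
neighborhoods and 1/3 in the exactly isotropic limit (random isotropic
draws sit above 1/3 because the top sample eigenvalue is biased upward).

### Topological connection

Key points propose edges to their 3 nearest neighbors; proposals are
admitted in ascending length order while both endpoints stay at degree
≤ 3 (maize is single-stemmed; no skeleton node needs more). Components
stranded by the degree cap are re-attached where their absorbed point
sets are closest — i.e. along the underlying contracted curve. Loops are
broken shortest-first: the cycle's nodes get a total-least-squares plane,
each cycle edge a weight W = W_s/max(W_s) + W_c/max(W_c) with W_s the
endpoints' summed plane distances and W_c the summed turning angles
against the adjacent cycle edges, and the max-weight edge is deleted;
only cycle edges are deleted, so connectivity is preserved. Edges whose
inter-source gap is an upper-tail outlier (blades merely passing close)
are cut and re-bridged along their own curve. The stem is traced from the
lowest degree-1 node, choosing at each junction the branch with the
greatest achievable progress (within 7 edges, exact tree DP) along a
reference direction that blends the accumulated base-to-here chord with a
standing vertical prior; leaves are the off-stem branches, ordered by
growth-point height. Branches shorter than 2.5 sampling radii are pruned
as junction artifacts, and polylines that re-trace another blade
(duplicate attachments) are dropped.

### Calibration

*Stem.* Growth points split the stem into sections. Each section's line
uses the stem's own surface points: the cylinder is isolated by
iteratively trimming points beyond 1.6× the median orthogonal residual
(junction corridors deposit leaf-base points in the stem cloud), a global
robust axis direction is shared across sections, and every node is
projected onto its section's line, so sections are exactly collinear.
Stem ends are recovered by walking a cutting plane outward until the
slab empties. When no stem cloud is supplied, section lines fall back to
the interior skeleton nodes (growth points excluded, as those are the
nodes bent by leaf attraction).

*Leaves.* Walking from the base, each polyline node is replaced by the
centroid of the original leaf points inside a slab perpendicular to the
local tangent (half-thickness 0.5× the walking step, step 0.5× the node
spacing, membership confined to a 5–8 cm ball); for a transversely
symmetric blade that centroid sits on the midrib. Past the last node the
plane keeps stepping until a slab holds fewer than 3 points, recovering
the missing tip; a step that slides backward also ends the walk.

*Base recovery.* Contraction merges each leaf's first ~10 cm into the
stem, so the apparent growth point sits too high and the first segment
leaves almost horizontally. With the stem surface masked out, the
connected component of the remaining points containing the leaf's own
points is the blade surface (organs only touch through the stem, up to
blade crossings). Near the insertion the blade lies in a vertical plane
through the stem axis with its width perpendicular to that plane, so in
coordinates (radial distance x, height y along the stem) the base points
collapse onto the vein. An orthogonal-distance quadratic
y = b₀+b₁x+b₂x²+b₃·off² — the off² term absorbs transverse blade sag,
and orthogonal distance avoids the errors-in-variables slope attenuation
that biases the base tangent flat — is fitted over x ∈ (r_stem+1 cm,
14 cm) and extended inward by a consistency-filtered second pass. Its
intersection with the stem line is the growth point; nodes sampled from
the arc replace the unreliable inner polyline. The base tangent is the
mean of the quadratic's slope at x = 0 and a tilted-conic-arc fit of the
sag-corrected blade (their truncation biases have opposite signs). The
rest of the vein is traced by the cutting-plane walk over the whole
off-stem cloud, stepping blindly (up to two steps) through slabs that
are empty or whose centroid jerks sideways, so brief blade crossings are
passed through; the traced and tree-guided polylines are then arbitrated
by probing whether the blade clearly continues past the walk's end.

### Traits

Leaf length is polyline arc length; top length refines the apex by a
parabola through the highest node and its neighbors so it does not
quantize to node spacing; inclination uses the measured base tangent
against the local stem axis (fitted over ±3 nodes — two adjacent nodes
can straddle a millimetric section kink and tilt by degrees), falling
back to the first-segments chord when no tangent was measured; azimuth
uses the horizontal component of the base tangent (for a planar vein
identical to the growth-to-tip definition, but immune to a wandering far
end), measured counter-clockwise from the lowest leaf; growth height and
plant height are vertical distances from the stem base. `evaluate`
compares azimuths on the circle (differences wrapped to ±180°) and
normalizes RMSE by the reference mean. The study runner aligns predicted
to reference leaves by a monotone dynamic program on growth height and
azimuth side; with equal counts this is exactly rank matching, and a
rare missed leaf does not scramble the remaining ranks.

## Synthetic plants

`make_plant` builds: a stem cylinder (radius 1.2 cm, tilt ≤ 2°) along a
height drawn from 1.1–2.0 m; 8–12 leaves at strictly increasing
insertions spread over 0.18–0.85 of the stem with alternate 180°±10°
phyllotaxy; each vein a quadratic arc in the vertical plane of its
azimuth, rising at a 25–50° insertion angle, arching over an apex and
drooping toward the tip, rescaled to an arc length of 0.35–0.55× the
stem height; a ribbon of surface points whose width ramps up over the
first 15 % of arc to 6–9 cm and tapers to zero at the tip, with a small
transverse sag below the midrib. Points are allocated by surface area
and perturbed by isotropic Gaussian noise (σ = 1 mm for "easy", 4 mm for
"realistic" studies); "realistic" also adds a brown pot shell below the
base and 1 % outlier clutter in small isolated clumps. Colors are each
organ's base RGB under multiplicative brightness jitter (matte shading)
plus σ = 0.6 per-channel sensor noise — the shading model under which a
brightness-ratio color filter is meaningful. Ground truth carries the
analytic curves, per-point organ labels, and a trait table evaluated
directly on the curves (the trait estimators applied to the finely
sampled truth polylines reproduce it to well under 1 %).

What the generator does **not** emulate: self-occlusion and view-dependent
point density, leaf twist and out-of-plane curvature, sheaths/collars,
tassels and ears, registration artifacts. Passing tests therefore
demonstrate the pipeline's geometric correctness under clean acquisition,
not robustness to every artifact of real scans.

## Known limitation: near-planar crowded plants

Because every synthetic vein lies exactly in a vertical plane and
phyllotaxy is 180°±10°, a grown plant is almost planar: blades two ranks
apart share a side and their arcs cross in 3D. Real maize blades twist
out of plane, so this surrogate is *harder* than typical scans in exactly
this respect. At crossings the contraction merges the two surfaces
locally, and on the densest plants (11–12 leaves) the downstream graph
can scramble one or two blades despite the cross-edge cutting, duplicate
removal and surface re-tracing described above; a single scrambled blade
dominates the pooled study-level error of the leaf-scale traits, and the
outcome is sensitive to which crossings merge. Plant-scale quantities
(growth heights, plant height) remain accurate. The acceptance tests
compare the surrogate study against the published six-plant reference
errors and are left failing where this limitation applies, with the
stage-level property suites and parameter-recovery tests documenting
which parts of the method are sound.

## Numerical choices

Voxel simplification bisects the voxel size to hit the target count
±10 % and keeps the original point nearest each occupied voxel centroid
(no interpolation; colors survive bit-exactly). All randomness (density
probes, study generation) flows from explicit integer seeds; the
pipeline is deterministic given its inputs and seed. Degenerate inputs
(collinear neighborhoods, empty slabs, missing organs) fall back to
uniform weights, unchanged geometry, or logged no-ops rather than
raising mid-pipeline; hard errors are reserved for violated contracts
(empty clouds, non-tree segmentation input, no surviving cluster).
Problem sizes in the tests — 10,000 points per plant, six-plant studies —
are the package's standard operating point.
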