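# Methods

## Model and assumptions

`voxabs` evaluates the inverse absorption factor of a reflection **h** as
the mean Beer–Lambert transmission over crystal voxels,

A_h = (1/N) Σ_n exp(−Σ_m μ_m (L1_nm + L2_nm)),

the discrete form of the volume integral over the diffracting crystal.
Assumptions: the beam illuminates the whole crystal (no partial-
illumination weighting — every crystal voxel enters the average); the
sample is fully described by the segmented label volume and one scalar
attenuation coefficient per material; refraction and secondary scattering
are ignored; background/vacuum never attenuates (μ fixed at 0).

All geometry lives in the array frame (z, y, x) with voxel centers at
integer coordinates and the volume occupying [0, dim−1] per axis; the
cuboid bounds sit on the outermost voxel centers, which can shift any
individual path length by up to one voxel relative to an outer-edge
convention. Reflection tables supply unit direction vectors for the
incident and diffracted beams in this frame (CSV columns `ix,iy,iz,dx,dy,dz`
in x, y, z component order); vectors with norm in [0.99, 1.01] are
renormalized, anything else is rejected.

## Standard traversal

Each per-voxel path is traced twice: back along the reversed incident
direction and forward along the diffracted one, starting at the
diffracting voxel. Initialization casts the ray against the six bounding
planes; the face with the smallest non-negative intersection distance is
the exit, and its axis becomes the driving axis, advancing one voxel per
step so each interval records exactly one voxel. Non-driving coordinates
are rounded half-away-from-zero — this (not banker's rounding) reproduces
the canonical 2D pattern in which a ray from pixel (0, 0) toward
(x, y) = (5, 2) records rows round(0.4·s) = 0, 0, 1, 1, 2, 2. When a ray
leaves exactly through an edge or corner the face enumeration
(x-min, x-max, y-min, y-max, z-min, z-max; lowest index wins) resolves the
tie toward X, which is the choice that keeps one voxel per interval in
that same worked example. Traversal always continues to the model
boundary: stopping at the first vacuum voxel would drop liquor or loop
lying beyond a gap and make the result sensitive to segmentation
artefacts.

The recorded staircase overcounts oblique paths, so per-material lengths
are proportions: L_m = (counts_m / total) · ‖end − start‖ · voxel size.
They sum to the Euclidean ray length by construction. Exponents are
assembled in one fixed accumulation order shared by every back-end, so
that gridding lookups on exact nodes equal the standard result bit for
bit.

Measured against a 10⁻³-voxel marching oracle on the 32³ sphere phantom,
per-material lengths agree within 1 voxel on ≈97% of random rays; the
worst near-tangent crossings of the 2-voxel loop shell deviate ~1.6
voxels. That residual is inherent to sampling one voxel per interval, not
a tunable.

## Bisection

On a conforming sample — materials ordered crystal, liquor, loop, vacuum
along any outward ray, no vacuum between crystal and loop — each material
occupies one contiguous run of steps, so a binary search per transition
(at most ⌈log₂ n⌉ + 2 label queries) replaces the O(n) walk. Boundaries
are searched in the fixed order crystal outer → sample/air → loop inner →
loop outer; the liquor is never searched, its length being the remainder
after subtracting crystal, loop and vacuum from the total. Because the
brackets nest, the remainder is never negative. When the voxel preceding
the air boundary is not loop (e.g. the ray leaves through the loop's open
side) the loop is flagged absent and gets zero length rather than a
guessed boundary. After the search, a few interior steps of the derived
liquor and vacuum runs are probed; a mismatch (an air pocket inside the
sample, sample material beyond the derived air boundary) emits
`NonConformingModelWarning` — the lengths are then the documented
approximation. The probes are best-effort: a pocket between probe points
goes undetected, matching the method's published failure mode.

## Gridding

Per sampled crystal voxel, a (360, 180) grid stores the *one-way* exponent
Σ_m μ_m L_m for the unit direction with azimuth θ = i° (about z, from +x
toward +y) and polar angle φ = j° (from +z). A reflection's exponent is
the sum of two nearest-neighbour lookups: reversed incident + diffracted.
For edge continuity the lookup grid is padded to (420, 210) — 30° of
azimuthal wrap per side and 15° of polar continuation per side, a polar
reflection landing on the meridian 180° away; (30°, 15°) is the only split
consistent with those shapes. Grids are double precision; values + padded
copy cost ≈1.2 MB per voxel, so the builder refuses plans whose total
exceeds a memory budget (default 2 GiB) — gridding is only practical
combined with sampling. An optional on-disk cache keyed by volume
checksum, coefficient hash and voxel set reuses grids across runs and
rejects mismatched keys. Nearest-neighbour lookup is exact on nodes and
otherwise errs by the exponent's variation within 1°; on the 32³ sphere
phantom, 200 random reflections at 1% sampling deviate from the standard
back-end by ~0.02% mean (< 2% asserted). Higher-order interpolation is
deliberately out of scope; nearest-neighbour's failure mode when adjacent
nodes differ strongly (elongated crystals) is a known limitation.

## Sampling

Strategies over the row-major-sorted crystal list: systematic (every k-th,
k = round(1/ratio); ratio 0.05% ⇒ k = 2000), randomized systematic (one
uniform draw per interval), random (uniform without replacement) and
stratified (k-means over features (z, y, x, distance-to-crystal-centroid),
unit weights, S = max(1, round(ratio·N)) clusters, single initialization
from the seed, 300 iterations, tolerance 10⁻⁴; the member voxel nearest
each centroid is kept, computed once per dataset rather than per
reflection). For ratios in (0.5, 1) the systematic interval rule cannot
also satisfy |selected| ≈ ratio·N; the interval rule wins, as practical
ratios are ≪ 1. Ratio 1.0 reproduces the no-sampling factors bitwise for
every strategy. The random strategies are kept for testing and comparison
even though systematic (default ratio 0.5%) is the recommended practice;
stratified suits compact, near-spherical crystals but its k-means cost
grows steeply with S and offers no global optimum. `ks_compare` wraps the
two-sample Kolmogorov–Smirnov test; the mean KS statistic against full
enumeration is non-increasing in ratio (asserted over 20 seeds on the
sphere phantom).

## Synthetic phantoms

`make_phantom` emulates a segmented tomogram of a mounted crystal:
a crystal core (sphere / capsule rod / octahedral bipyramid), a
uniform-thickness liquor shell and a loop shell built by Euclidean
distance transform, the loop opened over the +z half-volume. A half-space
cut (rather than a cone) guarantees that along any *straight* ray from a
crystal voxel, background never precedes loop — a line crosses a plane at
most once — which is the ordering the bisection back-end assumes. The
rounded stepped path can still jitter by ±½ voxel across the opening rim,
which occasionally trips the conformance probes; that reflects a genuine
(sub-voxel) bisection approximation, not a generator defect. Optional
segmentation noise flips a given fraction of labels uniformly (off by
default). Phantoms are pure functions of their parameters and seed.

What the phantoms do **not** emulate: irregular real segmentations
(rough interfaces, disconnected liquor films, internal vacuum bubbles),
partial beam illumination, and realistic loop geometry beyond "open on
one side". Passing tests therefore certify the geometry/numerics of the
engine, not segmentation robustness on real tomograms.

## Numerical choices and defaults

* voxel size default 0.3 µm (typical of the tomographic reconstructions
  this targets); coefficients in µm⁻¹ — representative long-wavelength
  protein values ship as `PRESET_COEFFICIENTS` (e.g. thermolysin
  0.01312/0.01583/0.01172 µm⁻¹ for crystal/liquor/loop).
* label codes default background=0, liquor=1, loop=2, crystal=3,
  overridable; codes restricted to [0, 255] so count arrays stay compact.
* double precision throughout; `precision="single"` evaluates exponent
  and transmission in float32 to mirror reduced-precision accelerator
  arithmetic (factors then agree with double to ~10⁻⁵ relative).
* on-face/tie tolerance 10⁻⁹ voxel; rays parallel to a plane contribute
  no exit candidate; a start on a face moving outward exits at t = 0.
* worker threads only distribute reflections across a thread pool; each
  reflection writes its own slot, so results are bitwise independent of
  the worker count.

Test problem sizes (32³ phantoms, ≤ 200 reflections, ≤ 40 oracle rays,
20 KS seeds) were chosen so the full suite exercises every guarantee at
desk scale; the engine itself is size-agnostic and the compiled kernels
handle tomogram-scale volumes.
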