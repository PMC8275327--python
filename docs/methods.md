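# Methods

## Implicit-surface model

The surface of a cell is the `F = 0.5` iso-level of a summed scalar field
of compactly supported kernels ("metaballs"),

    F(p) = Σ_i k(|p − c_i|, R_i),    k(d, R) = (1 − d²/R²)³ for d < R, else 0.

The Wyvill soft-object kernel was chosen because (i) its compact support
makes field evaluation spatially local — a KD-tree over ball centers gives
near-linear evaluation that is *exactly* equal to brute-force summation,
since excluded balls contribute a true zero — and (ii) it guarantees the
field vanishes on any grid padded beyond the largest influence radius,
which is what makes the closed-surface guarantee below unconditional.
Blending is field addition, so meta-objects combine by concatenating
their ball lists; the operation is commutative and associative.

At iso-level 0.5 a lone ball's surface is a sphere of radius
`s·R` with `s = √(1 − 0.5^{1/3}) ≈ 0.45420` (verified in the tests by
independent root-finding on the kernel). Everywhere in the package a ball
meant to *render* morphological radius `r` therefore stores influence
radius `r/s`, so the skeleton's calibrated diameters survive skinning.
Where several balls overlap the summed field bulges slightly outside each
individual surface; this is the intended smooth blending and the reason
the hybrid soma needs the displacement treatment described below.

## Adaptive resampling

Synthesized astrocyte processes carry sample spacings of ~0.05 µm against
radii of several µm. Resampling walks each section greedily and keeps a
sample once its Euclidean distance from the previously kept sample
reaches `spacing_factor ×` (radius of the last kept sample); endpoints
are always kept verbatim, and kept samples are a strict subset of the
originals (no interpolation), so the resampled polyline lies on the
original one. With the default factor 1.0 the kept spacing matches the
sphere-marching step, so no surface detail below the polygonization
resolution is lost. The operation is idempotent and monotone in the
factor. On the default synthetic astrocyte it removes ~97.6% of samples
while changing total cable length by under 0.2% (the morphometry report
computes this per arbor).

## Segment and arbor skinning

Each segment [a, b] is sphere-marched: `⌈L / (f·min(r_a, r_b))⌉ + 1`
balls (step factor `f`, default 1.0) equally spaced on the axis with
surface radii interpolated linearly. Using the smaller endpoint radius
for the step bound keeps the spacing ≤ one *local* radius everywhere,
which over-satisfies the overlap needed for seamless blending without
ballooning ball counts. Arbors are traversed depth-first; since blending
is order-independent the traversal order only fixes array layout.

## Soma

**Origin-to-arbor marching** places one ball at the somatic sample and
marches a segment from the soma center to each arbor's first sample with
radii tapering linearly from the soma radius to the root radius. Blended
with the arbors this always yields a single connected iso-surface.

**Hybrid.** An icosphere (3 subdivisions) at the soma radius is relaxed
by overdamped Hooke dynamics: each step moves vertices along the net
spring force (rest lengths = initial edge lengths, stiffness 0.1, step
scale 0.5), plus, during the first 60% of the default 100 steps, a pull
drawing vertices inside a cone around each arbor-root direction toward
`pull_fraction` (default 0.4) of the root distance. The overdamped
(gradient-descent) form was chosen over a velocity integrator because it
makes the spring energy provably non-increasing once the pulls freeze,
which is the contract the tests check; connectivity is never edited, so
the result is always closed genus-0. The relaxed surface is remeshed into
a uniform cloud: area-weighted sampling at the hexagonal-packing budget
`area/(√3/2 · spacing²)`, 50 iterations of pairwise repulsion with
re-projection onto the surface (projection uses exact point-triangle
closest points with KD-tree candidate pruning). The contract is
uniformity — nearest-neighbor spacing CV ≤ 0.35, typically ~0.05 — not a
particular remeshing algorithm.

Each cloud vertex then becomes one ball with surface radius
`1.25 × max` nearest-neighbor spacing (enough overlap for a continuous
slab under the coverage condition: max spacing below the polygonization
resolution). The center is displaced inward along −normal by the
*blended iso-offset*: the distance at which the summed field of the
undisplaced configuration crosses the iso-level along the outward normal,
found by 30 bisection steps per vertex. Displacing by the single-ball
surface radius instead (the naive reading of "displace by the radius used
to build the metaball") leaves the neighbor-overlap bulge uncompensated
and inflates the exterior volume by ~20%; the blended offset brings the
exterior partition within ~6% of the input surface volume on a sphere
test. Polygonizing the meta-patches alone yields exactly two nested
partitions; the interior one is pruned downstream. In a full cell the
arbors' field can flood the somatic cavity, in which case the blend has a
single partition from the start and no pruning is needed.

## Endfeet

An endfoot arrives as an open 2-manifold triangle patch with per-vertex
thickness (treated as a diameter; a flag flips it to a radius). Skinning
one ball per raw vertex fragments, because edge lengths exceed the
thickness. The patch is midpoint-subdivided `L` times, `L` the smallest
level with max-edge/2^L ≤ min-thickness, capped at 6 (4^L face growth);
thickness is interpolated linearly, so its range never widens. The
`smooth` mode applies Loop-style weights after each split — Loop rather
than Catmull–Clark because the patches are triangular — with crease rules
on the boundary (boundary vertices average only along the boundary) so
the endfoot outline is not eroded. After subdivision each vertex becomes
a ball with surface radius thickness/2, producing a single closed slab.

## Polygonization and the resolution rule

The blended meta-object is sampled on an axis-aligned grid whose spacing
is the *fragmentation-avoidance resolution*: the minimum effective
surface radius over every meta-component — skeleton sample radii **and**
endfoot half-thicknesses — clamped to an optional user cap and a hard
floor of 0.05 µm (guard against pathological grids). Restricting the
rule to skeleton radii fragments the endfeet whenever the skeleton is
much thicker than the endfoot slabs, as with the synthetic generator's
defaults, so the rule is applied to all components. The grid is padded by
the largest influence radius plus two spacings; compact support then
makes the field exactly zero on the boundary, and the marching-cubes
extraction (scikit-image, Lewiner variant — topologically consistent
with asymptotic-decider disambiguation) returns a closed 2-manifold
surface: every edge in exactly two faces, zero non-manifold edges and
vertices. Faces are oriented counter-clockwise-outward (positive signed
volume). A resolution too coarse for the smallest ball raises an
explicit error instead of returning a fragmented or empty mesh.

## Mesh post-processing and QC

* **Partitions** — connected components over shared vertices
  (scipy sparse components), ordered by enclosed volume; the interior of
  a two-partition mesh is identified by triangle count (volume as
  tie-break) and *verified* nested by a ray-parity test before removal.
* **Decimation** — Garland–Heckbert quadric edge collapse with a
  lazy-deletion heap; collapses are rejected unless the link condition
  holds (manifoldness) and no incident face flips its normal; boundary
  vertices are pinned. Stops early if the target ratio is unreachable
  without breaking manifoldness. On closed genus-0 inputs the Euler
  characteristic is preserved and the bounding extent moves by well under
  1%.
* **Repair** — merge duplicate vertices (1e-6 µm), drop degenerate and
  duplicate faces, remove fins at over-shared edges (dangling faces
  first, then smallest area), fill boundary loops with centroid fans
  oriented to match neighboring winding, make orientation coherent and
  outward, keep the largest partition. Idempotent on its success set;
  residual defects surface in the QC report rather than being silently
  accepted.
* **QC** — non-manifold edges are edges with more than two incident
  faces (boundary edges counted separately); non-manifold vertices are
  vertices whose incident faces form more than one fan. Self-intersection
  counting uses a vectorized Möller triangle–triangle test on KD-tree
  candidate pairs and equals the all-pairs brute force by construction
  (tested on random soups). `watertight` requires one partition, all
  edges shared exactly twice, zero non-manifold elements and zero
  self-intersections — the hand-off condition for tetrahedral meshers.
* **Hausdorff** — symmetric RMS point-to-surface distance from
  area-weighted samples on both meshes (default 100k per side),
  normalized by the bounding-box diagonal of the first mesh (Metro
  convention); deterministic given the sampling seed.

## Synthetic data generator

The generator emulates the *shape class* the pipeline must handle, not
biological statistics: a single-sample soma (radius 6 µm) at the origin;
6 arbors, binary branching to order 4, section lengths 7 µm decaying by
0.8 per order; radii tapering by 0.8 per branch order so the smallest
skeleton radius is `6 × 0.8⁴ ≈ 2.46 µm`; sections sampled densely at
0.05 µm with a smooth, curvature-based meander (persistent turning axis,
~0.05 rad/µm) — smooth below the radius scale, as synthesized processes
are, so that resampling is a fair test rather than a corner-cutting one;
two endfeet patches (7×7 grids spanning ~100° of a 4 µm virtual vessel,
thickness uniform in [0.5, 1.5] µm, coarse enough to force subdivision).
All randomness flows through one seeded generator; outputs are
byte-identical across runs. Defect meshes (hole, fin, inverted winding,
nested shells) exercise the repair and QC paths.

What the generator does **not** model: space-filling microdomain
competition, synapse-driven branching statistics, realistic process
radii (real astrocyte processes are far thinner than the soma — here the
tapering is gentle so that desk-scale grids stay tractable), or endfeet
re-projected onto a real vasculature surface. Passing tests therefore
demonstrate the geometric guarantees (manifoldness, partition behavior,
fidelity under decimation) on this shape class, not morphometric realism.

## Numerical choices and problem sizes

Duplicate-vertex merge tolerance 1e-6 µm (far below any radius).
Field-evaluation equality between indexed and brute-force paths is exact
up to summation order (tolerance 1e-9 in tests). Bisection for the
hybrid displacement runs 30 iterations (resolution ~1e-9 of the search
interval). The default full-size astrocyte polygonizes to ~3.5×10⁵
triangles at 0.25 µm and takes a few seconds; its quadric decimation to
10% takes ~2 minutes; unit tests run scaled-down configurations (2–3
arbors, order 2, endfeet omitted where they are irrelevant to the
property under test) chosen to keep each property check sharp at small
problem sizes.

## Known limitations

* The repair pipeline's hole filling uses centroid fans: pathological
  (highly non-planar or self-crossing) boundary loops can produce
  self-intersecting fills; these are reported by QC, not hidden.
* Decimation treats the target ratio as a bound, not an exact count, and
  does not simplify across partition boundaries.
* The soft-body soma is a deliberately simple overdamped mass-spring
  model — a plausibility device, not a mechanical simulation.
* Self-intersection counting is exact but pairwise; it reports a count,
  not a repair (intersecting decimated meshes are for visualization
  only, matching the two-branch design).
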