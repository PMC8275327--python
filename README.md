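# astroskin

Watertight surface meshes of astrocytes from skeletal morphologies, by
metaball skinning.

Astrocytes are star-shaped glial cells whose geometry — a soma, a dense
sponge of branching processes, and flattened perivascular endfeet wrapping
blood vessels — is usually available only as a skeleton: SWC-style point
samples with radii, plus endfeet given as open triangle patches with a
per-vertex thickness. Reaction–diffusion simulation and large-scale
visualization both need closed surface geometry instead: a single,
2-manifold, self-intersection-free triangle mesh per cell that a
tetrahedral mesher (TetGen, Quartet, TetWild) will accept. Skinning such
branchy shapes with explicit surface operations routinely produces
self-intersections at acute branch angles; implicit surfaces do not.

`astroskin` is for computational neuroscientists who need those meshes
without a 3D-content-creation suite in the loop: it reads SWC + an endfeet
sidecar, skins every component with metaballs, polygonizes the blended
field, and emits QC'd watertight (simulation) and decimated
(visualization) meshes, as a Python library and a small CLI.

## Method

Every component is converted to a set of *metaballs* — points `c_i` with
compact-support kernels — and blended by plain field summation

    F(p) = Σ_i (1 − |p − c_i|²/R_i²)³   for |p − c_i| < R_i, else 0,

with the surface taken as the iso-level `F = 0.5` (Wyvill soft-object
kernel). A single ball's iso-surface is a sphere of radius
`R·√(1 − 0.5^{1/3}) ≈ 0.4542·R`, so a ball meant to render morphological
radius `r` stores influence radius `r/0.4542`.

* **Arbors** — sections are first adaptively resampled (a sample is kept
  once it is one local radius from the previously kept sample; endpoints
  verbatim), then each segment is sphere-marched: balls along the axis at
  most one local radius apart, radii interpolated between the two samples.
* **Soma** — either *origin-to-arbor marching* (one meta-soma ball plus a
  marched segment toward each arbor root; fast, guarantees a single
  partition) or the *hybrid* scheme: a Hooke mass-spring relaxation of an
  icosphere pulled toward the arbor roots, remeshed into a uniform point
  cloud, then one ball per cloud vertex displaced inward along the normal
  by the blended iso-offset so the exterior iso-surface reproduces the
  relaxed surface.
* **Endfeet** — patches are midpoint-subdivided (optionally with
  Loop-style smoothing) until the longest edge drops below the smallest
  per-vertex thickness, then skinned with one ball per vertex at surface
  radius thickness/2; without the subdivision the slab would fragment.
* **Polygonization** — marching cubes (Lewiner) on a grid at the
  fragmentation-avoidance resolution (the smallest effective surface
  radius over all components), padded so the field vanishes at the
  boundary; the extracted surface is therefore closed and 2-manifold with
  zero non-manifold edges and vertices.
* **Post-processing** — interior-partition pruning (ray-parity nesting
  check), quadric edge-collapse decimation for the visualization branch,
  and a repair pipeline (duplicate merge, fin removal, hole filling,
  orientation) plus a full QC report (partitions, manifoldness,
  self-intersections, area, volume) for the simulation branch.

## Worked example

```sh
python examples/02_resample_and_skin.py
```

```
samples 7807 -> 187 (cable length change 0.16%)
metaballs:            1713
grid resolution:      0.252 µm (min effective radius rule)
triangles:            346712
partitions:           1
surface area:         7397 µm²
enclosed volume:      29857 µm³
non-manifold edges:   0 (guaranteed 0)
```

A synthetic astrocyte (6 arbors, branch order 4, two endfeet) is
resampled from 7807 to 187 samples while changing total cable length by
0.16%, skinned into 1713 balls, and polygonized at 0.252 µm — half the
smallest endfoot thickness — into a single closed partition whose area
and volume are the quantities biologists read off these models. The other
examples cover morphology synthesis and I/O (`01`), the two soma schemes
(`03`), endfoot subdivision (`04`), and decimation/repair/QC (`05`).

Equivalent CLI:

```sh
astroskin synth --seed 42 --out cell
astroskin mesh --input cell.swc --endfeet cell.endfeet.h5 \
    --out meshes --branch simulation,visual --decimate 0.1
astroskin qc meshes/cell_simulation.obj
```

## Scope

The package starts from existing morphologies: skeleton *synthesis* and
tetrahedralization are out of scope — the simulation branch ends at a
watertight surface mesh ready for TetGen/Quartet/TetWild.
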