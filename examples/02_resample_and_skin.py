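"""Adaptive resampling + metaball skinning of one astrocyte.

Resamples the oversampled skeleton (kept samples one local radius apart),
skins soma/arbors/endfeet into one blended meta-object and polygonizes it
into a single closed triangle mesh.
"""

from astroskin import (
    MeshQCReport,
    PipelineConfig,
    ResamplingPolicy,
    SynthAstroParams,
    generate_astrocyte,
    mesh_morphology,
    morphometry_report,
    resample_morphology,
)
from astroskin import meshops

m = generate_astrocyte(SynthAstroParams(seed=42))
resampled = resample_morphology(m, ResamplingPolicy(spacing_factor=1.0))
cmp = morphometry_report(m, resampled)
print(f"samples {m.n_samples()} -> {resampled.n_samples()} "
      f"(cable length change {100 * cmp.relative_cable_change:.2f}%)")

mesh, info = mesh_morphology(m, PipelineConfig())
print(f"metaballs:            {info['n_balls']}")
print(f"grid resolution:      {info['resolution']:.3g} µm (min effective radius rule)")
print(f"triangles:            {len(mesh.faces)}")
print(f"partitions:           {info['partition_count_raw']}")

qc = meshops.mesh_metrics(mesh, check_self_intersections=False)
print(f"surface area:         {qc.surface_area:.0f} µm²")
print(f"enclosed volume:      {qc.volume:.0f} µm³")
print(f"non-manifold edges:   {qc.non_manifold_edges} (guaranteed 0)")

# A single watertight partition means the soma, every arbor and both endfeet
# blended into one continuous implicit surface at the chosen resolution.
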