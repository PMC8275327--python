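"""Endfoot subdivision and skinning.

Shows why a raw endfoot patch cannot be skinned directly (edge lengths far
above the per-vertex thickness fragment the implicit slab) and how midpoint
subdivision to the required level fixes it.
"""

import numpy as np

from astroskin import (
    SubdivisionSpec,
    meshops,
    polygonize,
    required_levels,
    skin_endfoot,
    subdivide_patch,
)
from astroskin.endfeet import FragmentationRiskError
from astroskin.morphology import EndfootPatch

# a flat 10x10 µm patch, 2 µm thick, tessellated with only 8 triangles
n = 3
xs = np.linspace(0, 10, n)
verts = np.array([[x, y, 0.0] for y in xs for x in xs])
tris = []
for i in range(n - 1):
    for j in range(n - 1):
        a = i * n + j
        tris += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
patch = EndfootPatch(vertices=verts, thickness=np.full(n * n, 2.0),
                     triangles=np.array(tris))

try:
    skin_endfoot(patch)
except FragmentationRiskError as exc:
    print(f"raw patch rejected: {exc}")

levels = required_levels(patch)
sub = subdivide_patch(patch, SubdivisionSpec(levels=levels, mode="simple"))
print(f"subdivision levels: {levels} "
      f"({len(patch.triangles)} -> {len(sub.triangles)} triangles, 4^L growth)")

mo = skin_endfoot(sub)
mesh = polygonize(mo)
print(f"skinned slab: {len(mo)} balls -> {len(mesh.faces)} faces, "
      f"{len(meshops.split_partitions(mesh))} closed component "
      f"(Euler characteristic {mesh.euler_number})")

# One ball per subdivided vertex with surface radius = thickness/2 produces
# a single smooth closed slab instead of a string of disconnected blobs.
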