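"""Measure 3D shape complexity (MCI) of voxelized organelle phantoms.

Builds a sphere and an elongated capsule at the reference SBF-SEM voxel size
(10 x 10 x 30 nm), meshes each binary mask and computes surface area, volume,
MCI and sphericity. The sphere should sit at the isoperimetric floor
9/(4 pi) ~= 0.716; the capsule scores higher because complexity grows with
surface area relative to volume.
"""

from mitomorph3d import (
    SPHERE_MCI,
    ShapeSpec,
    mci,
    mesh_from_mask,
    mesh_surface_area,
    mesh_volume,
    sphericity,
    voxelize,
)

for spec in (
    ShapeSpec("sphere", {"radius": 500.0}),
    ShapeSpec("capsule", {"radius": 200.0, "length": 2000.0}),
):
    volume, truth = voxelize(spec)
    mesh = mesh_from_mask(volume.labels > 0, volume.voxel_size)
    sa, v = mesh_surface_area(mesh), mesh_volume(mesh)
    print(f"{spec.kind}: SA = {sa * 1e-6:.3f} um^2, V = {v * 1e-9:.4f} um^3")
    print(f"  MCI = {mci(sa, v):.4f}  (sphere floor = {SPHERE_MCI:.4f})")
    print(f"  sphericity = {sphericity(sa, v):.4f}  (1 = perfect sphere)")

print(
    "\nThe capsule's higher MCI and lower sphericity quantify its elongation;\n"
    "both scores are independent of absolute organelle size."
)
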