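"""Per-organelle 3D morphometry: surface area, volume, MCI and sphericity.

The mitochondrial complexity index (MCI) is a dimensionless, scale-invariant
shape score

    MCI = SA^3 / (16 pi^2 V^2)

derived as the square of the 3D analogue of form factor. It is minimised by
the sphere at 9/(4 pi) ~= 0.7162 (the isoperimetric floor) and grows without
bound as branching and surface elaboration increase. Sphericity,
pi^(1/3) (6V)^(2/3) / SA, is the classical bounded alternative; the two are
linked exactly by MCI * sphericity^3 = 9/(4 pi).

Surface area and volume are measured on a closed triangle mesh of the
0.5-level isosurface of each organelle's binary mask, with the binary field
Gaussian-smoothed at sigma = 2.5x the finest voxel pitch beforehand. The
smoothing scale was calibrated on analytic sphere and capsule phantoms so
that meshed MCI agrees with the analytic value to within ~2% at the reference
(10, 10, 30) nm anisotropic voxel size; set ``mesh_smoothing_sigma_nm: 0`` to
mesh the raw binary field instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .io_formats import DEFAULT_CONFIG, LabeledVolume, SurfaceMesh

__all__ = [
    "OrganelleRecord",
    "SPHERE_MCI",
    "extract_organelles",
    "mesh_from_mask",
    "mesh_surface_area",
    "mesh_volume",
    "voxel_volume",
    "mci",
    "sphericity",
    "compute_morphometrics",
]

#: MCI of the perfect sphere, 9/(4 pi): the isoperimetric floor.
SPHERE_MCI = 9.0 / (4.0 * math.pi)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class OrganelleRecord:
    """One connected mitochondrion extracted from a labeled volume."""

    organelle_id: int
    label: int
    voxel_count: int
    touches_border: bool
    bbox: tuple = None
    mask: np.ndarray | None = None
    subject_id: str = ""
    cell_id: str = ""
    group: str = ""
    compartment: str = "IMF"
    volume_nm3: float | None = None
    surface_area_nm2: float | None = None
    voxel_volume_nm3: float | None = None
    mci: float | None = None
    sphericity: float | None = None
    flags: list = field(default_factory=list)


def extract_organelles(volume: LabeledVolume, exclude_border: bool = True):
    """Split a labeled volume into connected organelles (26-connectivity).

    Each connected component of each non-zero label becomes one record;
    diagonal voxel contacts are merged, mirroring outer-membrane continuity
    in manual tracing. Components touching the grid boundary are flagged
    ``touches_border``; with ``exclude_border`` they are returned flagged but
    should be omitted from population statistics (``compute_morphometrics``
    drops them). Returns a list of :class:`OrganelleRecord` stubs carrying a
    cropped copy of each component mask.
    """
    labels = volume.labels
    records: list[OrganelleRecord] = []
    ids = volume.label_ids
    if ids.size == 0:
        warnings.warn("labeled volume contains no organelles", stacklevel=2)
        return records
    next_id = 1
    shape = labels.shape
    for lab in ids:
        comp, n_comp = ndimage.label(labels == lab, structure=_STRUCT_26)
        slices = ndimage.find_objects(comp)
        for ci, sl in enumerate(slices, start=1):
            mask = comp[sl] == ci
            touches = any(
                s.start == 0 or s.stop == dim for s, dim in zip(sl, shape)
            )
            records.append(
                OrganelleRecord(
                    organelle_id=next_id,
                    label=int(lab),
                    voxel_count=int(mask.sum()),
                    touches_border=touches,
                    bbox=tuple((s.start, s.stop) for s in sl),
                    mask=mask,
                )
            )
            next_id += 1
    if exclude_border:
        for rec in records:
            if rec.touches_border:
                rec.flags.append("border")
    return records


def mesh_from_mask(
    mask: np.ndarray,
    voxel_size=DEFAULT_CONFIG["voxel_size"],
    smoothing_sigma_nm: float | None = None,
    upsample_min_extent_vox: int = 6,
    upsample_factor: int = 4,
) -> SurfaceMesh:
    """Closed, outward-oriented triangle mesh of a binary mask.

    ``mask`` is (z, y, x); ``voxel_size`` is (dx, dy, dz) in nm. The mesh is
    the 0.5-level marching-cubes isosurface of the (Gaussian pre-smoothed)
    indicator field, with vertices in physical nm. Objects thinner than
    ``upsample_min_extent_vox`` voxels on any axis are nearest-neighbour
    upsampled ``upsample_factor``-fold first so that few-voxel organelles
    still mesh to near their true volume. If smoothing would erase the object
    entirely (peak field <= 0.5) the raw binary field is meshed instead.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot mesh an empty mask")
    dx, dy, dz = (float(v) for v in voxel_size)
    objs = ndimage.find_objects(mask.astype(np.uint8))[0]
    mask = mask[objs]  # crop to content; padding below restores closure
    extents = mask.shape
    if min(extents) < upsample_min_extent_vox:
        k = upsample_factor
        mask = (
            np.repeat(np.repeat(np.repeat(mask, k, axis=0), k, axis=1), k, axis=2)
        )
        dx, dy, dz = dx / k, dy / k, dz / k
    if smoothing_sigma_nm is None:
        smoothing_sigma_nm = 2.5 * min(dx, dy, dz)
    field_ = np.pad(mask, 4).astype(np.float32)
    if smoothing_sigma_nm > 0:
        smoothed = ndimage.gaussian_filter(
            field_, sigma=(smoothing_sigma_nm / dz, smoothing_sigma_nm / dy, smoothing_sigma_nm / dx)
        )
        if smoothed.max() > 0.5:
            field_ = smoothed
    verts, faces, _, _ = measure.marching_cubes(field_, level=0.5, spacing=(dz, dy, dx))
    tm = trimesh.Trimesh(verts, faces, process=False)
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def _as_trimesh(mesh) -> trimesh.Trimesh:
    if isinstance(mesh, trimesh.Trimesh):
        return mesh
    return mesh.to_trimesh()


def _require_closed(tm: trimesh.Trimesh) -> None:
    if not tm.is_watertight:
        n_boundary = len(trimesh.grouping.group_rows(tm.edges_sorted, require_count=1))
        raise ValueError(f"mesh is not closed: {n_boundary} boundary edges")


def mesh_surface_area(mesh) -> float:
    """Total triangle area of a closed mesh, in nm^2."""
    tm = _as_trimesh(mesh)
    _require_closed(tm)
    return float(tm.area)


def mesh_volume(mesh) -> float:
    """Enclosed volume of a closed mesh (divergence theorem), nm^3.

    Inward-oriented meshes are reoriented; the result is always positive.
    """
    tm = _as_trimesh(mesh)
    _require_closed(tm)
    return float(abs(tm.volume))


def voxel_volume(mask: np.ndarray, voxel_size=DEFAULT_CONFIG["voxel_size"]) -> float:
    """Voxel-counting volume: count x dx dy dz, in nm^3."""
    dx, dy, dz = (float(v) for v in voxel_size)
    return float(np.count_nonzero(mask)) * dx * dy * dz


def mci(surface_area: float, volume: float) -> float:
    """Mitochondrial complexity index, SA^3 / (16 pi^2 V^2).

    Exactly scale invariant: mci(c^2 SA, c^3 V) == mci(SA, V) for any c > 0.
    """
    if surface_area <= 0 or volume <= 0:
        raise ValueError("mci requires SA > 0 and V > 0")
    return surface_area**3 / (16.0 * math.pi**2 * volume**2)


def sphericity(surface_area: float, volume: float) -> float:
    """Sphericity pi^(1/3) (6V)^(2/3) / SA; 1 for the perfect sphere."""
    if surface_area <= 0 or volume <= 0:
        raise ValueError("sphericity requires SA > 0 and V > 0")
    return math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area


def compute_morphometrics(
    volume: LabeledVolume,
    metadata: dict | None = None,
    config: dict | None = None,
):
    """Run extract -> mesh -> SA, V -> MCI, sphericity for a whole volume.

    Returns a pandas DataFrame (one completed row per retained organelle)
    alongside the full record list. Border-touching organelles are dropped
    when ``exclude_border``; per-organelle meshing failures are flagged on
    the record rather than aborting the batch. Deterministic given inputs.
    """
    import pandas as pd

    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    meta = {"subject_id": "s1", "cell_id": "c1", "group": "", "compartment": "IMF"}
    if metadata:
        meta.update(metadata)
    records = extract_organelles(volume, exclude_border=cfg["exclude_border"])
    tol = cfg["mesh_voxel_volume_tolerance"]
    rows = []
    for rec in records:
        rec.subject_id = meta["subject_id"]
        rec.cell_id = meta["cell_id"]
        rec.group = meta["group"]
        rec.compartment = meta["compartment"]
        if cfg["exclude_border"] and rec.touches_border:
            continue
        rec.voxel_volume_nm3 = rec.voxel_count * volume.voxel_volume_nm3
        if rec.voxel_count < cfg["min_reliable_voxels"]:
            rec.flags.append("few_voxels")
        try:
            mesh = mesh_from_mask(
                rec.mask,
                volume.voxel_size,
                smoothing_sigma_nm=cfg["mesh_smoothing_sigma_nm"],
                upsample_min_extent_vox=cfg["mesh_upsample_min_extent_vox"],
                upsample_factor=cfg["mesh_upsample_factor"],
            )
            rec.surface_area_nm2 = mesh_surface_area(mesh)
            rec.volume_nm3 = mesh_volume(mesh)
            rec.mci = mci(rec.surface_area_nm2, rec.volume_nm3)
            rec.sphericity = sphericity(rec.surface_area_nm2, rec.volume_nm3)
            if abs(rec.volume_nm3 - rec.voxel_volume_nm3) > tol * rec.voxel_volume_nm3:
                rec.flags.append("mesh_voxel_volume_mismatch")
                warnings.warn(
                    f"organelle {rec.organelle_id}: mesh volume deviates from voxel "
                    f"volume by more than {tol:.0%}",
                    stacklevel=2,
                )
        except Exception as exc:  # noqa: BLE001 - flagged, never aborts the batch
            rec.flags.append(f"mesh_failed:{exc}")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "cell_id": rec.cell_id,
                "organelle_id": rec.organelle_id,
                "group": rec.group,
                "compartment": rec.compartment,
                "volume_um3": None if rec.volume_nm3 is None else rec.volume_nm3 * 1e-9,
                "sa_um2": None if rec.surface_area_nm2 is None else rec.surface_area_nm2 * 1e-6,
                "mci": rec.mci,
                "sphericity": rec.sphericity,
                "voxel_count": rec.voxel_count,
                "flags": ";".join(rec.flags),
            }
        )
    return pd.DataFrame(rows), records
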