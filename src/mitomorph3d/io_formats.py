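"""Spatial data types and file formats.

The package works on integer-labeled 3D segmentation volumes as produced by
manual tracing of serial block face SEM stacks. Grids are stored in (z, y, x)
axis order with z the section/stack axis, which for transversely imaged muscle
is the fiber's longitudinal axis. All physical coordinates are nanometres
internally; tabular outputs convert to um^3 / um^2 at the table boundary only.

Supported formats: multi-page TIFF and MRC for label volumes, OBJ/STL/PLY for
triangle meshes, CSV for metrics tables, YAML for configuration.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh
import yaml

__all__ = [
    "LabeledVolume",
    "SurfaceMesh",
    "FormatError",
    "ConfigurationError",
    "DEFAULT_CONFIG",
    "read_labeled_volume",
    "write_labeled_volume",
    "read_mesh",
    "write_mesh",
    "write_metrics_table",
    "read_metrics_table",
    "load_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ConfigurationError(ValueError):
    """Invalid or incomplete configuration."""


#: Voxel size of the reference SBF-SEM acquisition: 10 nm in-plane, 30 nm
#: section thickness, as (dx, dy, dz).
DEFAULT_VOXEL_SIZE = (10.0, 10.0, 30.0)

#: Documented defaults for every tunable the package exposes. Values are nm
#: unless stated otherwise.
DEFAULT_CONFIG: dict = {
    "voxel_size": list(DEFAULT_VOXEL_SIZE),
    "longitudinal_axis": "z",
    "exclude_border": True,
    "min_reliable_voxels": 20,
    "mesh_smoothing_sigma_nm": None,  # None -> 2.5 x finest voxel pitch
    "mesh_upsample_min_extent_vox": 6,
    "mesh_upsample_factor": 4,
    "mesh_voxel_volume_tolerance": 0.10,
    "myofibril_width_nm": 1000.0,
    "sarcomere_length_nm": 2000.0,
    "nanotunnel_d_max_nm": 250.0,
    "nanotunnel_l_min_nm": 50.0,
    "membrane_correction_nm": 24.0,
    "nucleoid_diameter_nm": 110.0,
    "kurtosis_convention": "raw",  # "raw" (Pearson) or "excess" (Fisher)
    "simple_percentile": 10.0,
    "complex_percentile": 90.0,
}

_METRICS_COLUMNS = [
    "subject_id",
    "cell_id",
    "organelle_id",
    "group",
    "compartment",
    "volume_um3",
    "sa_um2",
    "mci",
    "sphericity",
    "mbi",
    "mbi_class",
    "spans_sarcomere",
    "n_nanotunnels",
]

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass
class LabeledVolume:
    """Integer-labeled anisotropic voxel grid.

    Parameters
    ----------
    labels
        3D integer array in (z, y, x) order; 0 is background, k > 0 an
        organelle id.
    voxel_size
        Physical voxel pitch (dx, dy, dz) in nm.
    longitudinal_axis
        Which grid axis runs along the muscle fiber. Default "z": the stack
        axis, since acquisition is transverse.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    longitudinal_axis: str = "z"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"labels must be integers, got dtype {self.labels.dtype}")
        if self.labels.min() < 0:
            raise FormatError("labels must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        if self.longitudinal_axis not in _AXIS_INDEX:
            raise ConfigurationError(
                f"longitudinal_axis must be one of {sorted(_AXIS_INDEX)}, got {self.longitudinal_axis!r}"
            )

    @property
    def longitudinal_index(self) -> int:
        """Array axis index (into the (z, y, x) grid) of the fiber axis."""
        return _AXIS_INDEX[self.longitudinal_axis]

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel pitch reordered to match the (z, y, x) array axes."""
        dx, dy, dz = self.voxel_size
        return (dz, dy, dx)

    @property
    def label_ids(self) -> np.ndarray:
        """Sorted non-zero labels present in the grid."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def voxel_volume_nm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


@dataclass
class SurfaceMesh:
    """Closed triangle mesh with vertices in physical nm coordinates."""

    vertices: np.ndarray
    faces: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("faces must be (m, 3) triangles")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight


def read_labeled_volume(path, voxel_size=None, longitudinal_axis="z") -> LabeledVolume:
    """Read a multi-page TIFF or MRC stack of integer labels.

    ``voxel_size`` (dx, dy, dz in nm) overrides anything recorded in the file
    header. For TIFF, which carries no physical unit here, a missing
    ``voxel_size`` is a configuration error. For MRC the cell dimensions in
    the header are used when ``voxel_size`` is None.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if not np.issubdtype(data.dtype, np.integer):
            raise FormatError(
                f"{path}: expected integer labels, found {data.dtype} pixel data"
            )
        if voxel_size is None:
            raise ConfigurationError(
                f"{path}: TIFF carries no voxel size; pass voxel_size=(dx, dy, dz) in nm"
            )
        return LabeledVolume(data, voxel_size, longitudinal_axis)
    if suffix in {".mrc", ".rec", ".st"}:
        data, header_voxel = _read_mrc(path)
        if not np.issubdtype(data.dtype, np.integer):
            raise FormatError(f"{path}: expected integer labels, found {data.dtype}")
        vs = voxel_size if voxel_size is not None else header_voxel
        if vs is None:
            raise ConfigurationError(f"{path}: no voxel size in MRC header and none given")
        return LabeledVolume(data, vs, longitudinal_axis)
    raise FormatError(f"{path}: unsupported volume format {suffix!r} (use TIFF or MRC)")


def write_labeled_volume(volume: LabeledVolume, path) -> None:
    """Write a labeled volume as multi-page TIFF or MRC (by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, volume.labels)
    elif suffix in {".mrc", ".rec", ".st"}:
        _write_mrc(path, volume.labels, volume.voxel_size)
    else:
        raise FormatError(f"{path}: unsupported volume format {suffix!r}")


# ---------------------------------------------------------------------------
# Minimal MRC2014 support (header words 1-13 + cella + map stamp). Data is
# stored x-fastest, so the numpy array shape is (nz, ny, nx) matching the
# internal (z, y, x) order. Cell dimensions are written in nm.
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODE_OF = {np.dtype(v): k for k, v in _MRC_MODES.items()}


def _read_mrc(path: Path):
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise FormatError(f"{path}: truncated MRC header ({len(raw)} bytes)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from("<3f", raw, 40)
    if mode not in _MRC_MODES:
        raise FormatError(f"{path}: unsupported MRC mode {mode}")
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=1024)
    if data.size != count:
        raise FormatError(f"{path}: truncated MRC data section")
    data = data.reshape(nz, ny, nx)
    voxel = None
    if mx > 0 and my > 0 and mz > 0 and xlen > 0 and ylen > 0 and zlen > 0:
        voxel = (xlen / mx, ylen / my, zlen / mz)
    return np.ascontiguousarray(data), voxel


def _write_mrc(path: Path, labels: np.ndarray, voxel_size) -> None:
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError("MRC label writer requires integer data")
    lo, hi = int(labels.min()), int(labels.max())
    if lo >= 0 and hi <= np.iinfo(np.uint16).max:
        data = labels.astype(np.uint16)
    elif np.iinfo(np.int16).min <= lo and hi <= np.iinfo(np.int16).max:
        data = labels.astype(np.int16)
    else:
        raise FormatError(f"label range [{lo}, {hi}] exceeds 16-bit MRC modes")
    mode = _MRC_MODE_OF[data.dtype]
    nz, ny, nx = data.shape
    dx, dy, dz = voxel_size
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * dx, ny * dy, nz * dz)  # cella, nm
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mesh(path) -> SurfaceMesh:
    """Read an OBJ/STL/PLY triangle mesh (coordinates taken as nm)."""
    path = Path(path)
    try:
        tm = trimesh.load_mesh(path, process=False)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"{path}: unreadable mesh file ({exc})") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"{path}: file contains no triangle mesh")
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_mesh(mesh: SurfaceMesh, path, file_format=None) -> None:
    """Write a mesh as OBJ, STL or PLY. Non-watertight meshes warn."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in {"obj", "stl", "ply"}:
        raise FormatError(f"unsupported mesh format {fmt!r} (use obj, stl or ply)")
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        warnings.warn(f"{path}: writing non-watertight mesh", stacklevel=2)
    tm.export(path, file_type=fmt)


def write_metrics_table(table: pd.DataFrame, path) -> None:
    """Write per-organelle metrics as CSV with a units header comment.

    The (subject_id, cell_id, organelle_id) key triple must be unique and
    volume/surface area strictly positive on completed rows.
    """
    table = table.copy()
    key = ["subject_id", "cell_id", "organelle_id"]
    missing = [c for c in key if c not in table.columns]
    if missing:
        raise ConfigurationError(f"metrics table missing key columns {missing}")
    if table.duplicated(subset=key).any():
        dupes = table.loc[table.duplicated(subset=key), key].iloc[0].tolist()
        raise ConfigurationError(f"duplicate organelle key {tuple(dupes)}")
    for col in ("volume_um3", "sa_um2"):
        if col in table.columns:
            bad = table[col].notna() & (table[col] <= 0)
            if bad.any():
                raise ConfigurationError(f"non-positive {col} in completed rows")
    cols = [c for c in _METRICS_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    with open(path, "w") as fh:
        fh.write("# mitomorph3d metrics: volume_um3 in um^3, sa_um2 in um^2, lengths in nm\n")
        table[cols].to_csv(fh, index=False)


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_config(path=None, **overrides) -> dict:
    """Load a YAML config and merge it (then overrides) over defaults.

    Unknown keys raise a :class:`ConfigurationError` listing valid keys.
    """
    config = dict(DEFAULT_CONFIG)
    sources = []
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        sources.append(loaded)
    sources.append({k: v for k, v in overrides.items() if v is not None})
    for source in sources:
        for k, v in source.items():
            if k not in DEFAULT_CONFIG:
                raise ConfigurationError(
                    f"unknown config key {k!r}; valid keys: {sorted(DEFAULT_CONFIG)}"
                )
            config[k] = v
    return config
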