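"""Synthetic voxel phantoms and cohort populations with known ground truth.

No public image stacks exist for this kind of serial block face SEM
morphometry, so every downstream module is exercised on synthetic data whose
truth is known by construction:

* :func:`voxelize` renders analytic solids (spheres, capsules, tube
  networks, nanotunnel dumbbells and blind protrusions) into anisotropic
  label grids, attaching analytic surface area / volume where defined.
* :func:`generate_fiber_volume` emulates the sarcomere-registered IMF
  network: organelles seeded at z-band planes with a controllable
  transverse / equal / longitudinal branching mix and optional nanotunnels,
  kept at least one background voxel apart so connected-component
  extraction is unambiguous (mirroring distinct-outer-membrane
  segmentation).
* :func:`generate_cohort` draws hierarchical lognormal metric populations
  (person / cell / within-cell components) at the multi-level spreads
  reported for healthy human muscle, with a disease group re-weighted to
  place a target mass of organelles below the control 10th MCI percentile
  and to carry an elevated nanotunnel rate.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DEFAULT_VOXEL_SIZE, LabeledVolume
from .population import CohortSummary

__all__ = [
    "ShapeSpec",
    "CohortSpec",
    "GeneratedCohort",
    "sphere_truth",
    "capsule_truth",
    "voxelize",
    "generate_fiber_volume",
    "generate_cohort",
]

#: MCI isoperimetric floor (sphere value), used as the offset of the
#: complexity distribution so generated MCIs are always attainable shapes.
_MCI_FLOOR = 9.0 / (4.0 * math.pi)

_KINDS = {"sphere", "capsule", "tube_network", "nanotunnel_dumbbell", "nanotunnel_protrusion"}


@dataclass
class ShapeSpec:
    """Analytic solid to voxelize.

    kind-specific ``params`` (all nm, axes as (z, y, x) unit-ish vectors):

    - sphere: ``radius``
    - capsule: ``radius``, ``length`` (cylindrical part), ``axis``
    - tube_network: ``segments`` [(p0, p1, radius), ...] relative to center
    - nanotunnel_dumbbell: ``body_radius``, ``tube_radius``, ``tube_length``
      (surface-to-surface), ``axis``
    - nanotunnel_protrusion: ``body_radius``, ``tube_radius``,
      ``tube_length`` (beyond the body surface), ``axis``
    """

    kind: str
    params: dict = field(default_factory=dict)
    label: int = 1

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; valid: {sorted(_KINDS)}")


def sphere_truth(radius: float) -> dict:
    return {
        "surface_area_nm2": 4.0 * math.pi * radius**2,
        "volume_nm3": 4.0 / 3.0 * math.pi * radius**3,
    }


def capsule_truth(radius: float, length: float) -> dict:
    """Analytic SA/V of a capsule (cylinder of ``length`` with hemispherical caps)."""
    return {
        "surface_area_nm2": 4.0 * math.pi * radius**2 + 2.0 * math.pi * radius * length,
        "volume_nm3": 4.0 / 3.0 * math.pi * radius**3 + math.pi * radius**2 * length,
    }


def _axis_vector(axis) -> np.ndarray:
    if isinstance(axis, str):
        return {"z": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "x": np.array([0, 0, 1.0])}[axis]
    v = np.asarray(axis, dtype=float)
    return v / np.linalg.norm(v)


def _segments_for(spec: ShapeSpec):
    """Shape as a union of capsule segments [(p0, p1, radius)] about the origin."""
    p = spec.params
    if spec.kind == "sphere":
        r = p["radius"]
        return [(np.zeros(3), np.zeros(3), r)], sphere_truth(r)
    if spec.kind == "capsule":
        r, length = p["radius"], p["length"]
        u = _axis_vector(p.get("axis", "x"))
        half = u * length / 2.0
        return [(-half, half, r)], capsule_truth(r, length)
    if spec.kind == "tube_network":
        segs = [(np.asarray(a, float), np.asarray(b, float), r) for a, b, r in p["segments"]]
        return segs, {}
    if spec.kind == "nanotunnel_dumbbell":
        R, rt, lt = p["body_radius"], p["tube_radius"], p["tube_length"]
        u = _axis_vector(p.get("axis", "x"))
        c = u * (R + lt / 2.0)  # body centers at +-c
        truth = {
            "tube_length_nm": lt,
            "tube_diameter_nm": 2.0 * rt,
            "body_radius_nm": R,
            "n_nanotunnels": 1,
            "end_status": "connecting",
        }
        return [(-c, -c, R), (c, c, R), (-c, c, rt)], truth
    if spec.kind == "nanotunnel_protrusion":
        R, rt, lt = p["body_radius"], p["tube_radius"], p["tube_length"]
        u = _axis_vector(p.get("axis", "x"))
        truth = {
            "tube_length_nm": lt,
            "tube_diameter_nm": 2.0 * rt,
            "body_radius_nm": R,
            "n_nanotunnels": 1,
            "end_status": "free_ended",
        }
        return [(np.zeros(3), np.zeros(3), R), (np.zeros(3), u * (R + lt), rt)], truth
    raise AssertionError(spec.kind)


def _rasterize_segments(segments, voxel_size, margin_vox=3):
    """Binary (z, y, x) mask of a union of capsules, centered in the grid."""
    dx, dy, dz = (float(v) for v in voxel_size)
    pitch = np.array([dz, dy, dx])
    pts = np.array([q for a, b, r in segments for q in (a - r, a + r, b - r, b + r)])
    # lattice centered on the shape: symmetric sampling avoids a half-voxel
    # erosion bias on one side of the solid
    center = (pts.min(axis=0) + pts.max(axis=0)) / 2.0
    half_n = np.ceil((pts.max(axis=0) - center) / pitch).astype(int) + margin_vox
    shape = 2 * half_n + 1
    zz = center[0] + (np.arange(shape[0]) - half_n[0]) * pitch[0]
    yy = center[1] + (np.arange(shape[1]) - half_n[1]) * pitch[1]
    xx = center[2] + (np.arange(shape[2]) - half_n[2]) * pitch[2]
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    coords = np.stack([Z, Y, X], axis=-1)
    mask = np.zeros(shape, dtype=bool)
    for a, b, r in segments:
        a, b = np.asarray(a, float), np.asarray(b, float)
        ab = b - a
        denom = float(ab @ ab)
        rel = coords - a
        if denom == 0:
            d2 = (rel**2).sum(axis=-1)
        else:
            t = np.clip((rel @ ab) / denom, 0.0, 1.0)
            d2 = ((rel - t[..., None] * ab) ** 2).sum(axis=-1)
        mask |= d2 <= r**2
    return mask


def voxelize(spec: ShapeSpec, voxel_size=DEFAULT_VOXEL_SIZE, margin_vox=3):
    """Render a shape into a labeled volume; returns (LabeledVolume, truth).

    The truth dict carries analytic SA/V where defined (sphere, capsule) and
    tube geometry for the nanotunnel phantoms. The shape is centered with a
    ``margin_vox`` background border; a margin below 1 voxel would let the
    solid touch the grid boundary and is an error.
    """
    if margin_vox < 1:
        raise ValueError("margin_vox must be >= 1 so the shape stays off the border")
    segments, truth = _segments_for(spec)
    mask = _rasterize_segments(segments, voxel_size, margin_vox)
    labels = np.where(mask, np.int32(spec.label), np.int32(0))
    truth = dict(truth)
    truth["kind"] = spec.kind
    truth["label"] = spec.label
    return LabeledVolume(labels, voxel_size), truth


def generate_fiber_volume(
    n_columns=(2, 2),
    n_planes=2,
    sarcomere_length: float = 2000.0,
    myofibril_width: float = 1000.0,
    voxel_size=DEFAULT_VOXEL_SIZE,
    class_mix=(0.404, 0.506, 0.091),
    occupancy: float = 1.0,
    nanotunnel_rate_per_100: float = 0.0,
    body_radius: float = 160.0,
    tube_radius: float = 50.0,
    seed: int = 0,
):
    """Sarcomere-registered phantom network with per-organelle truth.

    Organelles are seeded on a checkerboard of (column, column, z-band
    plane) cells — the parity gap guarantees >= 1 background voxel between
    organelles, honouring the distinct-outer-membrane segmentation rule.
    Each organelle is drawn as transverse (a capsule across the fiber
    bridging 1-2 myofibril widths), equal (a compact blob), or longitudinal
    (a capsule along the fiber spanning a half or full sarcomere), per
    ``class_mix`` = (transverse, equal, longitudinal). A fraction of equal
    organelles set by ``nanotunnel_rate_per_100`` becomes a two-body
    dumbbell joined by a thin connecting nanotunnel.

    Returns (LabeledVolume, truth DataFrame, zband_positions). Raises if the
    requested geometry cannot be placed without contact.
    """
    rng = np.random.default_rng(seed)
    mix = np.asarray(class_mix, dtype=float)
    if mix.min() < 0 or mix.sum() <= 0:
        raise ValueError("class_mix must be non-negative with positive sum")
    mix = mix / mix.sum()
    dx, dy, dz = (float(v) for v in voxel_size)
    w, s = float(myofibril_width), float(sarcomere_length)
    # private cell per organelle; transverse capsules may reach into the
    # (empty) parity-neighbour cell but never beyond it
    cell_xy = 1.3 * w
    max_trans_extent = 2.0 * w + 3.0 * body_radius
    if max_trans_extent >= 2.0 * cell_xy - 2.0 * max(dx, dy):
        raise ValueError(
            "organelles too large for the cell grid: would touch a neighbour"
        )
    nz_per_plane = int(round(s / dz))
    nx_per_cell = int(round(cell_xy / dx))
    ny_per_cell = int(round(cell_xy / dy))
    ncy, ncx = int(n_columns[0]), int(n_columns[1])
    shape = (
        (n_planes + 1) * nz_per_plane,
        (ncy + 2) * ny_per_cell,
        (ncx + 2) * nx_per_cell,
    )
    labels = np.zeros(shape, dtype=np.int32)
    pitch = np.array([dz, dy, dx])
    zband_positions = [(p + 0.5) * nz_per_plane * dz for p in range(n_planes)]
    truth_rows = []
    label = 0
    for p in range(n_planes):
        for iy in range(ncy):
            for ix in range(ncx):
                if (p + iy + ix) % 2:
                    continue  # parity gap guarantees separation
                if rng.random() > occupancy:
                    continue
                label += 1
                center = np.array(
                    [
                        zband_positions[p],
                        (iy + 1.5) * ny_per_cell * dy,
                        (ix + 1.5) * nx_per_cell * dx,
                    ]
                )
                cls = ("transverse", "equal", "longitudinal")[
                    int(rng.choice(3, p=mix))
                ]
                has_nt = False
                if cls == "transverse":
                    m = int(rng.integers(1, 3))  # myofibrils bridged
                    # single in-plane orientation: perpendicular 2-width rods
                    # in diagonally adjacent cells would otherwise touch
                    axis = "x"
                    # centerline spans m widths plus one body radius of slack
                    # so the (slightly shrunken) voxel skeleton still covers
                    # the full m myofibril widths
                    half_len = (m * w + body_radius) / 2.0
                    segs = [
                        (
                            center - _axis_vector(axis) * half_len,
                            center + _axis_vector(axis) * half_len,
                            body_radius,
                        )
                    ]
                    counts = (m, 0, 0, 0)
                    extent_l = 2.0 * body_radius
                elif cls == "longitudinal":
                    # full-sarcomere spanners only at the top plane: grown
                    # upward they would reach the z-range of the next plane's
                    # transverse rods in neighbouring columns
                    full = (p == n_planes - 1) and rng.random() < 0.5
                    length = (s if full else s / 2.0) + body_radius
                    # grow upward from the home plane; parity neighbour above is empty
                    segs = [
                        (center, center + np.array([length, 0.0, 0.0]), body_radius)
                    ]
                    counts = (0, 1, 0, 0) if full else (0, 0, 1, 0)
                    extent_l = length + 2.0 * body_radius
                else:
                    has_nt = rng.random() < nanotunnel_rate_per_100 / 100.0
                    if has_nt:
                        # short connecting tunnel: keeps the dumbbell's total
                        # span under one myofibril width, so its branching
                        # class stays "equal"
                        gap = 300.0
                        u = _axis_vector("x")
                        c1 = center - u * (body_radius + gap / 2.0)
                        c2 = center + u * (body_radius + gap / 2.0)
                        segs = [(c1, c1, body_radius), (c2, c2, body_radius), (c1, c2, tube_radius)]
                    else:
                        segs = [(center, center, body_radius)]
                    counts = (0, 0, 0, 0)
                    extent_l = 2.0 * body_radius
                _stamp_segments(labels, segs, pitch, label)
                truth_rows.append(
                    {
                        "label": label,
                        "mbi_class_truth": cls,
                        "myofibrils_bridged": counts[0],
                        "sarcomeres": counts[1],
                        "half_sarcomeres": counts[2],
                        "z_bands": counts[3],
                        "longitudinal_extent_nm": extent_l,
                        "has_nanotunnel": has_nt,
                        "home_plane_nm": zband_positions[p],
                    }
                )
    volume = LabeledVolume(labels, voxel_size)
    truth = pd.DataFrame(truth_rows)
    if label == 0:
        raise ValueError("no organelles generated; increase occupancy or grid size")
    return volume, truth, zband_positions


def _stamp_segments(labels, segments, pitch, label):
    """Rasterize capsules into the label grid (bounding-box restricted)."""
    shape = labels.shape
    for a, b, r in segments:
        lo = np.minimum(a, b) - r - pitch
        hi = np.maximum(a, b) + r + pitch
        i0 = np.maximum(np.floor(lo / pitch).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / pitch).astype(int) + 1, shape)
        if (i0 >= i1).any():
            continue
        zz = np.arange(i0[0], i1[0]) * pitch[0]
        yy = np.arange(i0[1], i1[1]) * pitch[1]
        xx = np.arange(i0[2], i1[2]) * pitch[2]
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        coords = np.stack([Z, Y, X], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        rel = coords - a
        if denom == 0:
            d2 = (rel**2).sum(axis=-1)
        else:
            t = np.clip((rel @ ab) / denom, 0.0, 1.0)
            d2 = ((rel - t[..., None] * ab) ** 2).sum(axis=-1)
        region = labels[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]]
        inside = d2 <= r**2
        clash = inside & (region != 0) & (region != label)
        if clash.any():
            raise ValueError("organelle placement collision: density too high")
        region[inside] = label


@dataclass
class CohortSpec:
    """Statistical cohort recipe; defaults follow the healthy-human study design.

    Volume is lognormal with natural-log SDs at the three nesting levels
    (within-cell 0.81, between-cell 0.14, between-person 0.28); MCI is the
    sphere floor plus a lognormal with the corresponding reported spreads.
    The disease group re-weights complexity so that ``disease_simple_mass``
    of its organelles fall below the control 10th percentile and draws
    nanotunnels at ``disease_nanotunnel_rate`` per 100 mitochondria (other
    features are drawn from the control distributions, so group differences
    are confined to simple-fraction and nanotunnel frequency by default).
    """

    n_control: int = 8
    n_disease: int = 6
    cells_per_subject: int = 3
    mitos_per_cell: int = 50
    log_volume_mean: float = math.log(0.25)  # ln um^3
    vol_sd_within: float = 0.81
    vol_sd_cell: float = 0.14
    vol_sd_person: float = 0.28
    log_mci_mean: float = math.log(1.3)  # ln of (MCI - sphere floor)
    mci_sd_within: float = 0.68
    mci_sd_cell: float = 0.26
    mci_sd_person: float = 0.43
    mbi_mix: tuple = (0.404, 0.506, 0.091)
    control_nanotunnel_rate: float = 2.1  # per 100 mitochondria
    disease_nanotunnel_rate: float = 38.0
    disease_simple_mass: float = 0.46
    volume_density_mean: float = 2.6  # percent, both groups by default
    volume_density_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.disease_simple_mass <= 1.0:
            raise ValueError("disease_simple_mass must be in [0, 1]")
        if min(self.control_nanotunnel_rate, self.disease_nanotunnel_rate) < 0:
            raise ValueError("nanotunnel rates must be >= 0")


@dataclass
class GeneratedCohort:
    metrics: pd.DataFrame
    summaries: list  # CohortSummary per individual, generator truth
    q10_mci: float
    q90_mci: float
    q10_vol: float
    q90_vol: float


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Draw a two-group hierarchical cohort with truth summaries attached."""
    rng = np.random.default_rng(spec.seed)
    rows = []

    def _draw_subject(subject_id, group):
        pv = rng.normal(0.0, spec.vol_sd_person)
        pm = rng.normal(0.0, spec.mci_sd_person)
        for c in range(spec.cells_per_subject):
            cv = rng.normal(0.0, spec.vol_sd_cell)
            cm = rng.normal(0.0, spec.mci_sd_cell)
            for k in range(spec.mitos_per_cell):
                vol = math.exp(
                    spec.log_volume_mean + pv + cv + rng.normal(0.0, spec.vol_sd_within)
                )
                mci = _MCI_FLOOR + math.exp(
                    spec.log_mci_mean + pm + cm + rng.normal(0.0, spec.mci_sd_within)
                )
                cls = ("transverse", "equal", "longitudinal")[
                    int(rng.choice(3, p=np.asarray(spec.mbi_mix) / np.sum(spec.mbi_mix)))
                ]
                rows.append(
                    {
                        "subject_id": subject_id,
                        "cell_id": f"{subject_id}_c{c + 1}",
                        "organelle_id": k + 1,
                        "group": group,
                        "compartment": "IMF",
                        "volume_um3": vol,
                        "mci": mci,
                        "mbi_class": cls,
                    }
                )

    for i in range(spec.n_control):
        _draw_subject(f"control_{i + 1}", "control")
    for i in range(spec.n_disease):
        _draw_subject(f"disease_{i + 1}", "disease")
    df = pd.DataFrame(rows)

    control = df[df["group"] == "control"]
    q10_mci = float(np.quantile(control["mci"], 0.10))
    q90_mci = float(np.quantile(control["mci"], 0.90))
    q10_vol = float(np.quantile(control["volume_um3"], 0.10))
    q90_vol = float(np.quantile(control["volume_um3"], 0.90))

    # disease tail re-weighting: mixture of below-q10 resamples and
    # control-like draws so the pooled below-q10 mass hits the target
    m = spec.disease_simple_mass
    if m > 0:
        base_mass = 0.10
        if m < base_mass:
            raise ValueError(
                f"infeasible disease_simple_mass {m}: below the control baseline {base_mass}"
            )
        p_mix = (m - base_mass) / (1.0 - base_mass)
        simple_pool = control.loc[control["mci"] < q10_mci, "mci"].to_numpy()
        disease_idx = df.index[df["group"] == "disease"]
        replace = rng.random(disease_idx.size) < p_mix
        resampled = rng.choice(simple_pool, size=int(replace.sum()), replace=True)
        df.loc[disease_idx[replace], "mci"] = resampled

    summaries = []
    for sid, sub in df.groupby("subject_id", sort=True):
        group = sub["group"].iloc[0]
        rate = (
            spec.control_nanotunnel_rate
            if group == "control"
            else spec.disease_nanotunnel_rate
        )
        n_mito = len(sub)
        n_nt = int(rng.poisson(rate * n_mito / 100.0))
        summaries.append(
            CohortSummary(
                subject_id=sid,
                group=group,
                pct_simple=100.0 * float((sub["mci"] < q10_mci).mean()),
                pct_complex=100.0 * float((sub["mci"] > q90_mci).mean()),
                pct_small=100.0 * float((sub["volume_um3"] < q10_vol).mean()),
                pct_large=100.0 * float((sub["volume_um3"] > q90_vol).mean()),
                median_mci=float(sub["mci"].median()),
                median_volume=float(sub["volume_um3"].median()),
                volume_density_pct=max(
                    0.1, float(rng.normal(spec.volume_density_mean, spec.volume_density_sd))
                ),
                nanotunnels_per_100=100.0 * n_nt / n_mito,
            )
        )
    return GeneratedCohort(df, summaries, q10_mci, q90_mci, q10_vol, q90_vol)
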