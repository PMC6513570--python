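import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomorph3d import (
    LabeledVolume,
    ShapeSpec,
    SPHERE_MCI,
    compute_morphometrics,
    extract_organelles,
    mci,
    mesh_from_mask,
    mesh_surface_area,
    mesh_volume,
    sphericity,
    voxel_volume,
    voxelize,
)
from mitomorph3d.io_formats import SurfaceMesh
from mitomorph3d.synthetic import capsule_truth

VOXEL = (10.0, 10.0, 30.0)


def _analytic_mci(truth):
    return mci(truth["surface_area_nm2"], truth["volume_nm3"])


class TestMciAndSphericity:
    def test_sphere_scores_the_isoperimetric_floor(self):
        assert mci(4 * math.pi, 4 * math.pi / 3) == pytest.approx(SPHERE_MCI, abs=1e-12)

    def test_capsule_analytic_value(self):
        # r = 1, cylindrical length 10: SA = 24 pi, V = 34 pi / 3
        t = capsule_truth(1.0, 10.0)
        assert t["surface_area_nm2"] == pytest.approx(24 * math.pi)
        assert t["volume_nm3"] == pytest.approx(34 * math.pi / 3)
        assert _analytic_mci(t) == pytest.approx(2.1412, abs=2e-4)
        assert sphericity(t["surface_area_nm2"], t["volume_nm3"]) == pytest.approx(
            68 ** (2 / 3) / 24, abs=1e-12
        )

    def test_exact_scale_invariance(self):
        base = mci(24 * math.pi, 34 * math.pi / 3)
        for c in (0.01, 10.0, 1e4):
            assert mci(c**2 * 24 * math.pi, c**3 * 34 * math.pi / 3) == pytest.approx(
                base, rel=1e-12
            )

    @given(
        sa=st.floats(min_value=1e-3, max_value=1e9),
        v=st.floats(min_value=1e-3, max_value=1e9),
    )
    @settings(max_examples=100, deadline=None)
    def test_mci_sphericity_identity(self, sa, v):
        # MCI * sphericity^3 == 9 / (4 pi) for any positive SA, V
        assert mci(sa, v) * sphericity(sa, v) ** 3 == pytest.approx(SPHERE_MCI, rel=1e-12)

    @pytest.mark.parametrize("sa,v", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_non_positive_inputs_are_domain_errors(self, sa, v):
        with pytest.raises(ValueError):
            mci(sa, v)
        with pytest.raises(ValueError):
            sphericity(sa, v)


class TestExtraction:
    def test_two_disjoint_blobs_of_one_label_become_two_records(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[1:3, 1:3, 1:3] = 1
        labels[4:6, 4:6, 4:6] = 1  # touches border
        vol = LabeledVolume(labels, VOXEL)
        recs = extract_organelles(vol, exclude_border=False)
        assert len(recs) == 2

    def test_diagonal_contact_merges_under_26_connectivity(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[1, 1, 1] = 1
        labels[2, 2, 2] = 1
        recs = extract_organelles(LabeledVolume(labels, VOXEL), exclude_border=False)
        assert len(recs) == 1

    def test_border_touching_component_is_flagged(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0:2, 1:3, 1:3] = 1
        recs = extract_organelles(LabeledVolume(labels, VOXEL))
        assert recs[0].touches_border and "border" in recs[0].flags

    def test_all_background_volume_warns_and_returns_empty(self):
        vol = LabeledVolume(np.zeros((3, 3, 3), dtype=np.int32), VOXEL)
        with pytest.warns(UserWarning, match="no organelles"):
            assert extract_organelles(vol) == []


class TestMeshing:
    def test_voxelized_sphere_surface_area_within_2pct(self, sphere_phantom):
        vol, truth = sphere_phantom
        mesh = mesh_from_mask(vol.labels > 0, vol.voxel_size)
        assert mesh_surface_area(mesh) == pytest.approx(truth["surface_area_nm2"], rel=0.02)
        assert mesh_volume(mesh) == pytest.approx(truth["volume_nm3"], rel=0.02)

    def test_single_voxel_meshes_closed_near_voxel_volume(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        mesh = mesh_from_mask(mask, VOXEL)
        assert mesh.is_watertight
        # isosurface of one voxel is smoothed; 15% tolerance documented
        assert mesh_volume(mesh) == pytest.approx(3000.0, rel=0.15)

    def test_refining_voxels_converges_monotonically_to_analytic(self):
        spec = ShapeSpec("sphere", {"radius": 500.0})
        errors = []
        for f in (2.0, 1.0, 0.5):
            vs = (10 * f, 10 * f, 30 * f)
            vol, truth = voxelize(spec, voxel_size=vs)
            mesh = mesh_from_mask(vol.labels > 0, vs)
            errors.append(abs(mesh_surface_area(mesh) / truth["surface_area_nm2"] - 1))
        assert errors[0] > errors[1] > errors[2]
        # 2x-refined mask agrees with original within 1%
        assert errors[1] + errors[2] < 0.01

    def test_inward_oriented_mesh_volume_reported_positive(self, sphere_phantom):
        vol, _ = sphere_phantom
        mesh = mesh_from_mask(vol.labels > 0, vol.voxel_size)
        flipped = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1])
        assert mesh_volume(flipped) > 0

    def test_open_mesh_error_names_boundary_edges(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        faces = np.array([[0, 1, 2]])
        with pytest.raises(ValueError, match="boundary edges"):
            mesh_surface_area(SurfaceMesh(verts, faces))

    def test_voxel_volume_is_count_times_pitch(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        assert voxel_volume(mask, VOXEL) == pytest.approx(8 * 3000.0)


class TestMeshedMciOracles:
    def test_meshed_sphere_mci_within_2pct_of_floor(self, sphere_phantom):
        vol, _ = sphere_phantom
        mesh = mesh_from_mask(vol.labels > 0, vol.voxel_size)
        value = mci(mesh_surface_area(mesh), mesh_volume(mesh))
        assert value == pytest.approx(SPHERE_MCI, rel=0.02)
        assert value >= SPHERE_MCI - 0.02  # isoperimetric floor

    def test_meshed_capsule_mci_within_2pct_of_analytic(self, resolved_capsule_phantom):
        vol, truth = resolved_capsule_phantom
        mesh = mesh_from_mask(vol.labels > 0, vol.voxel_size)
        assert mci(mesh_surface_area(mesh), mesh_volume(mesh)) == pytest.approx(
            _analytic_mci(truth), rel=0.02
        )

    def test_mci_drift_under_2x_scaling_below_2pct(self, resolved_capsule_phantom):
        vol, _ = resolved_capsule_phantom
        mesh = mesh_from_mask(vol.labels > 0, vol.voxel_size)
        small = mci(mesh_surface_area(mesh), mesh_volume(mesh))
        vol2, _ = voxelize(ShapeSpec("capsule", {"radius": 400.0, "length": 4000.0, "axis": "x"}))
        mesh2 = mesh_from_mask(vol2.labels > 0, vol2.voxel_size)
        large = mci(mesh_surface_area(mesh2), mesh_volume(mesh2))
        assert abs(large / small - 1) < 0.02


class TestPipeline:
    def test_three_spheres_give_three_rows_near_floor(self):
        vol1, _ = voxelize(ShapeSpec("sphere", {"radius": 150.0}))
        blob = vol1.labels > 0
        dz, dy, dx = blob.shape
        labels = np.zeros((dz + 8, dy + 8, 3 * dx + 16), dtype=np.int32)
        for i in range(3):
            off = 4 + i * (dx + 4)
            labels[4 : 4 + dz, 4 : 4 + dy, off : off + dx][blob] = i + 1
        table, _ = compute_morphometrics(LabeledVolume(labels, VOXEL))
        assert len(table) == 3
        assert np.allclose(table["mci"], SPHERE_MCI, rtol=0.02)

    def test_capsule_scores_higher_mci_than_sphere(self, sphere_phantom, capsule_phantom):
        rows = []
        for vol, _ in (sphere_phantom, capsule_phantom):
            table, _ = compute_morphometrics(LabeledVolume(vol.labels, vol.voxel_size))
            rows.append(table.iloc[0]["mci"])
        assert rows[1] > rows[0]

    def test_border_touching_organelle_excluded_from_table(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels[5:9, 5:9, 5:9] = 1
        labels[0:4, 12:16, 12:16] = 2  # touches z face
        vol = LabeledVolume(labels, VOXEL)
        with_border, _ = compute_morphometrics(vol, config={"exclude_border": False})
        without, _ = compute_morphometrics(vol, config={"exclude_border": True})
        assert len(with_border) == 2 and len(without) == 1
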