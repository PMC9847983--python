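"""Colony morphometrics against closed forms and independent oracles."""

import math

import numpy as np
import pytest
import trimesh
from shapely.geometry import Polygon
from shapely.ops import unary_union

from meshutil import (
    box,
    colony_from_trimesh,
    cylinder,
    icosphere,
    stacked_cubes,
    tandem_cubes,
    unit_cube,
    view_from_upstream,
)
from reefflow.mesh_io import ColonyMesh, MeshValidationError
from reefflow.morphometrics import (
    ColonyGeometry,
    colony_height,
    frontal_area,
    measure_colony,
    orientation_sensitivity,
    plan_area,
    porosity,
    solid_volume,
)


def shapely_silhouette_area(mesh: ColonyMesh) -> float:
    """Independent occlusion-removed plan-silhouette oracle: exact polygon union."""
    polys = []
    for tri in mesh.vertices[mesh.faces][:, :, :2]:
        p = Polygon(tri)
        if p.area > 0:
            polys.append(p)
    return unary_union(polys).area


class TestHeight:
    def test_unit_cube(self):
        assert colony_height(unit_cube()) == pytest.approx(1.0)

    def test_scaling_doubles_height(self):
        mesh = unit_cube()
        doubled = ColonyMesh(mesh.vertices * 2.0, mesh.faces, 1.0, mesh.watertight)
        assert colony_height(doubled) == pytest.approx(2.0 * colony_height(mesh))


class TestFrontalArea:
    def test_cube_single_upstream_face(self):
        assert frontal_area(unit_cube()) == pytest.approx(1.0, abs=1e-12)

    def test_tandem_cubes_sum_without_occlusion(self):
        # each element in the flow path contributes: no shading correction
        assert frontal_area(tandem_cubes()) == pytest.approx(2.0, abs=1e-12)

    def test_tandem_face_sum_exceeds_silhouette(self):
        tandem = tandem_cubes()
        silhouette = plan_area(view_from_upstream(tandem), resolution=0.01)
        assert silhouette == pytest.approx(1.0, rel=0.01)
        assert frontal_area(tandem) > 1.5 * silhouette

    def test_sphere_matches_disc(self):
        assert frontal_area(icosphere()) == pytest.approx(math.pi, rel=0.01)

    def test_convex_face_sum_equals_silhouette(self):
        # convex body: no self-occlusion, so the face sum equals the
        # rasterised occlusion-removed silhouette
        ico = icosphere()
        silhouette = plan_area(view_from_upstream(ico), resolution=0.02)
        assert frontal_area(ico) == pytest.approx(silhouette, rel=0.01)

    def test_translation_invariant(self):
        mesh = tandem_cubes()
        shifted = ColonyMesh(
            mesh.vertices + np.array([3.0, -2.0, 0.0]), mesh.faces, 1.0, mesh.watertight
        )
        assert frontal_area(shifted) == pytest.approx(frontal_area(mesh), rel=1e-12)


class TestPlanArea:
    def test_unit_cube(self):
        assert plan_area(unit_cube(), resolution=0.01) == pytest.approx(1.0, abs=0.05)

    def test_stacked_cubes_counted_once(self):
        assert plan_area(stacked_cubes(), resolution=0.01) == pytest.approx(1.0, abs=0.05)

    def test_cylinder_matches_disc(self):
        assert plan_area(cylinder(), resolution=0.01) == pytest.approx(math.pi / 4, rel=0.01)

    @pytest.mark.parametrize("mesh_factory", [cylinder, stacked_cubes, icosphere])
    def test_matches_exact_union_oracle(self, mesh_factory):
        mesh = mesh_factory()
        assert plan_area(mesh) == pytest.approx(shapely_silhouette_area(mesh), rel=0.005)

    def test_resolution_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            plan_area(unit_cube(), resolution=0.2)

    def test_halving_resolution_converged(self):
        mesh = cylinder()
        coarse = plan_area(mesh, resolution=0.01)
        fine = plan_area(mesh, resolution=0.005)
        assert abs(fine - coarse) / coarse < 0.005


class TestSolidVolume:
    def test_unit_cube_exact(self):
        assert solid_volume(unit_cube()) == pytest.approx(1.0, abs=1e-12)

    def test_sphere(self):
        assert solid_volume(icosphere()) == pytest.approx(4 * math.pi / 3, rel=0.01)

    def test_disjoint_cubes_additive(self):
        assert solid_volume(tandem_cubes()) == pytest.approx(2.0, abs=1e-12)

    def test_voxel_route_agrees_with_divergence(self):
        mesh = icosphere()
        v_div = solid_volume(mesh, method="divergence")
        v_vox = solid_volume(mesh, resolution=0.02, method="voxel")
        assert v_vox == pytest.approx(v_div, rel=0.005)

    def test_voxel_halving_converged(self):
        mesh = icosphere()
        coarse = solid_volume(mesh, resolution=0.02, method="voxel")
        fine = solid_volume(mesh, resolution=0.01, method="voxel")
        assert abs(fine - coarse) / coarse < 0.005

    def test_open_base_mesh_closed_against_bed(self):
        # cube with the bottom face removed: columns are closed at z = 0
        tm = trimesh.creation.box(extents=(1, 1, 1))
        tm.apply_translation((0.5, 0.5, 0.5))
        tm.merge_vertices()
        tm.update_faces(tm.face_normals[:, 2] > -0.5)
        mesh = colony_from_trimesh(tm)
        assert not mesh.watertight
        assert solid_volume(mesh, resolution=0.01) == pytest.approx(1.0, rel=0.01)


class TestPorosity:
    def test_box_filling_solid_is_dense(self):
        assert porosity(unit_cube()) == pytest.approx(0.0, abs=1e-9)

    def test_cylinder_in_square_box(self):
        assert porosity(cylinder()) == pytest.approx(1 - math.pi / 4, rel=0.01)

    def test_half_height_slab_with_corner_spike(self):
        # slab fills the lower half; a thin spike sets the box height
        slab = box(extents=(1.0, 1.0, 0.5))
        spike = box(extents=(0.01, 0.01, 1.0), translate=(0.99, 0.99, 0.0))
        mesh = colony_from_trimesh(trimesh.util.concatenate([slab, spike]))
        assert porosity(mesh) == pytest.approx(0.5, abs=0.01)

    def test_plan_hull_footprint_smaller_than_bbox(self):
        mesh = cylinder()
        phi_bbox = porosity(mesh, phi_box="bbox")
        phi_hull = porosity(mesh, phi_box="plan-hull")
        assert phi_hull < phi_bbox
        assert phi_hull == pytest.approx(0.0, abs=0.01)


class TestMeasureColony:
    def test_unit_cube_summary(self):
        geom = measure_colony(unit_cube(), thetas=[0.0], resolution=0.01)
        assert geom.h == pytest.approx(1.0)
        assert geom.Ap == pytest.approx(1.0, abs=0.05)
        assert geom.Af(0.0) == pytest.approx(1.0, abs=1e-12)
        assert geom.phi == pytest.approx(0.0, abs=1e-9)
        assert geom.volume_method == "divergence"

    def test_cuboid_frontal_area_by_azimuth(self):
        mesh = colony_from_trimesh(box(extents=(2, 1, 1)))
        geom = measure_colony(mesh, thetas=[0.0, 90.0])
        assert geom.Af(0.0) == pytest.approx(1.0, abs=1e-9)
        assert geom.Af(90.0) == pytest.approx(2.0, abs=1e-9)

    def test_empty_theta_list_rejected(self):
        with pytest.raises(ValueError):
            measure_colony(unit_cube(), thetas=[])

    @pytest.mark.parametrize("s", [0.5, 2.0])
    def test_scaling_laws(self, s):
        mesh = colony_from_trimesh(box(extents=(2, 1, 1)))
        scaled = ColonyMesh(mesh.vertices * s, mesh.faces, 1.0, mesh.watertight)
        g1 = measure_colony(mesh, [0.0])
        g2 = measure_colony(scaled, [0.0])
        assert g2.h == pytest.approx(s * g1.h, rel=1e-9)
        assert g2.Af(0.0) == pytest.approx(s**2 * g1.Af(0.0), rel=1e-9)
        assert g2.Ap == pytest.approx(s**2 * g1.Ap, rel=0.005)
        assert g2.V_solid == pytest.approx(s**3 * g1.V_solid, rel=1e-9)
        assert g2.phi == pytest.approx(g1.phi, abs=1e-6)

    def test_cylinder_plan_quantities_rotation_invariant(self):
        mesh = cylinder()
        from reefflow.mesh_io import rotate_to_azimuth

        rotated = rotate_to_azimuth(mesh, 37.0)
        assert plan_area(rotated) == pytest.approx(plan_area(mesh), rel=0.005)
        assert porosity(rotated) == pytest.approx(porosity(mesh), abs=0.005)


class TestOrientationSensitivity:
    @staticmethod
    def _geometry(af_by_theta):
        return ColonyGeometry(
            h=0.051,
            Ap=50.7e-4,
            Af_by_theta=af_by_theta,
            V_solid=1e-4,
            phi=0.6,
            footprint_area=60e-4,
            raster_resolution=1e-3,
        )

    def test_zero_for_same_azimuth(self):
        geom = self._geometry({0.0: 29.9e-4})
        assert orientation_sensitivity(geom, 0.0, 0.0) == 0.0

    def test_cuboid_quarter_turn_doubles(self):
        mesh = colony_from_trimesh(box(extents=(2, 1, 1)))
        geom = measure_colony(mesh, [0.0, 90.0])
        assert orientation_sensitivity(geom, 0.0, 90.0) == pytest.approx(100.0, abs=1e-6)

    def test_missing_azimuth_raises(self):
        geom = self._geometry({0.0: 29.9e-4})
        with pytest.raises(LookupError):
            orientation_sensitivity(geom, 0.0, 90.0)


def test_degenerate_mesh_porosity_rejected():
    # flat sheet: zero height box
    tm = trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        faces=[[0, 1, 2], [0, 2, 3]],
        process=False,
    )
    mesh = colony_from_trimesh(tm)
    with pytest.raises(MeshValidationError):
        porosity(mesh)
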