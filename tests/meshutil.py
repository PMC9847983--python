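"""Shared mesh-building helpers for the test suite."""

from __future__ import annotations

import numpy as np
import trimesh

from reefflow.mesh_io import ColonyMesh, _is_watertight


def colony_from_trimesh(tm: trimesh.Trimesh) -> ColonyMesh:
    """Wrap a trimesh solid as a ColonyMesh resting on the bed plane."""
    tm = tm.copy()
    tm.merge_vertices()
    v = np.asarray(tm.vertices, dtype=float)
    v[:, 2] -= v[:, 2].min()
    return ColonyMesh(
        vertices=v,
        faces=np.asarray(tm.faces, dtype=np.int64),
        units_scale=1.0,
        watertight=_is_watertight(tm),
    )


def box(extents=(1.0, 1.0, 1.0), translate=(0.0, 0.0, 0.0)) -> trimesh.Trimesh:
    tm = trimesh.creation.box(extents=extents)
    tm.apply_translation(np.asarray(extents) / 2.0 + np.asarray(translate, float))
    return tm


def unit_cube() -> ColonyMesh:
    return colony_from_trimesh(box())


def icosphere(radius=1.0, subdivisions=4) -> ColonyMesh:
    return colony_from_trimesh(trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius))


def cylinder(radius=0.5, height=1.0, sections=128) -> ColonyMesh:
    return colony_from_trimesh(trimesh.creation.cylinder(radius=radius, height=height, sections=sections))


def tandem_cubes() -> ColonyMesh:
    """Two unit cubes at x in [0, 1] and x in [3, 4]: the tandem fixture."""
    return colony_from_trimesh(
        trimesh.util.concatenate([box(), box(translate=(3.0, 0.0, 0.0))])
    )


def stacked_cubes() -> ColonyMesh:
    """Two unit cubes stacked vertically (plan projections coincide)."""
    return colony_from_trimesh(
        trimesh.util.concatenate([box(), box(translate=(0.0, 0.0, 1.0))])
    )


def view_from_upstream(mesh: ColonyMesh) -> ColonyMesh:
    """Permute axes (x, y, z) -> (y, z, x) so the plan view of the result is
    the silhouette of the original mesh seen from upstream (-x)."""
    v = mesh.vertices[:, [1, 2, 0]].copy()
    v[:, 2] -= v[:, 2].min()
    return ColonyMesh(v, mesh.faces, mesh.units_scale, mesh.watertight)
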