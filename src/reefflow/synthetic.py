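"""Parametric colony meshes with closed-form geometric oracles.

Each generator emulates one archetypal colony form with a watertight mesh of
simple solids whose height, plan area, frontal area, volume and porosity are
known in closed form:

* ``branching`` — an n x n grid of vertical polygonal prisms (branches);
* ``massive``  — a hemiellipsoid mound (narrow axis into the flow at 0 deg);
* ``table``    — a polygonal plate on a cylindrical stem.

Prism cross-sections are regular polygons and the oracles use the *exact*
polygon areas and widths, so mesh-vs-oracle comparisons are limited only by
the rasteriser (and, for the curved massive form, by surface discretisation).
A second generator produces synthetic (alpha, beta) attenuation datasets for
fit-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mesh_io import ColonyMesh, _is_watertight

__all__ = [
    "SyntheticColonySpec",
    "OracleGeometry",
    "generate_colony",
    "generate_attenuation_dataset",
]

_DEFAULT_DIMENSIONS = {
    # metres; scaled to match the centimetre-scale colonies used in
    # laboratory and numerical canopy-flow studies
    "table": {"plate_radius": 0.05, "plate_thickness": 0.008,
              "stem_radius": 0.012, "stem_height": 0.026},
    "massive": {"semi_axis_x": 0.04, "semi_axis_y": 0.03, "height": 0.051},
    "branching": {"branch_count": 9, "branch_diameter": 0.01,
                  "branch_height": 0.056, "grid_spacing": 0.03},
}


@dataclass(frozen=True)
class SyntheticColonySpec:
    """Recipe for one synthetic colony.

    ``mesh_resolution`` is the number of segments per curve (polygon edge
    count for prisms; the hemiellipsoid uses 2x segments around the azimuth
    and 1/2x rings of latitude).  ``jitter`` displaces branch positions by a
    seeded uniform fraction of the grid spacing (branching form only; off by
    default so fixtures are deterministic).
    """

    archetype: str
    dimensions: dict = field(default_factory=dict)
    mesh_resolution: int = 32
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.archetype not in _DEFAULT_DIMENSIONS:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; "
                f"expected one of {sorted(_DEFAULT_DIMENSIONS)}"
            )
        dims = dict(_DEFAULT_DIMENSIONS[self.archetype])
        unknown = set(self.dimensions) - set(dims)
        if unknown:
            raise ValueError(f"unknown dimensions for {self.archetype}: {sorted(unknown)}")
        dims.update(self.dimensions)
        for name, value in dims.items():
            if value <= 0:
                raise ValueError(f"dimension {name} must be positive")
        if self.mesh_resolution < 8 or self.mesh_resolution % 4:
            raise ValueError("mesh_resolution must be a multiple of 4, >= 8")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        object.__setattr__(self, "dimensions", dims)


@dataclass(frozen=True)
class OracleGeometry:
    """Closed-form counterpart of a measured ColonyGeometry (bbox porosity box)."""

    h: float
    Ap: float
    Af0: float
    V: float
    phi: float
    footprint_area: float

    def as_dict(self) -> dict:
        return {
            "h_m": self.h,
            "Ap_m2": self.Ap,
            "Af0_m2": self.Af0,
            "V_m3": self.V,
            "phi": self.phi,
            "footprint_area_m2": self.footprint_area,
        }


# ---------------------------------------------------------------------------
# mesh building blocks


def _regular_polygon(radius: float, n: int, center=(0.0, 0.0)) -> np.ndarray:
    """CCW regular n-gon with a vertex on the +x axis (n % 4 == 0 makes the
    bounding box exactly 2r x 2r)."""
    ang = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(x @ np.roll(y, -1) - y @ np.roll(x, -1)))


def _prism(poly: np.ndarray, z0: float, z1: float, voffset: int):
    """Closed prism over a CCW polygon; returns (vertices, faces) with
    outward winding; face indices start at voffset."""
    n = len(poly)
    bottom = np.column_stack([poly, np.full(n, z0)])
    top = np.column_stack([poly, np.full(n, z1)])
    verts = np.vstack([bottom, top])
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append([i, j, n + j])
        faces.append([i, n + j, n + i])
    for i in range(1, n - 1):  # top cap, CCW from above
        faces.append([n, n + i, n + i + 1])
    for i in range(1, n - 1):  # bottom cap, CW from above
        faces.append([0, i + 1, i])
    return verts, np.asarray(faces, dtype=np.int64) + voffset


def _hemiellipsoid(a: float, b: float, c: float, n_az: int, n_rings: int):
    """Closed hemiellipsoid (flat base on z = 0) with outward winding."""
    verts = []
    for i in range(n_rings):  # latitude rings, equator first
        lat = 0.5 * math.pi * i / n_rings
        for j in range(n_az):
            az = 2.0 * math.pi * j / n_az
            verts.append(
                [a * math.cos(lat) * math.cos(az),
                 b * math.cos(lat) * math.sin(az),
                 c * math.sin(lat)]
            )
    apex = len(verts)
    verts.append([0.0, 0.0, c])
    base_center = len(verts)
    verts.append([0.0, 0.0, 0.0])
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_az):
            j1 = (j + 1) % n_az
            lo, lo1 = i * n_az + j, i * n_az + j1
            up, up1 = (i + 1) * n_az + j, (i + 1) * n_az + j1
            faces.append([lo, lo1, up1])
            faces.append([lo, up1, up])
    top_ring = (n_rings - 1) * n_az
    for j in range(n_az):
        j1 = (j + 1) % n_az
        faces.append([top_ring + j, top_ring + j1, apex])
    for j in range(n_az):  # base cap, normal -z
        j1 = (j + 1) % n_az
        faces.append([base_center, j1, j])
    return np.asarray(verts), np.asarray(faces, dtype=np.int64)


def _assemble(parts) -> ColonyMesh:
    verts = np.vstack([v for v, _ in parts])
    faces = np.vstack([f for _, f in parts])
    verts[:, 2] -= verts[:, 2].min()
    mesh = ColonyMesh(vertices=verts, faces=faces, units_scale=1.0, watertight=False)
    return ColonyMesh(
        vertices=mesh.vertices,
        faces=mesh.faces,
        units_scale=1.0,
        watertight=_is_watertight(mesh.to_trimesh()),
    )


# ---------------------------------------------------------------------------
# archetype generators


def _generate_branching(spec: SyntheticColonySpec):
    dims = spec.dimensions
    n = int(dims["branch_count"])
    grid = round(math.sqrt(n))
    if grid * grid != n:
        raise ValueError("branch_count must be a perfect square (square grid)")
    d, h_b, s = dims["branch_diameter"], dims["branch_height"], dims["grid_spacing"]
    r = d / 2.0
    rng = np.random.default_rng(spec.seed)
    centers = []
    for i in range(grid):
        for j in range(grid):
            cx, cy = i * s, j * s
            if spec.jitter > 0:
                cx += rng.uniform(-spec.jitter, spec.jitter) * s
                cy += rng.uniform(-spec.jitter, spec.jitter) * s
            centers.append((cx, cy))
    for p in range(len(centers)):
        for q in range(p + 1, len(centers)):
            if math.dist(centers[p], centers[q]) < d:
                raise ValueError("branches overlap in plan; reduce jitter or diameter")
    poly0 = _regular_polygon(r, spec.mesh_resolution)
    parts, voff = [], 0
    for cx, cy in centers:
        v, f = _prism(poly0 + [cx, cy], 0.0, h_b, voff)
        parts.append((v, f))
        voff += len(v)
    mesh = _assemble(parts)

    area1 = _polygon_area(poly0)
    width_x = float(np.ptp(poly0[:, 0]))
    width_y = float(np.ptp(poly0[:, 1]))
    xs = [c[0] for c in centers]
    ys = [c[1] for c in centers]
    footprint = (max(xs) - min(xs) + width_x) * (max(ys) - min(ys) + width_y)
    volume = n * area1 * h_b
    oracle = OracleGeometry(
        h=h_b,
        Ap=n * area1,
        Af0=n * width_y * h_b,
        V=volume,
        phi=1.0 - volume / (footprint * h_b),
        footprint_area=footprint,
    )
    return mesh, oracle


def _generate_massive(spec: SyntheticColonySpec):
    dims = spec.dimensions
    a, b, c = dims["semi_axis_x"], dims["semi_axis_y"], dims["height"]
    v, f = _hemiellipsoid(a, b, c, 2 * spec.mesh_resolution, spec.mesh_resolution // 2)
    mesh = _assemble([(v, f)])
    volume = 2.0 / 3.0 * math.pi * a * b * c
    footprint = 4.0 * a * b
    oracle = OracleGeometry(
        h=c,
        Ap=math.pi * a * b,
        Af0=0.5 * math.pi * b * c,  # half-ellipse silhouette, narrow side into flow
        V=volume,
        phi=1.0 - volume / (footprint * c),
        footprint_area=footprint,
    )
    return mesh, oracle


def _generate_table(spec: SyntheticColonySpec):
    dims = spec.dimensions
    R, t = dims["plate_radius"], dims["plate_thickness"]
    r_s, h_s = dims["stem_radius"], dims["stem_height"]
    if r_s >= R:
        raise ValueError("stem radius must be smaller than the plate radius")
    plate_poly = _regular_polygon(R, spec.mesh_resolution)
    stem_poly = _regular_polygon(r_s, spec.mesh_resolution)
    v1, f1 = _prism(stem_poly, 0.0, h_s, 0)
    v2, f2 = _prism(plate_poly, h_s, h_s + t, len(v1))
    mesh = _assemble([(v1, f1), (v2, f2)])

    area_plate = _polygon_area(plate_poly)
    area_stem = _polygon_area(stem_poly)
    h = h_s + t
    footprint = float(np.ptp(plate_poly[:, 0]) * np.ptp(plate_poly[:, 1]))
    volume = area_plate * t + area_stem * h_s
    oracle = OracleGeometry(
        h=h,
        Ap=area_plate,
        Af0=float(np.ptp(plate_poly[:, 1])) * t + float(np.ptp(stem_poly[:, 1])) * h_s,
        V=volume,
        phi=1.0 - volume / (footprint * h),
        footprint_area=footprint,
    )
    return mesh, oracle


_GENERATORS = {
    "branching": _generate_branching,
    "massive": _generate_massive,
    "table": _generate_table,
}


def generate_colony(spec: SyntheticColonySpec) -> tuple[ColonyMesh, OracleGeometry]:
    """Build the mesh for a synthetic colony together with its analytic oracle."""
    return _GENERATORS[spec.archetype](spec)


# ---------------------------------------------------------------------------
# synthetic attenuation data


def generate_attenuation_dataset(
    c_true: float,
    alphas,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic (alpha, beta) pairs beta = 1 + c sqrt(alpha) + Gaussian noise.

    Noise is drawn with a seeded generator; beta is clipped at its physical
    floor of 1.  Returns an (n, 2) array of (alpha, beta) rows.
    """
    alphas = np.asarray(list(alphas), dtype=float)
    if (alphas < 0).any():
        raise ValueError("alpha values must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    beta = 1.0 + c_true * np.sqrt(alphas)
    if noise_sd > 0:
        beta = beta + rng.normal(0.0, noise_sd, size=len(alphas))
    beta = np.maximum(beta, 1.0)
    return np.column_stack([alphas, beta])
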