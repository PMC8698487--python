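"""Shared fixtures: small analytic meshes and randomized organic shapes."""

import numpy as np
import pytest
import trimesh

from mvcpair import CohortConfig, TriangleMesh
from mvcpair.geometry import RigidTransform, vertex_normals
from mvcpair.synthetic_data import draw_individual_params, generate_clavicle


def random_rigid(seed: int, max_translation: float = 50.0) -> RigidTransform:
    """Uniform random rotation (quaternion method) plus bounded translation."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return RigidTransform(R, rng.uniform(-max_translation, max_translation, size=3))


def make_blob(seed: int, radius: float = 60.0, subdivisions: int = 3) -> TriangleMesh:
    """Asymmetric organic closed surface: icosphere with smooth random radial
    bumps and an anisotropic stretch (well-defined principal axes)."""
    rng = np.random.default_rng(seed)
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(s.vertices)
    r = np.ones(len(v))
    for _ in range(4):
        centre = rng.normal(size=3)
        centre /= np.linalg.norm(centre)
        amp = rng.uniform(0.15, 0.35) * rng.choice([-1.0, 1.0])
        width = rng.uniform(0.4, 0.9)
        ang = np.arccos(np.clip(v @ centre, -1.0, 1.0))
        r += amp * np.exp(-((ang / width) ** 2))
    scale = np.array(
        [1.0 + rng.uniform(0.3, 0.6), 1.0, 1.0 - rng.uniform(0.2, 0.4)]
    )
    return TriangleMesh(
        v * r[:, None] * radius * scale, np.asarray(s.faces), f"blob{seed}"
    )


def add_outlier_bulge(
    mesh: TriangleMesh, seed: int, fraction: float = 0.10, height: float = 20.0
) -> TriangleMesh:
    """Displace a contiguous patch of `fraction` of the vertices outward by
    up to `height` mm (sharp cos^4 falloff), simulating a shape defect."""
    rng = np.random.default_rng(seed)
    n = mesh.n_vertices
    centre = int(rng.integers(0, n))
    d = np.linalg.norm(mesh.vertices - mesh.vertices[centre], axis=1)
    sel = np.argsort(d)[: int(fraction * n)]
    fall = np.zeros(n)
    fall[sel] = np.cos(0.5 * np.pi * d[sel] / max(d[sel].max(), 1e-9)) ** 4
    out = mesh.copy()
    out.vertices = mesh.vertices + vertex_normals(mesh) * (height * fall)[:, None]
    return out


def make_clavicle(seed: int, resolution=(40, 16), noise_sd: float = 0.1) -> TriangleMesh:
    rng = np.random.default_rng(seed)
    params = draw_individual_params(CohortConfig(seed=seed), rng)
    return generate_clavicle(
        params, seed=seed + 1, resolution=resolution, vertex_noise_sd=noise_sd,
        element_id=f"clav{seed}",
    )


def make_hull_mesh(seed: int, n_points: int = 12) -> TriangleMesh:
    """Random convex hull; always a valid watertight triangle mesh."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(scale=10.0, size=(n_points, 3))
    hull = trimesh.convex.convex_hull(pts)
    return TriangleMesh(
        np.asarray(hull.vertices), np.asarray(hull.faces), f"hull{seed}"
    )


def make_tapered_prism(
    n_axis: int = 12, length: float = 100.0, w0: float = 4.0, w1: float = 10.0
) -> TriangleMesh:
    """Closed square-section prism along x whose width grows linearly, so the
    wide (x = length) end is unambiguous for end-disambiguation checks."""
    xs = np.linspace(0.0, length, n_axis)
    widths = w0 + (w1 - w0) * xs / length
    ring = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=float)
    verts = []
    for x, w in zip(xs, widths):
        for ry, rz in ring:
            verts.append([x, w * ry, w * rz])
    faces = []

    def V(i, j):
        return i * 4 + (j % 4)

    for i in range(n_axis - 1):
        for j in range(4):
            faces.append([V(i, j), V(i + 1, j + 1), V(i + 1, j)])
            faces.append([V(i, j), V(i, j + 1), V(i + 1, j + 1)])
    c0 = len(verts)
    verts.append([0.0, 0.0, 0.0])
    c1 = len(verts)
    verts.append([length, 0.0, 0.0])
    for j in range(4):
        faces.append([c0, V(0, j + 1), V(0, j)])
        faces.append([c1, V(n_axis - 1, j), V(n_axis - 1, j + 1)])
    return TriangleMesh(np.asarray(verts), np.asarray(faces), "prism")


@pytest.fixture
def unit_cube() -> TriangleMesh:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces), "cube")


@pytest.fixture
def tetra() -> TriangleMesh:
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f, "tetra")
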