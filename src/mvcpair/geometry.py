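"""Rigid transforms, mirroring, coarse alignment, surface sampling, hollowing.

All file I/O lives in :mod:`mvcpair.mesh_io`; this module is pure geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import AlignmentError, MeshInvariantError
from .mesh_io import Side, TriangleMesh, mesh_components

__all__ = [
    "RigidTransform",
    "PointSample",
    "mirror",
    "apply_transform",
    "coarse_align",
    "sample_points",
    "hollow",
]

ORTHONORMAL_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t mapping one frame onto another."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def is_valid(self, tol: float = 1e-8) -> bool:
        R = self.rotation
        return bool(
            np.allclose(R.T @ R, np.eye(3), atol=tol)
            and abs(np.linalg.det(R) - 1.0) < max(tol, ORTHONORMAL_TOL * 10)
            and np.isfinite(self.translation).all()
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class PointSample:
    """Points sampled on a mesh surface, uniform by triangle area."""

    points: np.ndarray
    source_element_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)


def mirror(mesh: TriangleMesh) -> TriangleMesh:
    """Reflect across the plane x = centroid_x, reversing winding so outward
    normals are preserved.  A right element becomes a mirrored-right."""
    c = mesh.centroid()
    v = mesh.vertices.copy()
    v[:, 0] = 2.0 * c[0] - v[:, 0]
    f = mesh.faces[:, ::-1].copy()
    side = Side.MIRRORED_RIGHT if mesh.side == Side.RIGHT else mesh.side
    return TriangleMesh(v, f, mesh.element_id, side, set(mesh.tags))


def apply_transform(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    if not transform.is_valid():
        raise MeshInvariantError("transform rotation is not a proper orthonormal matrix")
    return TriangleMesh(
        transform.apply(mesh.vertices),
        mesh.faces.copy(),
        mesh.element_id,
        mesh.side,
        set(mesh.tags),
    )


def principal_axes(vertices: np.ndarray):
    """Centroid and right-handed principal axes (columns, descending variance)."""
    c = vertices.mean(axis=0)
    cov = np.cov((vertices - c).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    return c, evecs, evals


_PROPER_SIGN_FLIPS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=np.float64
)


def coarse_align(
    moving: TriangleMesh,
    fixed: TriangleMesh,
    n_subsample: int = 500,
    seed: int = 0,
) -> RigidTransform:
    """Automated first-pass alignment: centroid translation plus principal-axis
    rotation, with the 4-fold axis-sign ambiguity resolved by the candidate
    with lowest RMS nearest-neighbour distance on a small surface subsample.

    Replaces the manual alignment a human operator would perform before fine
    registration; the fine (trimmed-ICP) stage carries the accuracy.
    """
    cm, Em, lm = principal_axes(moving.vertices)
    cf, Ef, lf = principal_axes(fixed.vertices)
    scale = float(np.sqrt(max(lm[0], lf[0])))
    if lm[2] < 1e-12 * max(lm[0], 1.0) or lf[2] < 1e-12 * max(lf[0], 1.0):
        raise AlignmentError("degenerate (rank < 3) vertex covariance")

    sample = sample_points(moving, n_subsample, seed=seed).points
    tree = cKDTree(fixed.vertices)
    best = None
    best_cost = np.inf
    n_keep = max(int(0.8 * len(sample)), 3)  # trimmed cost: robust to bulges
    for s in _PROPER_SIGN_FLIPS:
        R = Ef @ np.diag(s) @ Em.T
        t = cf - R @ cm
        d, _ = tree.query(sample @ R.T + t)
        d = np.sort(d)[:n_keep]
        cost = float(np.sqrt(np.mean(d**2)))
        if cost < best_cost:
            best_cost = cost
            best = RigidTransform(R, t)
    assert best is not None
    return best


def coarse_align_partial(
    moving: TriangleMesh,
    fixed: TriangleMesh,
    n_subsample: int = 500,
    seed: int = 0,
    n_offsets: int = 7,
    n_candidates: int = 1,
):
    """Coarse alignment for partial-overlap cases (fragment vs whole bone).

    Centroid-to-centroid PCA alignment systematically misplaces an end
    fragment, so candidate poses combine the 4 proper axis-sign flips with
    evenly spaced offsets along the fixed mesh's first principal axis
    spanning the length difference; candidates are ranked by trimmed RMS
    nearest-neighbour cost.  Returns the best transform, or the n_candidates
    best (ascending cost) when n_candidates > 1 so a fine stage can
    disambiguate nearby local minima.
    """
    cm, Em, lm = principal_axes(moving.vertices)
    cf, Ef, lf = principal_axes(fixed.vertices)
    if lm[2] < 1e-12 * max(lm[0], 1.0) or lf[2] < 1e-12 * max(lf[0], 1.0):
        raise AlignmentError("degenerate (rank < 3) vertex covariance")
    axis_f = Ef[:, 0]
    span_m = np.ptp(moving.vertices @ Em[:, 0])
    span_f = np.ptp(fixed.vertices @ axis_f)
    slack = max(span_f - span_m, 0.0)
    offsets = np.linspace(-0.5, 0.5, n_offsets) * slack if slack > 0 else [0.0]

    sample = sample_points(moving, n_subsample, seed=seed).points
    tree = cKDTree(fixed.vertices)
    scored = []
    n_keep = max(int(0.8 * len(sample)), 3)
    for s in _PROPER_SIGN_FLIPS:
        R = Ef @ np.diag(s) @ Em.T
        base_t = cf - R @ cm
        moved = sample @ R.T + base_t
        for off in offsets:
            d, _ = tree.query(moved + off * axis_f)
            d = np.sort(d)[:n_keep]
            cost = float(np.sqrt(np.mean(d**2)))
            scored.append((cost, RigidTransform(R, base_t + off * axis_f)))
    scored.sort(key=lambda it: it[0])
    if n_candidates <= 1:
        return scored[0][1]
    return [t for _, t in scored[:n_candidates]]


def sample_points(mesh: TriangleMesh, n: int, seed: int = 0) -> PointSample:
    """Sample n points uniformly by surface area (triangle chosen with
    probability proportional to area, then uniform barycentric point)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0:
        raise MeshInvariantError("zero-area mesh cannot be sampled")
    rng = np.random.default_rng(seed)
    tri_idx = rng.choice(len(areas), size=n, p=areas / total)
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1.0
    u[flip] = 1.0 - u[flip]
    v[flip] = 1.0 - v[flip]
    t = mesh.triangles()[tri_idx]
    pts = t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + v[:, None] * (t[:, 2] - t[:, 0])
    return PointSample(pts, source_element_id=mesh.element_id, seed=seed)


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted outward vertex normals (unit length where defined)."""
    t = mesh.triangles()
    fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # length = 2 * area
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def hollow(mesh: TriangleMesh):
    """Keep only the connected component with the largest surface area.

    Surrogate for removal of internal (trabecular) surface data: CT-derived
    internal surfaces form disjoint shells inside the cortical envelope.
    Returns (mesh, removed_fraction); a single-component mesh passes through
    unchanged with fraction 0.
    """
    labels = mesh_components(mesh)
    n_comp = labels.max() + 1
    if n_comp == 1:
        return mesh, 0.0
    areas = mesh.face_areas()
    comp_area = np.bincount(labels, weights=areas, minlength=n_comp)
    keep_label = int(np.argmax(comp_area))
    keep = labels == keep_label
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriangleMesh(
        mesh.vertices[used],
        remap[faces],
        mesh.element_id,
        mesh.side,
        set(mesh.tags),
    )
    removed_fraction = 1.0 - len(faces) / mesh.n_faces
    return out, float(removed_fraction)
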