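"""Synthetic bilateral clavicle cohorts.

The generator replaces a CT-derived skeletal sample with parametric
clavicle-like meshes whose statistical structure matches what pair-matching
assumes: between-individual shape variation much larger than within-pair
(bilateral-asymmetry plus segmentation-noise) variation.

Each bone is a swept tube: an S-curved centreline in plan view with a gentle
superior bow, an elliptical cross-section that flares at the medial (sternal)
and lateral (acromial) ends and flattens laterally.  The lateral flare is
deliberately the most variable parameter across individuals, making the
acromial region the most individuating part of the bone, as is anatomically
the case.  Bilateral asymmetry is modelled as a small jitter of the
individual's parameters (not an independent redraw), so pairs remain more
similar than non-pairs; per-vertex Gaussian noise along normals stands in
for segmentation error.  A minority of elements can receive a healed-fracture
callus (a localised radial bulge).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigurationError
from .fragment_sim import long_axis_parameter
from .geometry import RigidTransform, apply_transform, principal_axes, vertex_normals
from .mesh_io import (
    CohortManifest,
    ManifestEntry,
    Side,
    TriangleMesh,
    write_manifest,
    write_mesh,
)

__all__ = [
    "CohortConfig",
    "IndividualParams",
    "draw_individual_params",
    "generate_clavicle",
    "generate_cohort",
    "add_fracture_callus",
]

#: e-folding length (in t units) of the end flares
FLARE_SCALE = 0.08
#: ellipse aspect ratio at the lateral end (1.0 at the medial end)
LATERAL_ASPECT = 0.6


@dataclass
class CohortConfig:
    """Population and acquisition parameters of a synthetic cohort.

    Length/amplitude/radius parameters are millimetres; flares are relative
    radius increments at the bone ends.  asymmetry_fraction scales the
    within-pair parameter jitter as a fraction of each between-individual sd.
    """

    n_individuals: int = 80
    length_mean: float = 140.0
    length_sd: float = 10.0
    s_curve_amp_mean: float = 10.0
    s_curve_amp_sd: float = 3.0
    superior_bow_amp_mean: float = 2.0
    superior_bow_amp_sd: float = 1.0
    shaft_radius_mean: float = 6.0
    shaft_radius_sd: float = 0.8
    medial_flare_mean: float = 0.4
    medial_flare_sd: float = 0.05
    lateral_flare_mean: float = 0.1
    lateral_flare_sd: float = 0.15  # deliberately the largest relative spread
    asymmetry_fraction: float = 0.1
    vertex_noise_sd: float = 0.15
    pathology_prevalence: float = 9.0 / 160.0
    internal_debris: bool = False
    mesh_resolution: Tuple[int, int] = (120, 48)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("need at least 2 individuals")
        for name in (
            "length_sd",
            "s_curve_amp_sd",
            "superior_bow_amp_sd",
            "shaft_radius_sd",
            "medial_flare_sd",
            "lateral_flare_sd",
            "vertex_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.asymmetry_fraction < 0:
            raise ConfigurationError("asymmetry_fraction must be >= 0")
        if not 0.0 <= self.pathology_prevalence <= 1.0:
            raise ConfigurationError("pathology_prevalence must be in [0, 1]")
        na, nc = self.mesh_resolution
        if na < 16 or nc < 8:
            raise ConfigurationError("mesh_resolution must be at least 16 x 8")


@dataclass
class IndividualParams:
    length: float
    s_curve_amp: float
    superior_bow_amp: float
    shaft_radius: float
    medial_flare: float
    lateral_flare: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.shaft_radius <= 0:
            raise ConfigurationError("length and shaft_radius must be positive")


_PARAM_FIELDS = (
    ("length", "length_mean", "length_sd"),
    ("s_curve_amp", "s_curve_amp_mean", "s_curve_amp_sd"),
    ("superior_bow_amp", "superior_bow_amp_mean", "superior_bow_amp_sd"),
    ("shaft_radius", "shaft_radius_mean", "shaft_radius_sd"),
    ("medial_flare", "medial_flare_mean", "medial_flare_sd"),
    ("lateral_flare", "lateral_flare_mean", "lateral_flare_sd"),
)


def draw_individual_params(config: CohortConfig, rng: np.random.Generator) -> IndividualParams:
    """One individual's parameter draw from the population distributions."""
    kwargs = {}
    for field_name, mean_name, sd_name in _PARAM_FIELDS:
        val = rng.normal(getattr(config, mean_name), getattr(config, sd_name))
        if field_name in ("length", "shaft_radius"):
            val = max(val, 0.2 * getattr(config, mean_name))  # keep physical
        kwargs[field_name] = float(val)
    return IndividualParams(**kwargs)


def jitter_params(
    params: IndividualParams, config: CohortConfig, rng: np.random.Generator
) -> IndividualParams:
    """Bilateral-asymmetry jitter: each parameter moves by a Gaussian with sd
    = asymmetry_fraction x that parameter's between-individual sd."""
    kwargs = {}
    for field_name, mean_name, sd_name in _PARAM_FIELDS:
        sd = config.asymmetry_fraction * getattr(config, sd_name)
        val = getattr(params, field_name) + rng.normal(0.0, sd)
        if field_name in ("length", "shaft_radius"):
            val = max(val, 0.2 * getattr(config, mean_name))
        kwargs[field_name] = float(val)
    return IndividualParams(**kwargs)


def _tube(
    params: IndividualParams, n_axis: int, n_circ: int, radius_scale: float = 1.0,
    length_margin: float = 0.0,
):
    """Swept-tube vertices and faces in the canonical (left) frame.

    Returns (vertices, faces, medial_cap_index).  Outward winding throughout.
    """
    L = params.length
    A1 = params.s_curve_amp
    A2 = params.superior_bow_amp
    t = np.linspace(length_margin, 1.0 - length_margin, n_axis)
    centre = np.stack(
        [L * t, A1 * np.sin(2.0 * np.pi * t), A2 * np.sin(np.pi * t)], axis=1
    )
    tangent = np.stack(
        [
            np.full_like(t, L),
            A1 * 2.0 * np.pi * np.cos(2.0 * np.pi * t),
            A2 * np.pi * np.cos(np.pi * t),
        ],
        axis=1,
    )
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    up = np.array([0.0, 0.0, 1.0])
    normal = np.cross(np.broadcast_to(up, tangent.shape), tangent)
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    binorm = np.cross(tangent, normal)

    r = params.shaft_radius * radius_scale * (
        1.0
        + params.medial_flare * np.exp(-t / FLARE_SCALE)
        + params.lateral_flare * np.exp(-(1.0 - t) / FLARE_SCALE)
    )
    aspect = 1.0 + (LATERAL_ASPECT - 1.0) * t
    theta = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    ring = (
        centre[:, None, :]
        + (r * 1.0)[:, None, None] * np.cos(theta)[None, :, None] * normal[:, None, :]
        + (r * aspect)[:, None, None] * np.sin(theta)[None, :, None] * binorm[:, None, :]
    )
    vertices = ring.reshape(-1, 3)

    def V(i, j):
        return i * n_circ + (j % n_circ)

    faces = []
    for i in range(n_axis - 1):
        for j in range(n_circ):
            faces.append([V(i, j), V(i + 1, j + 1), V(i + 1, j)])
            faces.append([V(i, j), V(i, j + 1), V(i + 1, j + 1)])
    medial_cap = len(vertices)
    lateral_cap = medial_cap + 1
    vertices = np.concatenate([vertices, centre[[0]], centre[[-1]]])
    for j in range(n_circ):
        faces.append([medial_cap, V(0, j + 1), V(0, j)])
        faces.append([lateral_cap, V(n_axis - 1, j), V(n_axis - 1, j + 1)])
    return vertices, np.asarray(faces, dtype=np.int64), medial_cap


def generate_clavicle(
    params: IndividualParams,
    side: Side = Side.LEFT,
    seed: int = 0,
    resolution: Tuple[int, int] = (120, 48),
    vertex_noise_sd: float = 0.15,
    internal_debris: bool = False,
    element_id: str = "",
) -> TriangleMesh:
    """Build one clavicle-like mesh.

    The left side is built directly; a right side is the same swept surface
    reflected through its centroid's YZ plane (with winding flipped).  Vertex
    noise is drawn along outward normals with the given seed.
    """
    n_axis, n_circ = resolution
    v, f, medial_cap = _tube(params, n_axis, n_circ)
    tags = {f"medial_vertex:{medial_cap}"}
    if internal_debris:
        # small disjoint interior shell; removed later by hollowing
        dv, df, _ = _tube(
            params,
            max(n_axis // 2, 8),
            max(n_circ // 2, 6),
            radius_scale=0.45,
            length_margin=0.05,
        )
        df = df[:, ::-1]  # inward-facing shell
        f = np.concatenate([f, df + len(v)])
        v = np.concatenate([v, dv])
    mesh = TriangleMesh(v, f, element_id=element_id, side=Side.LEFT, tags=tags)
    if vertex_noise_sd > 0:
        rng = np.random.default_rng(seed)
        vn = vertex_normals(mesh)
        mesh.vertices = mesh.vertices + vn * rng.normal(
            0.0, vertex_noise_sd, size=(len(v), 1)
        )
    if side != Side.LEFT:
        c = mesh.centroid()
        mv = mesh.vertices.copy()
        mv[:, 0] = 2.0 * c[0] - mv[:, 0]
        mesh = TriangleMesh(mv, mesh.faces[:, ::-1].copy(), element_id, Side.RIGHT, mesh.tags)
    return mesh


def add_fracture_callus(mesh: TriangleMesh, seed: int = 0, height: Optional[float] = None) -> TriangleMesh:
    """Add a healed-fracture callus: a localised radial bulge.

    Local radius is multiplied by 1 + h * exp(-(t - t0)^2 / (2 w^2)) with
    h ~ U(0.2, 0.5), t0 ~ U(0.25, 0.75) along the long axis and w = 0.05,
    realised by displacing vertices along their outward normals.
    """
    rng = np.random.default_rng(seed)
    h = float(rng.uniform(0.2, 0.5)) if height is None else float(height)
    t0 = float(rng.uniform(0.25, 0.75))
    w = 0.05
    t = long_axis_parameter(mesh)
    c, axes, _ = principal_axes(mesh.vertices)
    rel = mesh.vertices - c
    radial = np.sqrt(
        (rel @ axes[:, 1]) ** 2 + (rel @ axes[:, 2]) ** 2
    )
    bump = h * np.exp(-((t - t0) ** 2) / (2.0 * w**2))
    vn = vertex_normals(mesh)
    out = mesh.copy()
    out.vertices = mesh.vertices + vn * (radial * bump)[:, None]
    out.tags = set(mesh.tags) | {"pathology:healed_fracture"}
    return out


def _random_rigid(rng: np.random.Generator) -> RigidTransform:
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
    return RigidTransform(R, rng.uniform(-50.0, 50.0, size=3))


def generate_cohort(
    config: CohortConfig, out_dir=None
) -> Tuple[List[TriangleMesh], CohortManifest]:
    """Generate a full bilateral cohort: one left and one right element per
    individual, each exported in a random pose, with ground truth recorded in
    the manifest.  Fully reproducible from config.seed.

    If out_dir is given, meshes are written as OBJ files and a manifest.csv
    alongside; mesh order in the return value matches manifest rows.
    """
    rng = np.random.default_rng(config.seed)
    meshes: List[TriangleMesh] = []
    entries: List[ManifestEntry] = []
    for i in range(config.n_individuals):
        ind_id = f"IND{i:03d}"
        left_params = draw_individual_params(config, rng)
        right_params = jitter_params(left_params, config, rng)
        # draw all per-individual randomness unconditionally so cohorts that
        # differ only in pathology_prevalence stay paired element-for-element
        u_path = rng.random()
        u_side = rng.random()
        callus_seed = int(rng.integers(0, 2**31 - 1))
        pathological_side: Optional[Side] = None
        if u_path < config.pathology_prevalence:
            pathological_side = Side.LEFT if u_side < 0.5 else Side.RIGHT
        for side, params in ((Side.LEFT, left_params), (Side.RIGHT, right_params)):
            noise_seed = int(rng.integers(0, 2**31 - 1))
            eid = f"{ind_id}-{'L' if side == Side.LEFT else 'R'}"
            mesh = generate_clavicle(
                params,
                side=side,
                seed=noise_seed,
                resolution=config.mesh_resolution,
                vertex_noise_sd=config.vertex_noise_sd,
                internal_debris=config.internal_debris,
                element_id=eid,
            )
            if pathological_side == side:
                mesh = add_fracture_callus(mesh, seed=callus_seed)
            mesh = apply_transform(mesh, _random_rigid(rng))
            meshes.append(mesh)
            entries.append(
                ManifestEntry(
                    element_id=eid,
                    side=side,
                    path="",
                    individual_id=ind_id,
                    tags=set(mesh.tags),
                )
            )
    manifest = CohortManifest(entries)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for mesh, entry in zip(meshes, manifest):
            p = out_dir / f"{entry.element_id}.obj"
            write_mesh(mesh, p)
            entry.path = str(p)
        write_manifest(manifest, out_dir / "manifest.csv")
    return meshes, manifest


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["mesh_resolution"] = list(config.mesh_resolution)
    return d
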