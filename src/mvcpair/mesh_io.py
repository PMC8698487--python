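"""Triangle-mesh and cohort-manifest I/O.

Every downstream stage of the pair-matching pipeline consumes the types
defined here.  Meshes are plain triangle soups in millimetres: geometry only,
no normals or texture data are kept (surface normals are implied by
counter-clockwise face winding).

Wavefront OBJ is read and written natively because the pipeline interprets a
deliberately narrow dialect (``v`` and ``f`` records only, 1-based indices)
and format errors must name the offending line.  PLY and STL go through
:mod:`trimesh`.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import trimesh as _trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ManifestError, MeshFormatError, MeshInvariantError

__all__ = [
    "Side",
    "TriangleMesh",
    "ValidationReport",
    "ManifestEntry",
    "CohortManifest",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "read_manifest",
    "write_manifest",
]

#: De-duplication / round-trip coordinate tolerance, mm.
COORD_TOL = 1e-6


class Side(str, enum.Enum):
    """Anatomical side of an element; rights become mirrored_right after reflection."""

    LEFT = "left"
    RIGHT = "right"
    MIRRORED_RIGHT = "mirrored_right"


@dataclass
class TriangleMesh:
    """A closed or open triangle mesh of one element's outer surface (mm units).

    Invariants (checked on construction): at least 4 vertices and 4 faces,
    finite coordinates, all face indices in range, no face repeating a vertex.
    Counter-clockwise winding encodes the outward normal.
    """

    vertices: np.ndarray
    faces: np.ndarray
    element_id: str = ""
    side: Side = Side.LEFT
    tags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if isinstance(self.side, str) and not isinstance(self.side, Side):
            self.side = Side(self.side)
        self.tags = set(self.tags)
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshInvariantError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshInvariantError(f"faces must be (m, 3), got {f.shape}")
        if len(v) < 4 or len(f) < 4:
            raise MeshInvariantError(
                f"mesh too small: {len(v)} vertices, {len(f)} faces (need >= 4 of each)"
            )
        if not np.isfinite(v).all():
            raise MeshInvariantError("non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshInvariantError(
                f"face index out of range [0, {len(v)}): min {f.min()}, max {f.max()}"
            )
        degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if degenerate.any():
            raise MeshInvariantError(
                f"{int(degenerate.sum())} faces repeat a vertex index"
            )

    # -- convenience geometry -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def volume(self) -> float:
        """Signed enclosed volume by the divergence theorem (positive for
        outward CCW winding on a closed surface)."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.element_id,
            self.side,
            set(self.tags),
        )

    def replace(self, **kwargs) -> "TriangleMesh":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ValidationReport:
    """Quality flags for one mesh; reporting only, never rejection."""

    element_id: str
    n_vertices: int
    n_faces: int
    n_unreferenced_vertices: int
    n_degenerate_faces: int
    n_components: int
    watertight: bool
    bbox_extent_mm: np.ndarray


@dataclass
class ManifestEntry:
    element_id: str
    side: Side
    path: str
    individual_id: Optional[str]
    tags: set = field(default_factory=set)


@dataclass
class CohortManifest:
    """Table assigning each mesh file an element ID, side, and ground truth.

    Invariants: element_id unique; each individual_id appears on at most one
    left and one right row.
    """

    rows: list  # list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [r.element_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate element_id(s): {dup}")
        seen: dict = {}
        for r in self.rows:
            if r.individual_id is None:
                continue
            side = Side.LEFT if r.side == Side.LEFT else Side.RIGHT
            key = (r.individual_id, side)
            if key in seen:
                raise ManifestError(
                    f"individual {r.individual_id!r} has two {side.value} elements"
                )
            seen[key] = r.element_id

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def entry(self, element_id: str) -> ManifestEntry:
        for r in self.rows:
            if r.element_id == element_id:
                return r
        raise KeyError(element_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_id": [r.element_id for r in self.rows],
                "side": [r.side.value for r in self.rows],
                "path": [r.path for r in self.rows],
                "individual_id": [r.individual_id or "" for r in self.rows],
                "tags": [";".join(sorted(r.tags)) for r in self.rows],
            }
        )


# -- OBJ ----------------------------------------------------------------------


def _read_obj(path: Path) -> tuple:
    vertices: list = []
    faces: list = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: malformed vertex record")
                try:
                    vertices.append([float(x) for x in parts[1:4]])
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc
            elif parts[0] == "f":
                idx = []
                for tok in parts[1:]:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError as exc:
                        raise MeshFormatError(
                            f"{path}:{lineno}: bad face index {tok!r}"
                        ) from exc
                    if i == 0:
                        raise MeshFormatError(
                            f"{path}:{lineno}: OBJ face indices are 1-based, got 0"
                        )
                    idx.append(i)
                if len(idx) < 3:
                    raise MeshFormatError(f"{path}:{lineno}: face with < 3 vertices")
                # fan-triangulate polygons; negative indices count from the end
                n = len(vertices)

                def _resolve(i: int) -> int:
                    j = i - 1 if i > 0 else n + i
                    if j < 0 or j >= n:
                        raise MeshFormatError(
                            f"{path}:{lineno}: face index {i} out of range (have {n} vertices)"
                        )
                    return j

                ring = [_resolve(i) for i in idx]
                for k in range(1, len(ring) - 1):
                    faces.append([ring[0], ring[k], ring[k + 1]])
            # all other record types (vn, vt, o, g, s, mtllib, usemtl...) ignored
    return np.asarray(vertices, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mvcpair OBJ export: {mesh.element_id or 'unnamed'}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# -- public I/O ---------------------------------------------------------------

_EXT_FORMAT = {".obj": "obj", ".ply": "ply", ".stl": "stl"}


def read_mesh(
    path,
    expected_format: str = "auto",
    element_id: Optional[str] = None,
    side: Side = Side.LEFT,
    tags: Optional[Iterable[str]] = None,
) -> TriangleMesh:
    """Read a triangle mesh from OBJ, PLY, or STL.

    Vertex order and face winding are preserved as stored in the file.
    Polygonal faces are fan-triangulated.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    fmt = expected_format
    if fmt == "auto":
        fmt = _EXT_FORMAT.get(path.suffix.lower())
        if fmt is None:
            raise MeshFormatError(f"cannot infer format from suffix: {path}")
    if fmt == "obj":
        vertices, faces = _read_obj(path)
    elif fmt in ("ply", "stl"):
        try:
            tm = _trimesh.load(str(path), file_type=fmt, process=False, maintain_order=True)
        except Exception as exc:  # noqa: BLE001 - normalise loader failures
            raise MeshFormatError(f"{path}: {exc}") from exc
        if not isinstance(tm, _trimesh.Trimesh):
            raise MeshFormatError(f"{path}: not a single triangle mesh")
        vertices = np.asarray(tm.vertices, dtype=np.float64)
        faces = np.asarray(tm.faces, dtype=np.int64)
    else:
        raise MeshFormatError(f"unsupported format {fmt!r}")
    return TriangleMesh(
        vertices,
        faces,
        element_id=element_id if element_id is not None else path.stem,
        side=side,
        tags=set(tags) if tags else set(),
    )


def write_mesh(mesh: TriangleMesh, path, fmt: Optional[str] = None):
    """Write a mesh to OBJ/PLY/STL; the file must round-trip through read_mesh."""
    path = Path(path)
    if fmt is None:
        fmt = _EXT_FORMAT.get(path.suffix.lower())
        if fmt is None:
            raise MeshFormatError(f"cannot infer format from suffix: {path}")
    # re-validate before touching the filesystem
    TriangleMesh(mesh.vertices, mesh.faces, mesh.element_id, mesh.side, mesh.tags)
    if not path.parent.exists():
        raise IOError(f"directory does not exist: {path.parent}")
    if fmt == "obj":
        _write_obj(mesh, path)
    elif fmt in ("ply", "stl"):
        tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        tm.export(str(path), file_type=fmt)
    else:
        raise MeshFormatError(f"unsupported format {fmt!r}")
    return path


# -- validation ---------------------------------------------------------------


def _sorted_edges(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.sort(e, axis=1)


def mesh_components(mesh: TriangleMesh) -> np.ndarray:
    """Connected-component label per face (faces sharing a vertex connect)."""
    f = mesh.faces
    n = mesh.n_vertices
    e = _sorted_edges(f)
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    _, vlabel = connected_components(adj, directed=False)
    return vlabel[f[:, 0]]


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Compute quality flags; the mesh is never modified.

    Watertight means every undirected edge is used by exactly two faces and
    each directed edge appears once (consistent winding).
    """
    f = mesh.faces
    referenced = np.zeros(mesh.n_vertices, dtype=bool)
    referenced[f.ravel()] = True
    t = mesh.triangles()
    areas = mesh.face_areas()
    degenerate = int((areas <= 0.0).sum())

    und = _sorted_edges(f)
    _, counts = np.unique(und, axis=0, return_counts=True)
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    _, dcounts = np.unique(directed, axis=0, return_counts=True)
    watertight = bool((counts == 2).all() and (dcounts == 1).all())

    labels = mesh_components(mesh)
    used = mesh.vertices[referenced]
    extent = used.max(axis=0) - used.min(axis=0)
    return ValidationReport(
        element_id=mesh.element_id,
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        n_unreferenced_vertices=int((~referenced).sum()),
        n_degenerate_faces=degenerate,
        n_components=int(labels.max()) + 1,
        watertight=watertight,
        bbox_extent_mm=extent,
    )


# -- manifest -----------------------------------------------------------------

MANIFEST_COLUMNS = ["element_id", "side", "path", "individual_id", "tags"]


def write_manifest(manifest: CohortManifest, path) -> Path:
    path = Path(path)
    manifest.to_frame().to_csv(path, index=False)
    return path


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing columns {missing}")
    rows = []
    for _, r in df.iterrows():
        try:
            side = Side(r["side"])
        except ValueError as exc:
            raise ManifestError(f"{path}: bad side {r['side']!r}") from exc
        tags = {t for t in str(r["tags"]).split(";") if t}
        rows.append(
            ManifestEntry(
                element_id=r["element_id"],
                side=side,
                path=r["path"],
                individual_id=r["individual_id"] or None,
                tags=tags,
            )
        )
    return CohortManifest(rows)
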