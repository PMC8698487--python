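"""Simulated fragmentation of whole-bone meshes.

Three fragment types mimic how a long bone breaks in commingled contexts:
sternal (medial end), midshaft (central portion, two cuts), and acromial
(lateral end).  A fragment keeps the faces whose vertices fall inside a
window of the normalised long-axis parameter; the cut loops are re-capped by
planar fan triangulation so fragments stay watertight, the mesh analogue of
hole-filling in a segmentation editor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import AlignmentError, FragmentError
from .geometry import principal_axes
from .mesh_io import TriangleMesh

__all__ = ["FragmentSpec", "long_axis_parameter", "make_fragment", "FRAGMENT_TYPES"]

FRAGMENT_TYPES = ("sternal", "midshaft", "acromial")

#: ratio of first to second principal eigenvalue below which the long axis is
#: considered undefined
MIN_ANISOTROPY = 1.5


@dataclass
class FragmentSpec:
    fragment_type: str
    retained_fraction_range: Tuple[float, float] = (0.25, 0.40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_type not in FRAGMENT_TYPES:
            raise ValueError(f"fragment_type must be one of {FRAGMENT_TYPES}")
        lo, hi = self.retained_fraction_range
        if not (0.1 < lo < hi < 0.9):
            raise ValueError("retained_fraction_range must satisfy 0.1 < low < high < 0.9")


def _medial_cap_index(mesh: TriangleMesh):
    for tag in mesh.tags:
        if tag.startswith("medial_vertex:"):
            return int(tag.split(":", 1)[1])
    return None


def long_axis_parameter(mesh: TriangleMesh) -> np.ndarray:
    """Normalised projection t in [0, 1] of each vertex onto the first
    principal axis, oriented so t=0 is the medial end.

    Orientation uses the generator's medial-vertex tag when present (robust
    to any rigid motion, since vertex order survives transforms and I/O);
    otherwise the end with the larger cross-section is taken as medial.
    """
    c, axes, evals = principal_axes(mesh.vertices)
    if evals[0] < MIN_ANISOTROPY * max(evals[1], 1e-300):
        raise AlignmentError(
            f"no dominant long axis (anisotropy {evals[0] / max(evals[1], 1e-300):.2f})"
        )
    proj = (mesh.vertices - c) @ axes[:, 0]
    t = (proj - proj.min()) / (proj.max() - proj.min())
    idx = _medial_cap_index(mesh)
    if idx is not None:
        flip = t[idx] > 0.5
    else:
        # cross-section size ~ mean squared distance to the axis near each end
        r2 = ((mesh.vertices - c) @ axes[:, 1]) ** 2 + ((mesh.vertices - c) @ axes[:, 2]) ** 2
        lo_sel, hi_sel = t < 0.15, t > 0.85
        if not lo_sel.any() or not hi_sel.any():
            flip = False
        else:
            flip = r2[hi_sel].mean() > r2[lo_sel].mean()
    return 1.0 - t if flip else t


def _boundary_loops(faces: np.ndarray):
    """Ordered directed boundary loops of an oriented triangle patch."""
    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = directed[counts[inv] == 1]
    nxt = {}
    for a, b in boundary:
        if int(a) in nxt:
            raise FragmentError("non-manifold cut boundary")
        nxt[int(a)] = int(b)
    loops = []
    remaining = dict(nxt)
    while remaining:
        start = next(iter(remaining))
        loop = [start]
        cur = remaining.pop(start)
        while cur != start:
            loop.append(cur)
            if cur not in remaining:
                raise FragmentError("open cut boundary (not a loop)")
            cur = remaining.pop(cur)
        loops.append(loop)
    return loops


def _cap_loops(vertices: np.ndarray, faces: np.ndarray):
    """Append a centroid vertex per boundary loop and fan-triangulate it.

    Boundary edges run counter-clockwise seen from outside the retained
    patch, so the fan (b, a, centre) keeps outward winding on the cap.
    """
    loops = _boundary_loops(faces)
    new_v = [vertices]
    new_f = [faces]
    next_idx = len(vertices)
    for loop in loops:
        centre = vertices[loop].mean(axis=0)
        new_v.append(centre[None, :])
        ring = np.asarray(loop)
        nxt_ring = np.roll(ring, -1)
        fan = np.stack(
            [nxt_ring, ring, np.full(len(ring), next_idx)], axis=1
        )
        new_f.append(fan)
        next_idx += 1
    return np.concatenate(new_v), np.concatenate(new_f)


def make_fragment(mesh: TriangleMesh, spec: FragmentSpec) -> TriangleMesh:
    """Crop a whole mesh to one fragment type and cap the cut loops.

    The retained fraction f is drawn uniformly from the spec's range:
    sternal keeps t in [0, f], acromial keeps t in [1-f, 1], and midshaft
    keeps a window of width f centred at c ~ U(0.4, 0.6).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.retained_fraction_range
    f = float(rng.uniform(lo, hi))
    if spec.fragment_type == "sternal":
        window = (0.0, f)
    elif spec.fragment_type == "acromial":
        window = (1.0 - f, 1.0)
    else:
        centre = float(rng.uniform(0.4, 0.6))
        window = (centre - f / 2.0, centre + f / 2.0)
    t = long_axis_parameter(mesh)
    inside = (t >= window[0]) & (t <= window[1])
    keep = inside[mesh.faces].all(axis=1)
    faces = mesh.faces[keep]
    if len(faces) < 4:
        raise FragmentError(
            f"{spec.fragment_type} cut retained only {len(faces)} faces"
        )
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    v, fc = _cap_loops(mesh.vertices[used], remap[faces])
    tags = set(mesh.tags) | {f"fragment:{spec.fragment_type}"}
    # the medial cap centre is gone from end fragments; drop a stale tag
    idx = _medial_cap_index(mesh)
    if idx is not None:
        tags = {tg for tg in tags if not tg.startswith("medial_vertex:")}
        if remap[idx] >= 0:
            tags.add(f"medial_vertex:{remap[idx]}")
    return TriangleMesh(
        v,
        fc,
        element_id=f"{mesh.element_id}:{spec.fragment_type}",
        side=mesh.side,
        tags=tags,
    )
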