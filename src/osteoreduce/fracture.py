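"""Virtual supracondylar fracture: plane cut, displacement, and replayed moves.

A fracture is created by cutting the humerus with a plane just proximal to
the condyles and rigidly displacing the distal fragment.  Fragment meshes are
stored in the intact pose; each fragment carries a current rigid transform,
which is what a training session manipulates.  The perturbation applied at
creation is kept as ``truth_displacement`` so a perfect reduction (its exact
inverse) is always available as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import HumerusModel
from .errors import CutError
from .transforms import RigidTransform

__all__ = [
    "FracturePlane",
    "FractureState",
    "default_fracture_plane",
    "cut_supracondylar",
    "displace_distal",
    "apply_move",
    "random_perturbation",
]

_FRAGMENT_IDS = ("shaft", "distal")


@dataclass(frozen=True)
class FracturePlane:
    """Cutting plane: a point on the plane and the unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0 or not np.isfinite(norm):
            raise ValueError("plane normal must be nonzero and finite")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points) -> np.ndarray:
        return (np.atleast_2d(np.asarray(points, float)) - self.point) @ self.normal


@dataclass(frozen=True)
class FractureState:
    """Two watertight fragments plus their current and true displacements."""

    fragments: dict  # fragment id -> trimesh.Trimesh, in intact pose
    current_transforms: dict = field(
        default_factory=lambda: {k: RigidTransform.identity() for k in _FRAGMENT_IDS}
    )
    truth_displacement: RigidTransform = field(default_factory=RigidTransform.identity)

    def fragment_ids(self):
        return tuple(self.fragments)

    def transformed_fragment(self, fragment_id: str):
        """The fragment mesh under its current transform."""
        import trimesh

        mesh = self.fragments[fragment_id]
        rt = self.current_transforms[fragment_id]
        return trimesh.Trimesh(rt.apply(mesh.vertices), mesh.faces, process=False)

    def reassembled_mesh(self):
        """All fragments under their current transforms, as one mesh."""
        import trimesh

        return trimesh.util.concatenate(
            [self.transformed_fragment(fid) for fid in self.fragments]
        )

    def to_dict(self) -> dict:
        return {
            "current_transforms": {
                k: v.to_dict() for k, v in self.current_transforms.items()
            },
            "truth_displacement": self.truth_displacement.to_dict(),
        }


def default_fracture_plane(model: HumerusModel) -> FracturePlane:
    """Supracondylar cut: transverse plane just proximal to the epicondyles,
    with the normal tilted 10 degrees anteriorly off the shaft axis."""
    truth = model.truth
    d = truth.hsa.direction
    t_epi = max(
        (truth.medial_epicondyle - truth.hsa.point) @ d,
        (truth.lateral_epicondyle - truth.hsa.point) @ d,
    )
    point = truth.hsa.point + (t_epi + truth.fe_length / 2.0) * d
    ml = truth.lateral_epicondyle - truth.medial_epicondyle
    ml = ml / np.linalg.norm(ml)
    anterior = np.cross(d, ml)
    anterior /= np.linalg.norm(anterior)
    tilt = np.deg2rad(10.0)
    normal = np.cos(tilt) * d + np.sin(tilt) * anterior
    return FracturePlane(point, normal)


def _boundary_loop(mesh) -> np.ndarray:
    """Ordered vertex indices of the single open boundary loop."""
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) < 3:
        raise CutError("cut produced no closed section loop")
    adjacency: dict[int, list[int]] = {}
    for a, b in boundary:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    if any(len(v) != 2 for v in adjacency.values()):
        raise CutError("cut section is not a single simple loop")
    start = min(adjacency)
    loop = [start]
    prev, cur = None, start
    while True:
        nxt = [n for n in adjacency[cur] if n != prev]
        if not nxt:
            raise CutError("cut section loop is not closed")
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        loop.append(cur)
    if len(loop) != len(adjacency):
        raise CutError("cut produced more than one section loop")
    return np.asarray(loop, dtype=int)


def _cap_open_mesh(mesh, outward: np.ndarray):
    """Close a planar hole with a triangulated fan over the section loop."""
    import trimesh

    # the slicer emits per-triangle vertices along the section; weld them so
    # the boundary becomes a connected loop
    mesh = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    mesh.merge_vertices(digits_vertex=7)
    mesh.update_faces(mesh.nondegenerate_faces())
    loop = _boundary_loop(mesh)
    verts = np.asarray(mesh.vertices)
    center = verts[loop].mean(axis=0)
    new_verts = np.vstack([verts, center])
    ci = len(verts)
    fan = np.array(
        [[ci, loop[i], loop[(i + 1) % len(loop)]] for i in range(len(loop))],
        dtype=int,
    )
    # orient the fan so its normals face along `outward`
    v0 = new_verts[fan[0, 1]] - center
    v1 = new_verts[fan[0, 2]] - center
    if np.cross(v0, v1) @ outward < 0:
        fan = fan[:, [0, 2, 1]]
    capped = trimesh.Trimesh(
        new_verts, np.vstack([mesh.faces, fan]), process=False
    )
    if not capped.is_watertight:
        raise CutError("capped fragment is not watertight")
    return capped


def cut_supracondylar(
    model: HumerusModel, plane: FracturePlane | None = None
) -> FractureState:
    """Cut the humerus into a shaft and a distal fragment.

    Both fragments are capped across the section with a triangle fan and are
    watertight; current transforms and the true displacement start at
    identity.  Raises :class:`CutError` if the plane misses the bone or the
    section is not a single loop.
    """
    import trimesh

    if plane is None:
        plane = default_fracture_plane(model)
    mesh = model.mesh
    sd = plane.signed_distance(mesh.vertices)
    if sd.min() > 0 or sd.max() < 0:
        raise CutError("fracture plane does not intersect the bone")

    halves = {}
    for sign in (1.0, -1.0):
        half = trimesh.intersections.slice_mesh_plane(
            mesh,
            plane_normal=sign * plane.normal,
            plane_origin=plane.point,
            cap=False,
        )
        if half is None or len(half.faces) == 0:
            raise CutError("fracture plane does not intersect the bone")
        capped = _cap_open_mesh(half, -sign * plane.normal)
        if capped.body_count != 1:
            raise CutError("cut produced more than two fragments")
        halves[sign] = capped

    head_side = float(np.sign(plane.signed_distance(model.truth.head_center)[0]))
    if head_side == 0:
        raise CutError("fracture plane passes through the humeral head landmark")
    fragments = {
        "shaft": halves[head_side],
        "distal": halves[-head_side],
    }
    return FractureState(fragments=fragments)


def displace_distal(
    state: FractureState, perturbation: RigidTransform
) -> FractureState:
    """Displace the distal fragment, updating the true displacement.

    This models the injury itself: the recorded ``truth_displacement`` is the
    total perturbation whose inverse constitutes a perfect reduction.
    """
    current = dict(state.current_transforms)
    current["distal"] = perturbation @ current["distal"]
    return replace(
        state,
        current_transforms=current,
        truth_displacement=perturbation @ state.truth_displacement,
    )


def apply_move(
    state: FractureState, fragment_id: str, move: RigidTransform
) -> FractureState:
    """Apply a user move to one fragment (the session-replay operation)."""
    if fragment_id not in state.fragments:
        raise CutError(f"unknown fragment id: {fragment_id!r}")
    current = dict(state.current_transforms)
    current[fragment_id] = move @ current[fragment_id]
    return replace(state, current_transforms=current)


def random_perturbation(
    rng: np.random.Generator,
    about: np.ndarray,
    angle_range_deg=(5.0, 25.0),
    translation_range_mm=(2.0, 10.0),
) -> RigidTransform:
    """Seeded random injury displacement about a point near the fracture.

    Rotation of uniform magnitude within ``angle_range_deg`` about a uniform
    random axis through ``about``, plus a translation of uniform magnitude
    within ``translation_range_mm`` in a uniform random direction.
    """
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(*angle_range_deg))
    rot = Rotation.from_rotvec(angle * axis)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    magnitude = rng.uniform(*translation_range_mm)
    spin = RigidTransform.rotation_about_point(rot, np.asarray(about, float))
    return RigidTransform(np.array([0.0, 0.0, 0.0, 1.0]), magnitude * direction) @ spin
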