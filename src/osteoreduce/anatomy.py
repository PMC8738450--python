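"""Parametric synthetic humeri with exact ground-truth landmarks.

Real CT-derived humeri are not distributed with this package, so testing and
calibration run on a constructive stand-in: a long bone assembled from a
shaft (capsule along the proximal axis), a spherical humeral head offset
posteromedially, two distal condylar spheres (trochlea medial, capitulum
lateral), two epicondylar bumps, and an anterior bicipital groove carved out
as a capsule subtraction.  The solid is defined as a signed-distance field
and contoured with marching cubes, which yields a watertight triangle mesh;
every landmark is recorded analytically from the same construction, so
detection and metric code can be graded against exact ground truth.

Frame convention (right humerus): millimetres, right-handed, +z proximal
along the shaft axis, +x lateral, +y anterior.  A left humerus is the mirror
of the right across the sagittal plane x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GenerationError
from .landmarks import Axis, LandmarkSet

__all__ = [
    "GenerationParams",
    "HumerusModel",
    "generate_humerus",
    "mirror_model",
    "generate_pair",
]

# fixed secondary dimensions (mm), not exposed as parameters
_EPICONDYLE_BUMP_RADIUS = 5.0
_EPICONDYLE_Z = 5.0
_GROOVE_RADIUS = 4.0
_GROOVE_X = 1.5  # slight lateral offset of the channel
_GROOVE_APEX_FRACTION = 0.78  # of the full axial extent
_GROOVE_END_RISE = 2.5  # mm shallower at the channel ends


@dataclass(frozen=True)
class GenerationParams:
    """Dimensions and randomness controls for one synthetic humerus.

    Defaults approximate an adult humerus: ~30 cm long, ~45 mm head
    diameter, condylar radii of roughly 10-12 mm.
    """

    shaft_length: float = 280.0
    shaft_radius: float = 10.0
    head_radius: float = 24.0
    head_offset: float = 6.0  # posteromedial offset of the head center
    trochlea_radius: float = 12.0
    capitulum_radius: float = 10.0
    epicondyle_protrusion: float = 8.0
    groove_depth: float = 3.0
    surface_noise_sd: float = 0.0
    asymmetry_sd: float = 0.0  # contralateral low-frequency shape jitter
    seed: int = 0
    voxel_pitch: float = 1.0  # marching-cubes sampling pitch

    def __post_init__(self):
        lengths = {
            "shaft_length": self.shaft_length,
            "shaft_radius": self.shaft_radius,
            "head_radius": self.head_radius,
            "trochlea_radius": self.trochlea_radius,
            "capitulum_radius": self.capitulum_radius,
            "epicondyle_protrusion": self.epicondyle_protrusion,
            "groove_depth": self.groove_depth,
            "voxel_pitch": self.voxel_pitch,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.head_offset < 0:
            raise ValueError("head_offset must be non-negative")
        if self.surface_noise_sd < 0 or self.asymmetry_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not self.shaft_length > 4.0 * self.head_radius:
            raise ValueError("shaft_length must exceed 4 * head_radius")
        if self.groove_depth >= self.shaft_radius:
            raise ValueError("groove_depth must be smaller than shaft_radius")

    def to_dict(self) -> dict:
        return {
            k: (int(v) if k == "seed" else float(v))
            for k, v in self.__dict__.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerationParams":
        return cls(**d)


@dataclass(frozen=True)
class HumerusModel:
    """A watertight humerus mesh with its analytic ground-truth landmarks."""

    mesh: object  # trimesh.Trimesh
    side: str  # "left" | "right"
    truth: LandmarkSet
    params: GenerationParams = field(default_factory=GenerationParams)

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


class _Geometry:
    """Analytic primitive layout for a *right* humerus."""

    def __init__(self, p: GenerationParams):
        self.p = p
        sep = 0.5 * (p.trochlea_radius + p.capitulum_radius)
        off = p.head_offset / np.sqrt(2.0)
        self.head_center = np.array([-off, -off, p.shaft_length])
        self.trochlea_center = np.array([-sep, 0.0, 0.0])
        self.capitulum_center = np.array([sep, 0.0, 0.0])
        # epicondylar bumps protrude `epicondyle_protrusion` beyond the
        # condylar bulge on each side
        re = _EPICONDYLE_BUMP_RADIUS
        med_tip = sep + p.trochlea_radius + p.epicondyle_protrusion
        lat_tip = sep + p.capitulum_radius + p.epicondyle_protrusion
        self.medial_bump_center = np.array([-(med_tip - re), 0.0, _EPICONDYLE_Z])
        self.lateral_bump_center = np.array([lat_tip - re, 0.0, _EPICONDYLE_Z])
        self.medial_epicondyle = np.array([-med_tip, 0.0, _EPICONDYLE_Z])
        self.lateral_epicondyle = np.array([lat_tip, 0.0, _EPICONDYLE_Z])
        # axial extent of the solid
        self.z_min = -p.trochlea_radius
        self.z_max = p.shaft_length + p.head_radius
        extent = self.z_max - self.z_min
        # groove channel: V-shaped capsule carved into the anterior shaft,
        # deepest at the apex so the landmark is unique
        zg = self.z_min + _GROOVE_APEX_FRACTION * extent
        y_surf = np.sqrt(p.shaft_radius**2 - _GROOVE_X**2)
        y_apex = y_surf - p.groove_depth + _GROOVE_RADIUS
        self.groove_apex = np.array([_GROOVE_X, y_apex, zg])
        self.groove_end_lo = np.array(
            [_GROOVE_X, y_apex + _GROOVE_END_RISE, zg - 0.12 * extent]
        )
        self.groove_end_hi = np.array(
            [_GROOVE_X, y_apex + _GROOVE_END_RISE, zg + 0.08 * extent]
        )
        self.bicipital_groove = np.array([_GROOVE_X, y_surf - p.groove_depth, zg])

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        p = self.p
        # the shaft capsule's lower end is buried inside the condylar mass so
        # the distal articular surface is purely condylar
        d = _capsule(pts, np.array([0.0, 0.0, p.trochlea_radius]),
                     np.array([0.0, 0.0, p.shaft_length]), p.shaft_radius)
        d = np.minimum(d, _sphere(pts, self.head_center, p.head_radius))
        d = np.minimum(d, _sphere(pts, self.trochlea_center, p.trochlea_radius))
        d = np.minimum(d, _sphere(pts, self.capitulum_center, p.capitulum_radius))
        d = np.minimum(
            d, _sphere(pts, self.medial_bump_center, _EPICONDYLE_BUMP_RADIUS)
        )
        d = np.minimum(
            d, _sphere(pts, self.lateral_bump_center, _EPICONDYLE_BUMP_RADIUS)
        )
        groove = np.minimum(
            _capsule(pts, self.groove_end_lo, self.groove_apex, _GROOVE_RADIUS),
            _capsule(pts, self.groove_apex, self.groove_end_hi, _GROOVE_RADIUS),
        )
        return np.maximum(d, -groove)

    def bounds(self, margin: float) -> tuple[np.ndarray, np.ndarray]:
        p = self.p
        xr = self.lateral_epicondyle[0]
        xl = min(self.medial_epicondyle[0], self.head_center[0] - p.head_radius)
        ymax = max(p.shaft_radius, self.head_center[1] + p.head_radius,
                   p.trochlea_radius)
        ymin = self.head_center[1] - p.head_radius
        lo = np.array([xl, ymin, self.z_min]) - margin
        hi = np.array([xr, ymax, self.z_max]) + margin
        return lo, hi

    def truth(self) -> LandmarkSet:
        return LandmarkSet.from_primary(
            head_center=self.head_center,
            bicipital_groove=self.bicipital_groove,
            trochlea_center=self.trochlea_center,
            capitulum_center=self.capitulum_center,
            medial_epicondyle=self.medial_epicondyle,
            lateral_epicondyle=self.lateral_epicondyle,
            head_radius=self.p.head_radius,
            hsa=Axis(np.zeros(3), np.array([0.0, 0.0, 1.0])),
        )


def _sphere(pts, center, radius):
    return np.linalg.norm(pts - center, axis=1) - radius


def _capsule(pts, a, b, radius):
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(pts - closest, axis=1) - radius


def _smooth_field(rng: np.random.Generator, n_waves: int, wavelengths: tuple):
    """Random smooth scalar field as a sum of plane cosine waves."""
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    lam = rng.uniform(*wavelengths, size=n_waves)
    k = dirs * (2.0 * np.pi / lam)[:, None]
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
    amp = rng.normal(size=n_waves)

    def field(pts: np.ndarray) -> np.ndarray:
        pts2 = np.atleast_2d(pts)
        vals = np.cos(pts2 @ k.T + phase) @ amp
        return vals / np.sqrt(0.5 * np.sum(amp**2))  # unit variance

    return field


def generate_humerus(params: GenerationParams, side: str = "right") -> HumerusModel:
    """Generate one synthetic humerus.

    The bone is always constructed right-sided and mirrored afterwards for
    ``side='left'``, so a left and a right bone from the same parameters are
    exact mirror images.  Identical parameters (including seed) give
    bit-identical meshes.
    """
    import trimesh
    from skimage import measure

    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    geo = _Geometry(params)
    pitch = params.voxel_pitch
    margin = 3.0 * pitch + 4.0 * params.surface_noise_sd
    lo, hi = geo.bounds(margin)
    xs = [np.arange(lo[i], hi[i] + pitch, pitch) for i in range(3)]
    grid = np.meshgrid(*xs, indexing="ij")
    pts = np.column_stack([g.ravel() for g in grid])
    sdf = geo.sdf(pts).reshape(grid[0].shape)
    try:
        verts, faces, _, _ = measure.marching_cubes(
            sdf, level=0.0, spacing=(pitch, pitch, pitch)
        )
    except (ValueError, RuntimeError) as exc:
        raise GenerationError(f"isosurface extraction failed: {exc}") from exc
    verts = verts + lo
    mesh = trimesh.Trimesh(verts, faces, process=False)
    mesh.merge_vertices(digits_vertex=6)
    mesh.update_faces(mesh.nondegenerate_faces())

    if params.surface_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xB07E]))
        noise = _smooth_field(rng, 24, (15.0, 40.0))
        disp = params.surface_noise_sd * noise(mesh.vertices)
        mesh = trimesh.Trimesh(
            mesh.vertices + disp[:, None] * np.asarray(mesh.vertex_normals),
            mesh.faces,
            process=False,
        )

    if not mesh.is_watertight:
        raise GenerationError("generated mesh is not watertight")
    if not mesh.volume > 0:
        raise GenerationError("generated mesh has non-positive enclosed volume")

    model = HumerusModel(mesh=mesh, side="right", truth=geo.truth(), params=params)
    return mirror_model(model) if side == "left" else model


def mirror_model(model: HumerusModel) -> HumerusModel:
    """Reflect a humerus across the sagittal plane x = 0.

    Triangle winding is re-flipped so outward normals are preserved; the side
    label toggles and ground-truth landmarks are mirrored.
    """
    import trimesh

    verts = np.asarray(model.mesh.vertices) * np.array([-1.0, 1.0, 1.0])
    faces = np.asarray(model.mesh.faces)[:, ::-1]
    mesh = trimesh.Trimesh(verts, faces, process=False)
    return HumerusModel(
        mesh=mesh,
        side="left" if model.side == "right" else "right",
        truth=model.truth.mirrored(),
        params=model.params,
    )


def generate_pair(params: GenerationParams) -> tuple[HumerusModel, HumerusModel]:
    """Generate a (right, left) pair for contralateral comparison.

    The left bone is the mirror of the right with smooth low-frequency shape
    jitter of scale ``asymmetry_sd`` (mm) applied, emulating natural
    left/right asymmetry; ``asymmetry_sd = 0`` yields an exact mirror pair.
    The jitter displaces mesh vertices and ground-truth landmark points with
    the same smooth field, so the left truth remains consistent with its
    surface.
    """
    import trimesh

    right = generate_humerus(params, side="right")
    left = mirror_model(right)
    if params.asymmetry_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xA57]))
        fields = [_smooth_field(rng, 12, (60.0, 140.0)) for _ in range(3)]

        def displace(pts):
            pts2 = np.atleast_2d(pts)
            disp = np.column_stack([f(pts2) for f in fields])
            return pts2 + params.asymmetry_sd * disp

        mesh = trimesh.Trimesh(
            displace(left.mesh.vertices), left.mesh.faces, process=False
        )
        if not mesh.is_watertight:
            raise GenerationError("jittered contralateral mesh is not watertight")
        tr = left.truth
        hsa_p2 = tr.hsa.point + 100.0 * tr.hsa.direction
        new_hsa_pts = displace(np.vstack([tr.hsa.point, hsa_p2]))
        truth = LandmarkSet.from_primary(
            head_center=displace(tr.head_center)[0],
            bicipital_groove=displace(tr.bicipital_groove)[0],
            trochlea_center=displace(tr.trochlea_center)[0],
            capitulum_center=displace(tr.capitulum_center)[0],
            medial_epicondyle=displace(tr.medial_epicondyle)[0],
            lateral_epicondyle=displace(tr.lateral_epicondyle)[0],
            head_radius=tr.head_radius,
            hsa=Axis(new_hsa_pts[0], new_hsa_pts[1] - new_hsa_pts[0]),
        )
        left = HumerusModel(mesh=mesh, side="left", truth=truth, params=params)
    return right, left
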