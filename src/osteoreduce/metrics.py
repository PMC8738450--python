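"""Contralateral comparison metrics and the reduction-accuracy coefficient.

The reduced bone is compared one-on-one against the mirrored healthy
contralateral bone (the "template").  The template is first registered onto
the reduced bone by a least-squares rigid superposition anchored on the
proximal/shaft side — in a supracondylar fracture the shaft is the surgeon's
fixed reference, so residual distal deviations measure reduction error.

Fifteen metrics are computed: six landmark point distances, four axis
angles, two length differences, the Jaccard overlaps of the two Mueller
cubes, and the area discrepancy of the distal "rotation triangle".  The
reduction-accuracy coefficient rho aggregates them into [0, 1] via clamped
linear sub-scores with per-metric tolerances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import RegistrationError
from .landmarks import Axis, LandmarkSet, OrientedCube
from .transforms import RigidTransform

__all__ = [
    "MetricVector",
    "RhoConfig",
    "register_template",
    "angle_between_axes",
    "cube_overlap",
    "rotation_triangle_area",
    "compute_metric_vector",
    "compute_rho",
]

#: metric name -> (report row label, unit)
METRIC_INFO = {
    "capitulum_mm": ("Capitulum", "mm"),
    "trochlea_mm": ("Trochlea", "mm"),
    "head_mm": ("Head", "mm"),
    "lateral_epicondyle_mm": ("Lateral epicondyle", "mm"),
    "medial_epicondyle_mm": ("Medial epicondyle", "mm"),
    "bicipital_groove_mm": ("Bicipital groove", "mm"),
    "angle_hsa_deg": ("Angle HSA", "deg"),
    "angle_eca_deg": ("Angle ECA", "deg"),
    "angle_fea_deg": ("Angle FEA", "deg"),
    "angle_fea_med_deg": ("Angle FEA-MED", "deg"),
    "fe_length_mm": ("FE length", "mm"),
    "humeral_length_mm": ("Humeral length", "mm"),
    "distal_overlap": ("Distal Mueller cube overlapping", "fraction"),
    "proximal_overlap": ("Proximal Mueller cube overlapping", "fraction"),
    "rotation_triangle_mm2": ("Area of the rotation triangle", "mm^2"),
}

_OVERLAP_METRICS = ("distal_overlap", "proximal_overlap")


@dataclass(frozen=True)
class MetricVector:
    """The 15 healthy-vs-reduced comparison metrics.

    Distances, angle differences and the triangle-area discrepancy are
    absolute deviations (>= 0, ideal 0); the two cube overlaps are Jaccard
    fractions in [0, 1] (ideal 1).
    """

    capitulum_mm: float
    trochlea_mm: float
    head_mm: float
    lateral_epicondyle_mm: float
    medial_epicondyle_mm: float
    bicipital_groove_mm: float
    angle_hsa_deg: float
    angle_eca_deg: float
    angle_fea_deg: float
    angle_fea_med_deg: float
    fe_length_mm: float
    humeral_length_mm: float
    distal_overlap: float
    proximal_overlap: float
    rotation_triangle_mm2: float

    def __post_init__(self):
        for f in fields(self):
            v = float(getattr(self, f.name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
            object.__setattr__(self, f.name, v)
        for name in _OVERLAP_METRICS:
            if getattr(self, name) > 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "MetricVector":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})

    def report_rows(self) -> list[dict]:
        """Table rows (label, unit, value) for the human-readable report."""
        return [
            {"metric": METRIC_INFO[k][0], "unit": METRIC_INFO[k][1], "value": v}
            for k, v in self.as_dict().items()
        ]


def _default_tolerances() -> dict:
    tol = {}
    for name in METRIC_INFO:
        if name in _OVERLAP_METRICS:
            continue
        if name.endswith("_deg"):
            tol[name] = 10.0
        elif name.endswith("_mm2"):
            tol[name] = 1.0
        else:
            tol[name] = 10.0
    return tol


@dataclass(frozen=True)
class RhoConfig:
    """Per-metric tolerances and weights for the rho aggregation.

    A deviation metric scores ``clamp(1 - deviation / tolerance, 0, 1)``;
    an overlap metric scores its own value.  Defaults: 10 mm for distances
    and length differences, 10 degrees for angles, 1 mm^2 for the rotation
    triangle, unit weights.  Tolerances are exposed so calibration data from
    real cases can replace them.
    """

    tolerances: dict = field(default_factory=_default_tolerances)
    weights: dict = field(
        default_factory=lambda: {name: 1.0 for name in METRIC_INFO}
    )

    def __post_init__(self):
        for name, tau in self.tolerances.items():
            if name not in METRIC_INFO or name in _OVERLAP_METRICS:
                raise ValueError(f"unknown deviation metric: {name}")
            if not tau > 0:
                raise ValueError(f"tolerance for {name} must be positive")
        total = 0.0
        for name, w in self.weights.items():
            if name not in METRIC_INFO:
                raise ValueError(f"unknown metric: {name}")
            if w < 0:
                raise ValueError(f"weight for {name} must be >= 0")
            total += w
        if not total > 0:
            raise ValueError("weights must not all be zero")

    def to_dict(self) -> dict:
        return {"tolerances": dict(self.tolerances), "weights": dict(self.weights)}

    @classmethod
    def from_dict(cls, d: dict) -> "RhoConfig":
        return cls(tolerances=dict(d["tolerances"]), weights=dict(d["weights"]))


def angle_between_axes(a: Axis | np.ndarray, b: Axis | np.ndarray) -> float:
    """Sign-insensitive angle between two line directions, in [0, 90] deg."""
    da = a.direction if isinstance(a, Axis) else np.asarray(a, float)
    db = b.direction if isinstance(b, Axis) else np.asarray(b, float)
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise ValueError("zero-length axis direction")
    cosine = abs(float(da @ db)) / (na * nb)
    return float(np.degrees(np.arccos(min(cosine, 1.0))))


def register_template(
    reduced: LandmarkSet, template: LandmarkSet
) -> RigidTransform:
    """Rigid superposition of the template onto the reduced bone.

    Anchored on the shaft-side triplet {head center, bicipital groove, point
    on the HSA 50 mm distal to the head}; solved in closed form (Kabsch), so
    the result is always a proper rotation plus translation, never a
    reflection or scaling.  Returns the transform to apply to the template.
    """
    a = _anchor_triplet(reduced)
    b = _anchor_triplet(template)
    for pts in (a, b):
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        if area < 1e-9:
            raise RegistrationError("anchor landmarks are collinear")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a - ca, b - cb)
    return RigidTransform.from_rotation(rot, ca - rot.apply(cb))


def _anchor_triplet(lm: LandmarkSet) -> np.ndarray:
    head_on_axis = lm.hsa.project(lm.head_center)
    shaft_point = head_on_axis - 50.0 * lm.hsa.direction
    return np.vstack([lm.head_center, lm.bicipital_groove, shaft_point])


def cube_overlap(a: OrientedCube, b: OrientedCube, voxel: float) -> float:
    """Jaccard overlap |A n B| / |A u B| of two oriented cubes.

    Both cubes are sampled on a grid of pitch ``voxel`` spanning their joint
    bounding box.  The grid lives in the first cube's local frame, so the
    result depends only on the cubes' relative pose and is invariant under a
    common rigid motion.
    """
    if not voxel > 0:
        raise ValueError("voxel pitch must be positive")
    if voxel > min(a.edge, b.edge) / 10.0:
        raise ValueError("voxel pitch must be at most a tenth of the cube edge")
    # express both cubes in a's local frame
    b = OrientedCube(a.axes @ (b.center - a.center), b.axes @ a.axes.T, b.edge)
    a = OrientedCube(np.zeros(3), np.eye(3), a.edge)
    corners = np.vstack([a.corners(), b.corners()])
    lo = corners.min(axis=0)
    hi = corners.max(axis=0)
    axes = [np.arange(lo[i] + voxel / 2.0, hi[i], voxel) for i in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([g.ravel() for g in grid])
    in_a = a.contains(pts)
    in_b = b.contains(pts)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(in_a & in_b) / union)


def _rotation_triangle(lm: LandmarkSet) -> np.ndarray:
    """Vertices (trochlea, capitulum, HSA x distal-plane intersection)."""
    mid = 0.5 * (lm.trochlea_center + lm.capitulum_center)
    t = (mid - lm.hsa.point) @ lm.hsa.direction
    apex = lm.hsa.point + t * lm.hsa.direction
    return np.vstack([lm.trochlea_center, lm.capitulum_center, apex])


def _triangle_area(tri: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0])))


def rotation_triangle_area(reduced: LandmarkSet, template: LandmarkSet) -> float:
    """Absolute area difference of the distal rotation triangles (mm^2).

    The triangle spans the two condylar centers and the point where the HSA
    pierces the distal transverse plane; a distal malrotation skews it, so
    the area discrepancy between sides captures rotational mismatch.  The
    area is intrinsic to each side, hence invariant to registration.
    """
    area_r = _triangle_area(_rotation_triangle(reduced))
    area_t = _triangle_area(_rotation_triangle(template))
    if area_r < 1e-12 or area_t < 1e-12:
        warnings.warn("degenerate (collinear) rotation triangle", RuntimeWarning)
    return abs(area_r - area_t)


def _fea_med_angle(lm: LandmarkSet) -> float:
    """Angle between the FEA and the trochlea-to-medial-epicondyle direction."""
    return angle_between_axes(
        lm.fea.direction, lm.medial_epicondyle - lm.trochlea_center
    )


def compute_metric_vector(
    reduced: LandmarkSet,
    template: LandmarkSet,
    voxel_divisions: int = 50,
) -> MetricVector:
    """All 15 comparison metrics between the reduced bone and the template.

    The template is registered internally with :func:`register_template`;
    cube overlaps use a voxel pitch of ``edge / voxel_divisions``.
    """
    rt = register_template(reduced, template)
    tpl = template.transformed(rt)

    def dist(name: str) -> float:
        return float(
            np.linalg.norm(getattr(reduced, name) - getattr(tpl, name))
        )

    def overlap(cube_r: OrientedCube, cube_t: OrientedCube) -> float:
        voxel = min(cube_r.edge, cube_t.edge) / voxel_divisions
        return cube_overlap(cube_r, cube_t, voxel)

    return MetricVector(
        capitulum_mm=dist("capitulum_center"),
        trochlea_mm=dist("trochlea_center"),
        head_mm=dist("head_center"),
        lateral_epicondyle_mm=dist("lateral_epicondyle"),
        medial_epicondyle_mm=dist("medial_epicondyle"),
        bicipital_groove_mm=dist("bicipital_groove"),
        angle_hsa_deg=angle_between_axes(reduced.hsa, tpl.hsa),
        angle_eca_deg=angle_between_axes(reduced.eca, tpl.eca),
        angle_fea_deg=angle_between_axes(reduced.fea, tpl.fea),
        angle_fea_med_deg=abs(_fea_med_angle(reduced) - _fea_med_angle(tpl)),
        fe_length_mm=abs(reduced.fe_length - tpl.fe_length),
        humeral_length_mm=abs(reduced.humeral_length - tpl.humeral_length),
        distal_overlap=overlap(reduced.muller_distal, tpl.muller_distal),
        proximal_overlap=overlap(reduced.muller_proximal, tpl.muller_proximal),
        rotation_triangle_mm2=rotation_triangle_area(reduced, tpl),
    )


def compute_rho(m: MetricVector, cfg: RhoConfig | None = None) -> float:
    """Aggregate the metric vector into the reduction-accuracy coefficient.

    ``rho = sum(w_i s_i) / sum(w_i)`` with ``s_i = clamp(1 - dev_i/tau_i,
    0, 1)`` for deviation metrics and ``s_i = overlap_i`` for the cube
    overlaps; 0 means no reduction, 1 a perfect one.
    """
    scores = rho_subscores(m, cfg)
    cfg = cfg or RhoConfig()
    num = sum(cfg.weights.get(k, 0.0) * s for k, s in scores.items())
    den = sum(cfg.weights.get(k, 0.0) for k in scores)
    return float(num / den)


def rho_subscores(m: MetricVector, cfg: RhoConfig | None = None) -> dict:
    """Per-metric sub-scores in [0, 1] entering the rho aggregation."""
    cfg = cfg or RhoConfig()
    out = {}
    for name, value in m.as_dict().items():
        if name in _OVERLAP_METRICS:
            out[name] = float(value)
        else:
            tau = cfg.tolerances[name]
            out[name] = float(np.clip(1.0 - value / tau, 0.0, 1.0))
    return out
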