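"""File formats and the end-to-end pipeline harness.

Meshes are exchanged as STL/PLY/OBJ (millimetres); landmark sets, metric
reports and configuration as JSON; session logs as JSON Lines, one event per
line.  JSON floats are serialized with 9 significant digits so reports
round-trip reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anatomy import GenerationParams, generate_pair, mirror_model
from .errors import FormatError
from .fracture import cut_supracondylar, displace_distal, random_perturbation
from .landmarks import LandmarkSet, detect_landmarks
from .metrics import RhoConfig
from .scoring import (
    ScoreBreakdown,
    ScoringConfig,
    SessionEvent,
    SessionLog,
    final_report,
    replay_session,
)

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_session_log",
    "write_session_log",
    "dump_json",
    "PipelineConfig",
    "run_pipeline",
]

_MESH_SUFFIXES = {".stl", ".ply", ".obj"}


def read_mesh(path):
    """Load a triangle mesh (STL, PLY or OBJ); vertices are millimetres.

    Polygonal faces (e.g. OBJ quads) are triangulated on load.  Raises
    :class:`FormatError` for unreadable or empty input.
    """
    import trimesh

    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(path, f"unsupported mesh format {path.suffix!r}")
    if not path.is_file():
        raise FormatError(path, "file does not exist")
    try:
        mesh = trimesh.load(path, force="mesh")
    except Exception as exc:
        raise FormatError(path, f"unreadable mesh: {exc}") from exc
    if mesh is None or not hasattr(mesh, "faces") or len(mesh.faces) == 0:
        raise FormatError(path, "mesh contains no triangles")
    import trimesh as _t

    return _t.Trimesh(
        np.asarray(mesh.vertices, float), np.asarray(mesh.faces), process=False
    )


def write_mesh(mesh, path):
    """Write a mesh as binary STL, PLY, or ASCII OBJ by file extension."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(path, f"unsupported mesh format {path.suffix!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)
    return path


def _round_floats(obj, sig: int = 9):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def dump_json(obj: dict, path=None) -> str:
    """Serialize with sorted keys and 9-significant-digit floats."""
    text = json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    dump_json(landmarks.to_dict(), path)


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    try:
        return LandmarkSet.from_dict(json.loads(path.read_text()))
    except (OSError, ValueError, KeyError) as exc:
        raise FormatError(path, f"invalid landmark file: {exc}") from exc


def write_session_log(log: SessionLog, path) -> None:
    lines = [json.dumps(_round_floats(e.to_dict())) for e in log.events]
    Path(path).write_text("\n".join(lines) + "\n")


def read_session_log(path) -> SessionLog:
    path = Path(path)
    try:
        events = [
            SessionEvent.from_dict(json.loads(line))
            for line in path.read_text().splitlines()
            if line.strip()
        ]
        return SessionLog(tuple(events))
    except (OSError, ValueError, KeyError) as exc:
        raise FormatError(path, f"invalid session log: {exc}") from exc


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end synthetic pipeline needs, in one place.

    All randomness (generation noise, the injury displacement) derives from
    the single ``seed``; identical configs produce byte-identical reports.
    """

    seed: int = 0
    generation: GenerationParams = None
    rho: RhoConfig = field(default_factory=RhoConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    perturbation_angle_deg: tuple = (5.0, 25.0)
    perturbation_translation_mm: tuple = (2.0, 10.0)

    def __post_init__(self):
        if self.generation is None:
            object.__setattr__(
                self, "generation", GenerationParams(seed=self.seed)
            )

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "generation": self.generation.to_dict(),
            "rho": self.rho.to_dict(),
            "scoring": self.scoring.to_dict(),
            "perturbation_angle_deg": list(self.perturbation_angle_deg),
            "perturbation_translation_mm": list(self.perturbation_translation_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {
            "seed",
            "generation",
            "rho",
            "scoring",
            "perturbation_angle_deg",
            "perturbation_translation_mm",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {"seed": int(d.get("seed", 0))}
        if "generation" in d:
            kwargs["generation"] = GenerationParams.from_dict(d["generation"])
        if "rho" in d:
            kwargs["rho"] = RhoConfig.from_dict(d["rho"])
        if "scoring" in d:
            kwargs["scoring"] = ScoringConfig.from_dict(d["scoring"])
        if "perturbation_angle_deg" in d:
            kwargs["perturbation_angle_deg"] = tuple(d["perturbation_angle_deg"])
        if "perturbation_translation_mm" in d:
            kwargs["perturbation_translation_mm"] = tuple(
                d["perturbation_translation_mm"]
            )
        return cls(**kwargs)


def default_session_log(state) -> SessionLog:
    """A minimal perfect-reduction session: one corrective move, one check."""
    inverse = state.truth_displacement.inverse()
    return SessionLog(
        (
            SessionEvent(0.0, "select"),
            SessionEvent(
                10.0,
                "move",
                {"fragment_id": "distal", "transform": inverse},
            ),
            SessionEvent(15.0, "check"),
            SessionEvent(20.0, "finish"),
        )
    )


def run_pipeline(config: PipelineConfig, log: SessionLog | None = None) -> ScoreBreakdown:
    """Execute the full synthetic chain and grade it.

    generate pair -> mirror the healthy side -> detect the template ->
    fracture and displace the injured side -> replay the session log
    (default: the perfect-reduction session) -> detect, compare, score.
    """
    right, left = generate_pair(config.generation)
    template = detect_landmarks(mirror_model(left).mesh)
    state = cut_supracondylar(right)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF42C]))
    perturbation = random_perturbation(
        rng,
        about=right.truth.fea.point,
        angle_range_deg=config.perturbation_angle_deg,
        translation_range_mm=config.perturbation_translation_mm,
    )
    state = displace_distal(state, perturbation)
    if log is None:
        log = default_session_log(state)
    state = replay_session(state, log)
    return final_report(state, template, log, config.scoring, config.rho)
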