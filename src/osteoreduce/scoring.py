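"""Gamified session score and the final per-metric report.

The final score of a training session is

    score = (k1 * rho - k2 * t - k3 * n_c) * h

where ``rho`` is the reduction-accuracy coefficient, ``t`` the elapsed time
in seconds, ``n_c`` the number of on-demand accuracy checks (each one a
stand-in for an intraoperative X-ray), and ``h`` a multiplier applied when
the healthy contralateral template was displayed at any point during the
session.  Defaults: k1 = 1000, k2 = 0.1, k3 = 10, h = 0.7.  The score is not
clamped; a slow, check-heavy session can go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SessionError
from .metrics import (
    MetricVector,
    RhoConfig,
    compute_metric_vector,
    compute_rho,
    rho_subscores,
)
from .transforms import RigidTransform

__all__ = [
    "ScoringConfig",
    "ScoreInputs",
    "SessionEvent",
    "SessionLog",
    "ScoreBreakdown",
    "compute_score",
    "summarize_session",
    "replay_session",
    "final_report",
]

_EVENT_KINDS = ("select", "move", "check", "toggle_hint", "finish")


@dataclass(frozen=True)
class ScoringConfig:
    """Coefficients of the score formula.

    k1: score units per unit rho; k2: score units per second; k3: score
    units per check; h_factor: multiplier when the template was used.
    """

    k1: float = 1000.0
    k2: float = 0.1
    k3: float = 10.0
    h_factor: float = 0.7

    def __post_init__(self):
        if not self.k1 > 0:
            raise ValueError("k1 must be positive")
        if self.k2 < 0 or self.k3 < 0:
            raise ValueError("k2 and k3 must be non-negative")
        if not 0.0 < self.h_factor <= 1.0:
            raise ValueError("h_factor must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
            "h_factor": self.h_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringConfig":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class ScoreInputs:
    """Per-session quantities entering the score formula."""

    rho: float
    t: float  # seconds elapsed
    n_c: float  # number of reduction checks
    template_used: bool = False

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if self.n_c < 0:
            raise ValueError("n_c must be non-negative")

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "t_seconds": self.t,
            "n_checks": self.n_c,
            "template_used": bool(self.template_used),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreInputs":
        return cls(
            rho=float(d["rho"]),
            t=float(d["t_seconds"]),
            n_c=float(d["n_checks"]),
            template_used=bool(d["template_used"]),
        )


def compute_score(inputs: ScoreInputs, cfg: ScoringConfig | None = None) -> float:
    """Evaluate the score formula exactly; may be negative (no clamping)."""
    cfg = cfg or ScoringConfig()
    h = cfg.h_factor if inputs.template_used else 1.0
    return (cfg.k1 * inputs.rho - cfg.k2 * inputs.t - cfg.k3 * inputs.n_c) * h


@dataclass(frozen=True)
class SessionEvent:
    """One timestamped event: select | move | check | toggle_hint | finish.

    ``payload`` carries the fragment id and rigid transform for a move, or
    the on/off boolean for a hint toggle.
    """

    timestamp: float  # seconds
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _EVENT_KINDS:
            raise SessionError(f"unknown event kind: {self.kind!r}")
        if self.timestamp < 0:
            raise SessionError("event timestamps must be non-negative")

    def to_dict(self) -> dict:
        d = {"timestamp": self.timestamp, "kind": self.kind}
        if self.kind == "move":
            d["fragment_id"] = self.payload["fragment_id"]
            d["transform"] = self.payload["transform"].to_dict()
        elif self.kind == "toggle_hint":
            d["on"] = bool(self.payload["on"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionEvent":
        payload = {}
        if d["kind"] == "move":
            payload = {
                "fragment_id": d["fragment_id"],
                "transform": RigidTransform.from_dict(d["transform"]),
            }
        elif d["kind"] == "toggle_hint":
            payload = {"on": bool(d["on"])}
        return cls(timestamp=float(d["timestamp"]), kind=d["kind"], payload=payload)


@dataclass(frozen=True)
class SessionLog:
    """Ordered event sequence ending in exactly one finish event."""

    events: tuple

    def __post_init__(self):
        events = tuple(self.events)
        if not events:
            raise SessionError("session log is empty")
        times = [e.timestamp for e in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise SessionError("event timestamps must be non-decreasing")
        finishes = [i for i, e in enumerate(events) if e.kind == "finish"]
        if len(finishes) != 1 or finishes[0] != len(events) - 1:
            raise SessionError("log must contain exactly one finish event, last")
        object.__setattr__(self, "events", events)


def summarize_session(log: SessionLog) -> dict:
    """Session penalties from the event log.

    Time runs from the first logged event to the finish event; checks are
    counted individually; the template counts as used if any hint toggle
    switched it on at any time, however briefly (the penalty models use,
    not duration).  ``rho`` comes from the geometry, not the log, so the
    caller combines this summary with it to build :class:`ScoreInputs`.
    """
    events = log.events
    t = events[-1].timestamp - events[0].timestamp
    n_c = sum(1 for e in events if e.kind == "check")
    template_used = any(
        e.kind == "toggle_hint" and bool(e.payload.get("on")) for e in events
    )
    return {"t": float(t), "n_c": int(n_c), "template_used": template_used}


def replay_session(state, log: SessionLog):
    """Apply every move event of a log to a fracture state, in order."""
    from .fracture import apply_move

    for event in log.events:
        if event.kind == "move":
            state = apply_move(
                state, event.payload["fragment_id"], event.payload["transform"]
            )
    return state


@dataclass(frozen=True)
class ScoreBreakdown:
    """The final report: inputs, score, metric vector and sub-scores."""

    inputs: ScoreInputs
    score: float
    metric_vector: MetricVector
    subscores: dict
    scoring_config: ScoringConfig
    rho_config: RhoConfig

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs.to_dict(),
            "score": self.score,
            "metrics": self.metric_vector.as_dict(),
            "metric_rows": self.metric_vector.report_rows(),
            "subscores": dict(self.subscores),
            "scoring_config": self.scoring_config.to_dict(),
            "rho_config": self.rho_config.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreBreakdown":
        return cls(
            inputs=ScoreInputs.from_dict(d["inputs"]),
            score=float(d["score"]),
            metric_vector=MetricVector.from_dict(d["metrics"]),
            subscores={k: float(v) for k, v in d["subscores"].items()},
            scoring_config=ScoringConfig.from_dict(d["scoring_config"]),
            rho_config=RhoConfig.from_dict(d["rho_config"]),
        )

    def to_text(self) -> str:
        """Human-readable session report."""
        lines = ["Reduction session report", "=" * 24, ""]
        lines.append(f"Final score:          {self.score:.2f}")
        lines.append(f"Reduction accuracy:   rho = {self.inputs.rho:.4f}")
        lines.append(f"Time elapsed:         {self.inputs.t:.1f} s")
        lines.append(f"Reduction checks:     {self.inputs.n_c:g}")
        lines.append(
            f"Template used:        {'yes' if self.inputs.template_used else 'no'}"
        )
        lines.append("")
        lines.append(f"{'Metric':34s}{'Unit':10s}{'Value':>10s}{'Score':>8s}")
        lines.append("-" * 62)
        for name, row in zip(self.metric_vector.as_dict(), self.metric_vector.report_rows()):
            lines.append(
                f"{row['metric']:34s}{row['unit']:10s}"
                f"{row['value']:10.3f}{self.subscores[name]:8.3f}"
            )
        return "\n".join(lines) + "\n"


def final_report(
    state,
    template,
    log: SessionLog,
    cfg: ScoringConfig | None = None,
    rho_cfg: RhoConfig | None = None,
) -> ScoreBreakdown:
    """Grade a finished session.

    Detects landmarks on the reassembled bone (fragments under their current
    transforms), registers the mirrored contralateral template, computes the
    metric vector and rho, combines them with the session penalties and
    evaluates the score formula.
    """
    from .landmarks import detect_landmarks

    cfg = cfg or ScoringConfig()
    rho_cfg = rho_cfg or RhoConfig()
    reduced = detect_landmarks(state.reassembled_mesh())
    mv = compute_metric_vector(reduced, template)
    rho = compute_rho(mv, rho_cfg)
    summary = summarize_session(log)
    inputs = ScoreInputs(
        rho=rho,
        t=summary["t"],
        n_c=summary["n_c"],
        template_used=summary["template_used"],
    )
    return ScoreBreakdown(
        inputs=inputs,
        score=compute_score(inputs, cfg),
        metric_vector=mv,
        subscores=rho_subscores(mv, rho_cfg),
        scoring_config=cfg,
        rho_config=rho_cfg,
    )
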