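"""Quality control of tracked clips.

A clip passes QC when all three conditions hold:

* at least two of the three pleural landmarks followed a plausible
  trajectory,
* the soft-tissue landmark trajectory is plausible, and
* at least 1 s of video remains for analysis after any trimming.

A first failure sends the clip to *redo* (re-track with fresh seeds); a
failure on the second attempt means *discard*. The original procedure
judged plausibility by visual review of the overlay video; here it is
operationalized with quantitative, config-exposed rules (inter-frame jump,
vertical drift, confidence floor, tracking loss) whose defaults are
reported in the QC output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tracking import PLEURAL_ROLES, SOFT_TISSUE, Trajectory

__all__ = [
    "PlausibilityRules",
    "QCVerdict",
    "trajectory_plausible",
    "clip_verdict",
    "trim",
    "MIN_ANALYZABLE_DURATION_S",
]

#: Minimum analyzable duration after trimming (inclusive bound).
MIN_ANALYZABLE_DURATION_S = 1.0


@dataclass(frozen=True)
class PlausibilityRules:
    """Quantitative stand-in for visual trajectory review.

    ``max_jump_px_per_frame``: largest credible inter-frame step; a tracked
    pleural point moving faster teleported to a different structure.
    ``max_vertical_drift_px``: the pleura is quasi-horizontal, so large
    net vertical drift signals the tracker slid off the band.
    ``min_confidence``: tracker score floor; violated when more than 10%
    of frames fall below it.
    ``require_no_loss``: any tracking loss is implausible by default.
    """

    max_jump_px_per_frame: float = 20.0
    max_vertical_drift_px: float = 40.0
    min_confidence: float = 0.3
    require_no_loss: bool = True

    def validate(self) -> None:
        if self.max_jump_px_per_frame <= 0:
            raise ValueError("max_jump_px_per_frame must be > 0")
        if self.max_vertical_drift_px <= 0:
            raise ValueError("max_vertical_drift_px must be > 0")
        if self.min_confidence <= 0:
            raise ValueError("min_confidence must be > 0")


@dataclass(frozen=True)
class QCVerdict:
    """Outcome of the post-hoc quality check for one clip attempt."""

    status: str  # pass | redo | discard
    plausible_pleural_count: int
    st_plausible: bool
    analyzable_duration_s: float
    attempt: int = 1
    reasons: tuple[str, ...] = ()


def trajectory_plausible(
    traj: Trajectory, rules: PlausibilityRules | None = None
) -> tuple[bool, list[str]]:
    """Check one trajectory against the plausibility rules.

    Returns (plausible, reasons); ``reasons`` lists every violated rule id
    among ``jump``, ``vertical_drift``, ``low_confidence``, ``lost``.
    """
    rules = rules or PlausibilityRules()
    rules.validate()
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    reasons: list[str] = []

    ok = ~(np.isnan(traj.x_px) | np.isnan(traj.y_px))
    x, y = traj.x_px[ok], traj.y_px[ok]
    if x.size >= 2:
        steps = np.hypot(np.diff(x), np.diff(y))
        if steps.max() > rules.max_jump_px_per_frame:
            reasons.append("jump")
        if np.max(np.abs(y - y[0])) > rules.max_vertical_drift_px:
            reasons.append("vertical_drift")
    conf = traj.confidence[~np.isnan(traj.confidence)]
    if conf.size and np.mean(conf < rules.min_confidence) > 0.10:
        reasons.append("low_confidence")
    if rules.require_no_loss and traj.lost_from is not None:
        reasons.append("lost")
    return (not reasons), reasons


def clip_verdict(
    trajectories: Sequence[Trajectory],
    rules: PlausibilityRules | None = None,
    trimmed_duration_s: float = 0.0,
    attempt: int = 1,
) -> QCVerdict:
    """Combine per-landmark plausibility into the clip verdict.

    Pass requires >= 2 plausible pleural landmarks AND a plausible
    soft-tissue landmark AND >= 1 s of analyzable video. Otherwise the
    verdict is redo on the first attempt and discard on any later attempt.
    """
    rules = rules or PlausibilityRules()
    by_role = {t.role: t for t in trajectories}
    if set(by_role) != set(PLEURAL_ROLES) | {SOFT_TISSUE} or len(trajectories) != 4:
        raise ValueError(
            "clip_verdict needs exactly the three pleural trajectories plus one soft-tissue trajectory"
        )
    if attempt < 1:
        raise ValueError("attempt is 1-based")

    reasons: list[str] = []
    pleural_ok = 0
    for role in PLEURAL_ROLES:
        ok, why = trajectory_plausible(by_role[role], rules)
        pleural_ok += ok
        reasons.extend(f"{role}:{w}" for w in why)
    st_ok, st_why = trajectory_plausible(by_role[SOFT_TISSUE], rules)
    reasons.extend(f"{SOFT_TISSUE}:{w}" for w in st_why)

    if pleural_ok < 2:
        reasons.append("insufficient_plausible_pleural")
    if not st_ok:
        reasons.append("st_implausible")
    if trimmed_duration_s < MIN_ANALYZABLE_DURATION_S:
        reasons.append("duration_below_1s")

    passed = pleural_ok >= 2 and st_ok and trimmed_duration_s >= MIN_ANALYZABLE_DURATION_S
    status = "pass" if passed else ("redo" if attempt == 1 else "discard")
    return QCVerdict(
        status=status,
        plausible_pleural_count=pleural_ok,
        st_plausible=st_ok,
        analyzable_duration_s=float(trimmed_duration_s),
        attempt=attempt,
        reasons=tuple(reasons),
    )


def trim(
    frames: np.ndarray, t_start: float, t_end: float, fps: float
) -> tuple[np.ndarray, float]:
    """Keep the [t_start, t_end) segment of a clip.

    Returns the retained frames and their duration in seconds (frame count
    over fps), which feeds the >= 1 s rule in :func:`clip_verdict`.
    """
    frames = np.asarray(frames)
    if fps <= 0:
        raise ValueError("fps must be > 0")
    n = frames.shape[0]
    clip_duration = n / fps
    if not (0 <= t_start < t_end <= clip_duration + 1e-9):
        raise ValueError(
            f"need 0 <= t_start < t_end <= clip duration ({clip_duration:.3f} s)"
        )
    start = int(round(t_start * fps))
    stop = min(int(round(t_end * fps)), n)
    if stop - start < 2:
        raise ValueError("trimmed segment must keep at least 2 frames")
    return frames[start:stop], (stop - start) / fps
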