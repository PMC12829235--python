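"""Landmark tracking and pixel-to-millimetre calibration.

Three pleural landmarks (left, central, right) and one soft-tissue
landmark are seeded in frame 0 and tracked through the clip. Tracking is a
pluggable contract: any object with ``init(frame, center)`` and
``update(frame) -> (x, y, confidence) | None`` works. Two implementations
ship:

* :class:`NCCTracker` — the reference tracker: normalized cross-correlation
  of the frame-0 template within a bounded search window, with 3-point
  parabolic sub-pixel peak refinement. Deterministic, dependency-light, the
  default for tests.
* :class:`CSRTTracker` — an adapter around OpenCV's discriminative
  correlation filter tracker (``TrackerCSRT``), available when ``cv2`` is
  importable.

Coordinate convention (documented in every CSV header): pixel origin
top-left, x rightward (the transversal plane along which lung sliding is
measured), y downward (vertical), 0-based frame indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from skimage.feature import match_template

__all__ = [
    "PLEURAL_LEFT",
    "PLEURAL_CENTRAL",
    "PLEURAL_RIGHT",
    "SOFT_TISSUE",
    "PLEURAL_ROLES",
    "LandmarkSeed",
    "Trajectory",
    "RulerCalibration",
    "TrackerConfig",
    "NCCTracker",
    "CSRTTracker",
    "make_tracker",
    "track_landmarks",
    "calibrate",
    "to_motion_curve",
]

PLEURAL_LEFT = "pleural_left"
PLEURAL_CENTRAL = "pleural_central"
PLEURAL_RIGHT = "pleural_right"
SOFT_TISSUE = "soft_tissue"
#: Tie-break / reporting order for pleural landmarks.
PLEURAL_ROLES = (PLEURAL_LEFT, PLEURAL_CENTRAL, PLEURAL_RIGHT)
ROLES = PLEURAL_ROLES + (SOFT_TISSUE,)


@dataclass(frozen=True)
class LandmarkSeed:
    """Seed position and template window for one landmark in frame 0."""

    role: str
    x_px: float
    y_px: float
    roi_halfwidth_px: int = 15
    roi_halfheight_px: int = 15

    def validate(self, height: int, width: int) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown landmark role {self.role!r}")
        if self.roi_halfwidth_px < 1 or self.roi_halfheight_px < 1:
            raise ValueError("ROI half-sizes must be >= 1 px")
        x0 = int(round(self.x_px)) - self.roi_halfwidth_px
        x1 = int(round(self.x_px)) + self.roi_halfwidth_px
        y0 = int(round(self.y_px)) - self.roi_halfheight_px
        y1 = int(round(self.y_px)) + self.roi_halfheight_px
        if x0 < 0 or y0 < 0 or x1 >= width or y1 >= height:
            raise ValueError(
                f"seed ROI for {self.role} ({x0}:{x1}, {y0}:{y1}) "
                f"falls outside the {width}x{height} frame"
            )


@dataclass
class Trajectory:
    """Per-frame tracked center of one landmark.

    ``lost_from`` is the first frame index at which the tracker failed
    (confidence collapse); positions at and after that index are NaN. A
    fully tracked clip has ``lost_from = None``.
    """

    role: str
    t: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    confidence: np.ndarray
    lost_from: int | None = None

    @property
    def n_valid(self) -> int:
        return self.t.size if self.lost_from is None else self.lost_from

    def to_frame(self, clip_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clip_id": clip_id,
                "frame": np.arange(self.t.size),
                "t_s": self.t,
                "role": self.role,
                "x_px": self.x_px,
                "y_px": self.y_px,
                "confidence": self.confidence,
            }
        )


@dataclass(frozen=True)
class RulerCalibration:
    """Two-point ruler calibration giving an isotropic pixel scale."""

    point_a_px: tuple[float, float]
    point_b_px: tuple[float, float]
    known_mm: float
    px_per_mm: float


def calibrate(
    point_a_px: Sequence[float], point_b_px: Sequence[float], known_mm: float
) -> RulerCalibration:
    """Derive px/mm from two ruler points a known distance apart."""
    if known_mm <= 0:
        raise ValueError("known_mm must be > 0")
    ax, ay = float(point_a_px[0]), float(point_a_px[1])
    bx, by = float(point_b_px[0]), float(point_b_px[1])
    dist = math.hypot(bx - ax, by - ay)
    if dist == 0:
        raise ValueError("ruler points must be distinct")
    return RulerCalibration((ax, ay), (bx, by), known_mm, dist / known_mm)


@dataclass(frozen=True)
class TrackerConfig:
    """Reference-tracker knobs.

    ``search_radius_px`` bounds the per-frame displacement the tracker can
    follow; ``lost_threshold`` is the correlation below which tracking is
    declared lost.
    """

    search_radius_px: int = 20
    lost_threshold: float = 0.2


class Tracker(Protocol):  # pragma: no cover - typing contract
    def init(self, frame: np.ndarray, center: tuple[float, float]) -> None: ...

    def update(self, frame: np.ndarray) -> tuple[float, float, float] | None: ...


class NCCTracker:
    """Frame-0 template matcher with bounded search and sub-pixel peak.

    The template is fixed at initialization (no model drift), matching the
    way a point landmark is followed on a quasi-stationary pleural band.
    Sub-pixel refinement fits a parabola through the correlation peak and
    its axial neighbours; it is skipped when the peak is numerically
    perfect (1 - peak < 1e-4), where the quadratic is degenerate and
    refinement would inject spurious offsets on noise-free clips.
    """

    def __init__(
        self,
        roi_halfwidth_px: int = 15,
        roi_halfheight_px: int = 15,
        config: TrackerConfig | None = None,
    ):
        self.hw = int(roi_halfwidth_px)
        self.hh = int(roi_halfheight_px)
        self.config = config or TrackerConfig()
        self.template: np.ndarray | None = None
        self.center: tuple[float, float] | None = None

    def init(self, frame: np.ndarray, center: tuple[float, float]) -> None:
        cx, cy = int(round(center[0])), int(round(center[1]))
        y0, y1 = cy - self.hh, cy + self.hh + 1
        x0, x1 = cx - self.hw, cx + self.hw + 1
        if x0 < 0 or y0 < 0 or x1 > frame.shape[1] or y1 > frame.shape[0]:
            raise ValueError("seed ROI out of frame bounds")
        self.template = frame[y0:y1, x0:x1].astype(float)
        self.center = (float(center[0]), float(center[1]))

    @staticmethod
    def _parabolic(cm: float, c0: float, cp: float) -> float:
        denom = cm - 2.0 * c0 + cp
        if denom >= 0:  # not a local max along this axis
            return 0.0
        offset = 0.5 * (cm - cp) / denom
        return float(np.clip(offset, -0.5, 0.5))

    def update(self, frame: np.ndarray) -> tuple[float, float, float] | None:
        assert self.template is not None and self.center is not None
        h, w = frame.shape
        r = self.config.search_radius_px
        cx, cy = int(round(self.center[0])), int(round(self.center[1]))
        x0 = max(cx - self.hw - r, 0)
        x1 = min(cx + self.hw + r + 1, w)
        y0 = max(cy - self.hh - r, 0)
        y1 = min(cy + self.hh + r + 1, h)
        search = frame[y0:y1, x0:x1].astype(float)
        if search.shape[0] < self.template.shape[0] or search.shape[1] < self.template.shape[1]:
            return None
        corr = match_template(search, self.template)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        peak = float(corr[iy, ix])
        if peak < self.config.lost_threshold:
            return None
        dx = dy = 0.0
        if 1.0 - peak > 1e-4:
            if 0 < ix < corr.shape[1] - 1:
                dx = self._parabolic(corr[iy, ix - 1], peak, corr[iy, ix + 1])
            if 0 < iy < corr.shape[0] - 1:
                dy = self._parabolic(corr[iy - 1, ix], peak, corr[iy + 1, ix])
        new_x = x0 + ix + dx + self.hw
        new_y = y0 + iy + dy + self.hh
        self.center = (new_x, new_y)
        return new_x, new_y, float(np.clip(peak, 0.0, 1.0))


class CSRTTracker:
    """Adapter for OpenCV's CSRT discriminative-correlation-filter tracker.

    Requires ``cv2`` (opencv-python / opencv-contrib-python). CSRT reports
    no per-frame score, so confidence is 1.0 while tracking succeeds.
    """

    def __init__(
        self,
        roi_halfwidth_px: int = 15,
        roi_halfheight_px: int = 15,
        config: TrackerConfig | None = None,
    ):
        try:
            import cv2  # noqa: F401
        except ImportError as exc:  # pragma: no cover - env without cv2
            raise ImportError(
                "CSRT tracking requires OpenCV (pip install opencv-contrib-python); "
                "use tracker='ncc' for the built-in reference tracker"
            ) from exc
        self._cv2 = __import__("cv2")
        self.hw = int(roi_halfwidth_px)
        self.hh = int(roi_halfheight_px)
        self._tracker = None

    def _make(self):  # pragma: no cover - exercised only with cv2 present
        cv2 = self._cv2
        if hasattr(cv2, "TrackerCSRT_create"):
            return cv2.TrackerCSRT_create()
        return cv2.TrackerCSRT.create()

    def init(self, frame: np.ndarray, center: tuple[float, float]) -> None:  # pragma: no cover
        cx, cy = center
        bbox = (int(round(cx)) - self.hw, int(round(cy)) - self.hh, 2 * self.hw + 1, 2 * self.hh + 1)
        self._tracker = self._make()
        self._tracker.init(self._to_bgr(frame), bbox)

    def _to_bgr(self, frame: np.ndarray) -> np.ndarray:  # pragma: no cover
        if frame.ndim == 2:
            return np.repeat(frame[:, :, None], 3, axis=2)
        return frame

    def update(self, frame: np.ndarray):  # pragma: no cover
        ok, bbox = self._tracker.update(self._to_bgr(frame))
        if not ok:
            return None
        x, y, bw, bh = bbox
        return x + bw / 2.0, y + bh / 2.0, 1.0


_TRACKERS = {"ncc": NCCTracker, "csrt": CSRTTracker}


def make_tracker(name: str, seed: LandmarkSeed, config: TrackerConfig | None = None):
    """Instantiate a tracker by name (``"ncc"`` or ``"csrt"``)."""
    try:
        cls = _TRACKERS[name]
    except KeyError:
        raise ValueError(f"unknown tracker {name!r}; choose from {sorted(_TRACKERS)}")
    return cls(seed.roi_halfwidth_px, seed.roi_halfheight_px, config)


def track_landmarks(
    frames: np.ndarray,
    seeds: Sequence[LandmarkSeed],
    tracker: str = "ncc",
    config: TrackerConfig | None = None,
    fps: float = 20.0,
) -> list[Trajectory]:
    """Track every seeded landmark through the frame stack.

    Frame 0 positions equal the seeds by definition. A tracker failure
    mid-clip sets ``Trajectory.lost_from``; no exception is raised so the
    QC layer can decide the clip's fate.
    """
    frames = np.asarray(frames)
    if frames.ndim == 4:  # colour stack: collapse to luminance
        frames = frames.mean(axis=3)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames >= 2, height, width) frame stack")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    n, h, w = frames.shape
    roles = [s.role for s in seeds]
    if len(set(roles)) != len(roles):
        raise ValueError("landmark roles must be distinct")
    for s in seeds:
        s.validate(h, w)
    if sum(r == SOFT_TISSUE for r in roles) > 1:
        raise ValueError("at most one soft_tissue seed per clip")

    t = np.arange(n, dtype=float) / fps
    out: list[Trajectory] = []
    for seed in seeds:
        trk = make_tracker(tracker, seed, config)
        trk.init(frames[0], (seed.x_px, seed.y_px))
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        conf = np.full(n, np.nan)
        x[0], y[0], conf[0] = seed.x_px, seed.y_px, 1.0
        lost_from: int | None = None
        for i in range(1, n):
            res = trk.update(frames[i])
            if res is None:
                lost_from = i
                break
            x[i], y[i], conf[i] = res
        out.append(
            Trajectory(
                role=seed.role, t=t, x_px=x, y_px=y, confidence=conf, lost_from=lost_from
            )
        )
    return out


def to_motion_curve(traj: Trajectory, cal: RulerCalibration):
    """Convert a pixel trajectory to a calibrated raw motion curve.

    Only the transversal (x) axis enters the movement statistic; the
    vertical axis is carried as auxiliary data. Frames at and after
    ``lost_from`` stay missing (NaN).
    """
    from .signal import MotionCurve  # local import to avoid a cycle

    if traj.n_valid < 1 or np.isnan(traj.x_px[0]):
        raise ValueError("trajectory lost at frame 0; no curve can be derived")
    return MotionCurve(
        role=traj.role,
        t=traj.t.copy(),
        x_mm=traj.x_px / cal.px_per_mm,
        y_mm=traj.y_px / cal.px_per_mm,
        stage="raw",
    )
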