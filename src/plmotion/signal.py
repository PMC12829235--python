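"""Motion-curve conditioning and the per-clip pleural movement statistic.

The processing pipeline is a fixed stage machine:

    raw -> smoothed -> rezeroed -> st_corrected -> excursion

1. **smooth**: running median, window 5, to suppress tracker jitter.
2. **rezero**: subtract the first sample so all landmarks share a common
   starting reference.
3. **soft-tissue correction**: if a pleural curve's Pearson correlation
   with the soft-tissue curve is >= 0.5, the soft-tissue displacement is
   subtracted point-by-point (removing probe/chest-wall common-mode
   motion); otherwise the curve passes through unchanged. The gate is
   one-sided: strong anti-correlation does not trigger subtraction.
4. **excursion**: max minus min of the corrected transversal curve; the
   clip statistic is the largest excursion among the pleural landmarks
   (ties broken left, central, right).

The soft-tissue curve is smoothed and rezeroed with the same parameters
before use, so the subtraction compares like-processed series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tracking import PLEURAL_ROLES

__all__ = [
    "STAGES",
    "MotionCurve",
    "ClipResult",
    "ConstantSeriesError",
    "smooth_median",
    "rezero",
    "pearson",
    "st_correct",
    "max_excursion",
    "clip_pl_movement",
    "process_clip_curves",
]

STAGES = ("raw", "smoothed", "rezeroed", "st_corrected")


class ConstantSeriesError(ValueError):
    """Pearson correlation is undefined for a constant series."""


@dataclass
class MotionCurve:
    """Calibrated transversal displacement (mm) over time for one landmark."""

    role: str
    t: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray | None = None
    stage: str = "raw"
    st_corr_r: float | None = None
    corrected: bool | None = None

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.x_mm)

    def _require_stage(self, expected: str, op: str) -> None:
        if self.stage != expected:
            raise ValueError(
                f"{op} requires a {expected!r} curve, got {self.stage!r} "
                f"(pipeline order is {' -> '.join(STAGES)})"
            )


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running median with symmetrically shrinking edge windows.

    At index i the half-window is min(w//2, i, n-1-i), so the first and
    last samples are their own medians and the output length equals the
    input length. Missing (NaN) samples stay missing; valid samples near a
    gap use the available neighbours.
    """
    n = x.size
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        if np.isnan(x[i]):
            continue
        k = min(half, i, n - 1 - i)
        out[i] = np.nanmedian(x[i - k : i + k + 1])
    return out


def smooth_median(curve: MotionCurve, window: int = 5) -> MotionCurve:
    """Running-median smoothing (default window 5 data points)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    curve._require_stage("raw", "smooth_median")
    if not curve.valid.any():
        raise ValueError("curve has no valid samples")
    return replace(curve, x_mm=_running_median(curve.x_mm, window), stage="smoothed")


def rezero(curve: MotionCurve) -> MotionCurve:
    """Redefine the zero point: subtract the first valid sample.

    Idempotent: re-zeroing an already rezeroed curve is a no-op.
    """
    if curve.stage not in ("smoothed", "rezeroed"):
        curve._require_stage("smoothed", "rezero")
    first = curve.x_mm[curve.valid.argmax()] if curve.valid.any() else np.nan
    if np.isnan(first):
        raise ValueError("curve has no valid samples")
    return replace(curve, x_mm=curve.x_mm - first, stage="rezeroed")


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation with pairwise NaN removal."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need >= 3 paired valid samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    return float(sps.pearsonr(a, b).statistic)


def st_correct(
    pl: MotionCurve, st: MotionCurve, threshold: float = 0.5
) -> MotionCurve:
    """Gate-and-subtract soft-tissue motion from a pleural curve.

    If ``pearson(pl, st) >= threshold`` (inclusive, per the 0.5 rule) the
    soft-tissue displacement is subtracted at each time point and
    ``corrected`` is True; otherwise the curve is returned unchanged with
    ``corrected`` False. An undefined correlation (either curve constant)
    also means no correction, with ``st_corr_r`` left as NaN.
    """
    pl._require_stage("rezeroed", "st_correct")
    st._require_stage("rezeroed", "st_correct")
    if pl.t.size != st.t.size or not np.allclose(pl.t, st.t):
        raise ValueError("pleural and soft-tissue curves must share a time base")
    try:
        r = pearson(pl.x_mm, st.x_mm)
    except ConstantSeriesError:
        r = float("nan")
    if not np.isnan(r) and r >= threshold:
        return replace(
            pl, x_mm=pl.x_mm - st.x_mm, stage="st_corrected", st_corr_r=r, corrected=True
        )
    return replace(pl, stage="st_corrected", st_corr_r=r, corrected=False)


def max_excursion(curve: MotionCurve) -> float:
    """Greatest left-to-right excursion: max - min over valid samples."""
    curve._require_stage("st_corrected", "max_excursion")
    x = curve.x_mm[curve.valid]
    if x.size == 0:
        raise ValueError("curve has no valid samples")
    return float(x.max() - x.min())


def clip_pl_movement(excursions: Mapping[str, float]) -> tuple[float, str]:
    """Clip statistic: the highest excursion among passing pleural landmarks.

    ``excursions`` maps pleural role -> excursion (mm) for the landmarks
    that passed QC plausibility. Ties break in role order left, central,
    right. Raises if no landmark survived (the QC discard path).
    """
    candidates = [(role, excursions[role]) for role in PLEURAL_ROLES if role in excursions]
    if not candidates:
        raise ValueError(
            "no pleural landmark passed QC; clip must go through the redo/discard path"
        )
    best_role, best = candidates[0]
    for role, val in candidates[1:]:
        if val > best:
            best_role, best = role, val
    return float(best), best_role


@dataclass
class ClipResult:
    """Per-clip outcome: corrected curves, excursions, the PL movement
    statistic and the QC verdict. ``pl_movement_mm`` is None for clips that
    did not pass QC."""

    clip_id: str
    curves: dict[str, MotionCurve] = field(default_factory=dict)
    st_corr_r: dict[str, float] = field(default_factory=dict)
    excursion_mm: dict[str, float] = field(default_factory=dict)
    pl_movement_mm: float | None = None
    representative_landmark: str | None = None
    qc: "object | None" = None  # QCVerdict; kept loose to avoid a module cycle

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role in PLEURAL_ROLES:
            if role not in self.curves and role not in self.excursion_mm:
                continue
            curve = self.curves.get(role)
            rows.append(
                {
                    "clip_id": self.clip_id,
                    "role": role,
                    "st_corr_r": self.st_corr_r.get(role, np.nan),
                    "corrected": curve.corrected if curve is not None else None,
                    "excursion_mm": self.excursion_mm.get(role, np.nan),
                    "pl_movement_mm": self.pl_movement_mm,
                    "representative_landmark": self.representative_landmark,
                }
            )
        return pd.DataFrame(rows)


def process_clip_curves(
    pleural: Sequence[MotionCurve],
    soft_tissue: MotionCurve,
    window: int = 5,
    threshold: float = 0.5,
) -> tuple[dict[str, MotionCurve], MotionCurve]:
    """Run smooth -> rezero -> soft-tissue correction for a whole clip.

    The soft-tissue curve goes through the identical smoothing/rezeroing
    before it is used for correlation and subtraction. Returns the
    corrected pleural curves keyed by role plus the processed soft-tissue
    curve.
    """
    st = rezero(smooth_median(soft_tissue, window))
    out: dict[str, MotionCurve] = {}
    for curve in pleural:
        prepped = rezero(smooth_median(curve, window))
        out[curve.role] = st_correct(prepped, st, threshold)
    return out, st
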