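"""Synthetic lung-ultrasound clip and cohort simulation.

Generates grayscale video-like frame stacks that mimic the geometry a
motion-tracking pipeline sees on a linear-probe lung ultrasound clip:

* a bright, quasi-horizontal pleural band with speckle texture,
* a sub-pleural speckle field that translates laterally together with the
  band (the "lung sliding" signal),
* an independent soft-tissue speckle layer above the band,
* a probe-translation component added to *all* structures, and
* additive per-frame Gaussian noise.

Because every displacement is applied analytically, each clip carries an
exact :class:`GroundTruth` against which tracking, soft-tissue correction
and the per-clip excursion statistic can be verified.

The module also simulates clip-level cohort tables (pleural-line movement,
ordinal lung-sliding category drawn from a proportional-odds model, and a
quadratic overdistention response) so the downstream inference layer has a
parameter-recovery oracle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "Waveform",
    "SyntheticClipSpec",
    "GroundTruth",
    "CohortEffect",
    "SpecValidationError",
    "generate_clip",
    "default_seeds",
    "generate_cohort",
    "write_clip",
    "SLIDING_CATEGORIES",
]

#: Ordered lung-sliding categories used throughout the package.
SLIDING_CATEGORIES = ("absent", "doubtful", "moderate", "extensive")


class SpecValidationError(ValueError):
    """Raised when a synthetic clip spec violates an invariant.

    The message names the offending field.
    """

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class Waveform:
    """Lateral displacement waveform, evaluated in millimetres.

    Parameters
    ----------
    kind
        ``"sinusoid"``: ``A * sin(2*pi*f*t + phase)``.
        ``"hold"``: constant displacement ``A`` (a breath-hold / static
        structure when ``A = 0``).
        ``"ramp"``: linear drift from 0 to ``A`` over the clip duration.
        ``"samples"``: explicit per-frame displacement samples in mm.
    amplitude_mm
        Peak displacement ``A`` (ignored for ``"samples"``).
    frequency_hz
        Oscillation frequency (sinusoid only). Defaults to a quiet-breathing
        respiratory rate of 15 breaths/min.
    phase_rad
        Phase offset (sinusoid only).
    samples_mm
        Per-frame displacement values for ``kind="samples"``; its length
        must equal the clip's frame count.
    """

    kind: str = "sinusoid"
    amplitude_mm: float = 2.5
    frequency_hz: float = 0.25
    phase_rad: float = 0.0
    samples_mm: tuple[float, ...] | None = None

    def evaluate(self, t: np.ndarray, duration_s: float) -> np.ndarray:
        """Displacement in mm at each time in ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "sinusoid":
            return self.amplitude_mm * np.sin(
                2.0 * math.pi * self.frequency_hz * t + self.phase_rad
            )
        if self.kind == "hold":
            return np.full_like(t, self.amplitude_mm)
        if self.kind == "ramp":
            return self.amplitude_mm * t / duration_s
        if self.kind == "samples":
            if self.samples_mm is None or len(self.samples_mm) != t.size:
                raise SpecValidationError(
                    "samples_mm",
                    f"needs exactly {t.size} per-frame samples",
                )
            return np.asarray(self.samples_mm, dtype=float)
        raise SpecValidationError("kind", f"unknown waveform kind {self.kind!r}")


STATIC = Waveform(kind="hold", amplitude_mm=0.0)


@dataclass(frozen=True)
class SyntheticClipSpec:
    """Full parameterization of a simulated clip.

    Default geometry approximates a linear-probe chest view: ~25 mm wide
    field at 10 px/mm with the pleural line mid-image. Default noise
    (``noise_sigma = 5`` grey levels) and speckle grain (2 px) give a
    texture that correlation trackers handle but that is not trivially
    clean.
    """

    width_px: int = 256
    height_px: int = 192
    fps: float = 20.0
    duration_s: float = 3.0
    px_per_mm: float = 10.0
    pleura_depth_px: int = 96
    pleura_thickness_px: int = 6
    pleural_motion: Waveform = field(default_factory=lambda: Waveform())
    st_motion: Waveform = field(default_factory=lambda: STATIC)
    probe_motion: Waveform = field(default_factory=lambda: STATIC)
    noise_sigma: float = 5.0
    speckle_grain_px: float = 2.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def validate(self) -> None:
        if self.fps <= 0:
            raise SpecValidationError("fps", "must be > 0")
        if self.px_per_mm <= 0:
            raise SpecValidationError("px_per_mm", "must be > 0")
        if self.n_frames < 2:
            raise SpecValidationError(
                "duration_s", "duration_s * fps must give at least 2 frames"
            )
        if not (0 < self.pleura_depth_px < self.height_px):
            raise SpecValidationError(
                "pleura_depth_px", "pleural band must lie inside the image"
            )
        if self.pleura_thickness_px < 1:
            raise SpecValidationError("pleura_thickness_px", "must be >= 1")
        for name in ("pleural_motion", "st_motion", "probe_motion"):
            wf: Waveform = getattr(self, name)
            if wf.amplitude_mm < 0:
                raise SpecValidationError(name, "amplitude_mm must be >= 0")
        if self.noise_sigma < 0:
            raise SpecValidationError("noise_sigma", "must be >= 0")
        if self.speckle_grain_px <= 0:
            raise SpecValidationError("speckle_grain_px", "must be > 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticClipSpec":
        raw = json.loads(text)
        for key in ("pleural_motion", "st_motion", "probe_motion"):
            if key in raw and isinstance(raw[key], dict):
                wf = dict(raw[key])
                if wf.get("samples_mm") is not None:
                    wf["samples_mm"] = tuple(wf["samples_mm"])
                raw[key] = Waveform(**wf)
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic per-frame displacement truth for a synthetic clip.

    ``pleural_x_mm`` is the *intrinsic* pleural displacement (probe motion
    excluded): it is what the pipeline should recover after soft-tissue
    correction. The texture below the pleural band is shifted by
    ``probe_x_mm + pleural_x_mm``; the soft-tissue layer by
    ``probe_x_mm + st_x_mm``.
    """

    t: np.ndarray
    pleural_x_mm: np.ndarray
    st_x_mm: np.ndarray
    probe_x_mm: np.ndarray

    @property
    def true_excursion_mm(self) -> float:
        """Max minus min of the intrinsic pleural displacement."""
        return float(np.max(self.pleural_x_mm) - np.min(self.pleural_x_mm))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.t.size),
                "t_s": self.t,
                "pleural_x_mm": self.pleural_x_mm,
                "st_x_mm": self.st_x_mm,
                "probe_x_mm": self.probe_x_mm,
            }
        )


def _speckle(rng: np.random.Generator, shape: tuple[int, int], grain_px: float) -> np.ndarray:
    """Zero-mean, unit-variance low-pass speckle texture."""
    raw = rng.standard_normal(shape)
    smooth = gaussian_filter(raw, sigma=grain_px, mode="wrap")
    sd = smooth.std()
    if sd == 0:  # pragma: no cover - degenerate grain
        return smooth
    return smooth / sd


def _shift_columns(tex: np.ndarray, margin: int, width: int, shift_px: float) -> np.ndarray:
    """Sample ``width`` columns of ``tex`` displaced by ``shift_px``.

    A structure displaced to the right by ``s`` renders as
    ``frame(x) = tex(x - s)``; sub-pixel shifts use linear interpolation.
    """
    pos = np.arange(width, dtype=float) + margin - shift_px
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    return tex[:, i0] * (1.0 - frac) + tex[:, i0 + 1] * frac


def generate_clip(spec: SyntheticClipSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic clip and its analytic ground truth.

    Returns
    -------
    frames : uint8 ndarray, shape (n_frames, height_px, width_px)
    truth : GroundTruth
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    t = np.arange(n, dtype=float) / spec.fps

    pleural_mm = spec.pleural_motion.evaluate(t, spec.duration_s)
    st_mm = spec.st_motion.evaluate(t, spec.duration_s)
    probe_mm = spec.probe_motion.evaluate(t, spec.duration_s)

    lower_px = (probe_mm + pleural_mm) * spec.px_per_mm
    upper_px = (probe_mm + st_mm) * spec.px_per_mm
    margin = int(np.ceil(np.abs(np.concatenate([lower_px, upper_px])).max())) + 2

    h, w = spec.height_px, spec.width_px
    wtex = w + 2 * margin
    depth = spec.pleura_depth_px

    # Soft-tissue layer: mid-grey speckle above the pleural band.
    st_tex = np.clip(120.0 + 45.0 * _speckle(rng, (depth, wtex), spec.speckle_grain_px), 0, 255)

    # Pleural layer: darker sub-pleural speckle with the bright band drawn
    # in (>= 200 grey levels) at a small static vertical undulation, so the
    # band and the sub-pleural field translate together.
    lower_h = h - depth
    lower_tex = np.clip(
        60.0 + 35.0 * _speckle(rng, (lower_h, wtex), spec.speckle_grain_px), 0, 255
    )
    und = 2.0 * np.sin(2.0 * math.pi * np.arange(wtex) / 64.0)
    rows = np.arange(lower_h)[:, None]
    band = (rows >= und[None, :]) & (rows < und[None, :] + spec.pleura_thickness_px)
    band_tex = np.clip(
        230.0 + 20.0 * _speckle(rng, (lower_h, wtex), spec.speckle_grain_px), 200, 255
    )
    lower_tex = np.where(band, band_tex, lower_tex)

    frames = np.empty((n, h, w), dtype=np.uint8)
    for i in range(n):
        img = np.empty((h, w), dtype=float)
        img[:depth] = _shift_columns(st_tex, margin, w, upper_px[i])
        img[depth:] = _shift_columns(lower_tex, margin, w, lower_px[i])
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(t=t, pleural_x_mm=pleural_mm, st_x_mm=st_mm, probe_x_mm=probe_mm)
    return frames, truth


def write_clip(
    frames: np.ndarray,
    truth: GroundTruth,
    spec: SyntheticClipSpec,
    outdir: str | Path,
    video: bool = False,
) -> Path:
    """Write a clip as a PNG frame sequence plus sidecar metadata.

    Produces ``frame_0000.png``..., ``ground_truth.csv`` (columns frame,
    t_s, pleural_x_mm, st_x_mm, probe_x_mm), ``spec.json`` and
    ``meta.json`` (fps, frame count). With ``video=True`` an additional
    ``clip.mp4`` is attempted through imageio, which requires an
    ffmpeg-enabled plugin.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(outdir / f"frame_{i:04d}.png", frame)
    truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)
    (outdir / "spec.json").write_text(spec.to_json())
    (outdir / "meta.json").write_text(
        json.dumps({"fps": spec.fps, "n_frames": int(frames.shape[0])})
    )
    if video:
        iio.imwrite(outdir / "clip.mp4", frames, fps=spec.fps)
    return outdir


def default_seeds(spec: SyntheticClipSpec, roi_halfwidth_px: int = 15, roi_halfheight_px: int = 12):
    """Standard landmark layout for a synthetic clip.

    Pleural seeds sit at 1/4, 1/2 and 3/4 of the image width, centred just
    below the pleural band so the template window lies entirely within the
    moving pleural layer (as an operator seeding on the pleural line would
    place them); the soft-tissue seed sits mid-depth in the tissue layer.
    """
    from .tracking import (
        PLEURAL_CENTRAL,
        PLEURAL_LEFT,
        PLEURAL_RIGHT,
        SOFT_TISSUE,
        LandmarkSeed,
    )

    w = spec.width_px
    y_pl = spec.pleura_depth_px + roi_halfheight_px + 2
    y_st = spec.pleura_depth_px // 2
    return [
        LandmarkSeed(PLEURAL_LEFT, w // 4, y_pl, roi_halfwidth_px, roi_halfheight_px),
        LandmarkSeed(PLEURAL_CENTRAL, w // 2, y_pl, roi_halfwidth_px, roi_halfheight_px),
        LandmarkSeed(PLEURAL_RIGHT, 3 * w // 4, y_pl, roi_halfwidth_px, roi_halfheight_px),
        LandmarkSeed(SOFT_TISSUE, w // 2, y_st, roi_halfwidth_px, roi_halfheight_px),
    ]


# ---------------------------------------------------------------------------
# Cohort simulation for the inference layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortEffect:
    """Latent-effect descriptor for a simulated clip-level cohort.

    The ordinal lung-sliding label follows a proportional-odds model
    ``P(Y <= k | x) = logistic(c_k - slope * x)`` on pleural-line movement
    ``x`` (mm). The default slope ``ln(1.25)`` encodes 25% higher odds of a
    higher sliding category per mm of movement. ``pl_movement_mm`` is drawn
    from a gamma distribution (mean 8 mm, SD 5 mm), spanning the absent
    (~2-3 mm) to extensive (~15 mm) range seen clinically. The
    overdistention response is ``od = b0 + b1*x + b2*x^2 + eps`` with a
    Gaussian noise term; it is intentionally not clipped to [0, 100] so
    polynomial refits recover the generating coefficients without
    censoring bias.
    """

    slope_per_mm: float = math.log(1.25)
    cutpoints: tuple[float, ...] = (0.9, 1.6, 2.4)
    categories: tuple[str, ...] = SLIDING_CATEGORIES
    pl_gamma_shape: float = 2.56
    pl_gamma_scale: float = 3.125
    od_beta: tuple[float, float, float] = (70.0, -12.53, 0.73)
    od_noise_sd: float = 15.0

    def validate(self) -> None:
        cuts = np.asarray(self.cutpoints, dtype=float)
        if cuts.size < 1 or np.any(np.diff(cuts) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        if len(self.categories) != cuts.size + 1:
            raise ValueError("need len(cutpoints) + 1 category labels")


def generate_cohort(
    n_clips: int,
    effect: CohortEffect | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a clip-level cohort table.

    Returns a DataFrame with columns ``clip_id``, ``pl_movement_mm``,
    ``sliding_category`` (ordered categorical) and ``od_percent``.
    """
    effect = effect or CohortEffect()
    effect.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    x = rng.gamma(effect.pl_gamma_shape, effect.pl_gamma_scale, size=n_clips)
    cuts = np.asarray(effect.cutpoints, dtype=float)
    # P(Y <= k | x) stacked over cutpoints; the sampled category is the
    # count of cumulative probabilities below a uniform draw.
    from scipy.special import expit

    cdf = expit(cuts[None, :] - effect.slope_per_mm * x[:, None])
    u = rng.uniform(size=n_clips)
    y_idx = (u[:, None] > cdf).sum(axis=1)

    b0, b1, b2 = effect.od_beta
    od = b0 + b1 * x + b2 * x**2
    if effect.od_noise_sd > 0:
        od = od + rng.normal(0.0, effect.od_noise_sd, size=n_clips)

    cat = pd.Categorical.from_codes(
        y_idx, categories=list(effect.categories), ordered=True
    )
    return pd.DataFrame(
        {
            "clip_id": [f"clip_{i:05d}" for i in range(n_clips)],
            "pl_movement_mm": x,
            "sliding_category": cat,
            "od_percent": od,
        }
    )
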