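# Methods

## The measurement

Lung sliding is quantified per clip as the **maximum pleural-line (PL)
lateral movement**: for each of three manually seeded pleural landmarks
(left, central, right), the greatest left-to-right excursion of its
calibrated transversal displacement curve over the analyzed segment, after
smoothing, re-zeroing and soft-tissue correction; the clip statistic is the
largest of the three. Vertical motion is tracked and exported but excluded
from the statistic. The measurement assumes a fixed frame rate (timestamps
are `frame / fps`; variable-frame-rate sources are rejected), an isotropic
pixel scale from a two-point ruler, and landmarks that stay within the
field of view.

## Processing pipeline and its choices

The curve pipeline is a stage machine `raw → smoothed → rezeroed →
st_corrected`, enforced at run time so stages cannot be skipped or
reordered.

- **Running median, window 5 samples.** At the boundaries the window
  shrinks symmetrically (half-width `min(2, i, n−1−i)`), so the output has
  the input's length and the first/last samples pass through. Alternatives
  (padding, truncation) differ only in the outermost two samples;
  shrinking was chosen because it neither invents data nor drops frames.
  Median output is bounded by the input's min/max, so excursions are never
  inflated by smoothing.
- **Re-zeroing** subtracts the first valid sample, giving every landmark a
  common start at 0. Mean-centering was rejected: a shared *starting*
  reference, not a shared average, is what makes curves visually and
  numerically comparable from the first frame. The operation is idempotent.
- **Soft-tissue correction.** Pearson correlation between each pleural
  curve and the identically processed (smoothed + rezeroed) soft-tissue
  curve gates a point-by-point subtraction at `r ≥ 0.5` (inclusive). The
  gate is one-sided: strong anti-correlation does not trigger subtraction.
  An undefined correlation (constant series, e.g. a perfectly still
  soft-tissue landmark) means no correction, with the correlation recorded
  as missing. Correlation is computed on the smoothed, rezeroed curves so
  both inputs to the subtraction have identical filtering provenance.
- **Missing data.** Tracking loss marks frames missing (NaN); missing
  samples propagate through smoothing and correction, and the excursion
  uses valid samples only. The ≥ 1 s analyzable-duration rule is enforced
  separately by QC, never by silent interpolation.
- **Ties** between landmark excursions break in the order left, central,
  right (documented, arbitrary, and stable).

## Tracking

The reference tracker is normalized cross-correlation of the frame-0
template (default 31 × 31 px) within a ± 20 px/frame search window, with a
3-point parabolic sub-pixel refinement of the correlation peak in x and y.
Refinement is skipped when the peak is within 1e−4 of a perfect
correlation: there the quadratic through the peak is degenerate and
refinement would add spurious sub-pixel offsets to clips it tracks exactly.
The refinement offset is clamped to ± 0.5 px. A correlation below 0.2
declares the track lost; loss is recorded (`lost_from`), never repaired.
The template is never updated, which suits a quasi-periodic scene and
makes the tracker drift-free by construction; the cost is sensitivity to
appearance change, which the QC rules are there to catch.

CSRT (a discriminative-correlation-filter tracker with a spatial
reliability map) is available through the same `init`/`update` contract
when OpenCV is installed; it reports no per-frame score, so its confidence
is a constant 1 while tracking succeeds. Both trackers produce identical
output shapes, units and downstream behaviour.

On noise-free synthetic clips with integer-pixel motion the reference
tracker is exact; with the simulator's default noise and sub-pixel
sinusoids its error is ≲ 0.15 px, well under the 1 px design bound used in
the correction-residual tolerance (1.5 × 1 px).

## Quality control

A clip passes when (i) at least two of the three pleural trajectories are
plausible, (ii) the soft-tissue trajectory is plausible, and (iii) at
least 1 s of video remains after trimming. Any failure → *redo* on the
first attempt, *discard* on the second; discard is unreachable without a
prior redo. Plausibility in the original workflow was a human judgement on
the overlay video; here it is operationalized with quantitative,
config-exposed defaults chosen for a linear-probe chest view at
typical frame rates: inter-frame jump ≤ 20 px (a faster step implies the
tracker jumped structures), net vertical drift ≤ 40 px (the pleura is
quasi-horizontal), tracker confidence ≥ 0.3 on ≥ 90 % of frames, and no
tracking loss. Relaxing any threshold can only move verdicts toward pass.
Pre-analysis suitability screening is a caller-supplied checklist recorded
in the log, not hard-coded image criteria.

## Synthetic data

The simulator renders what the tracking problem actually sees, not
ultrasound physics. A scene is two speckle layers (low-pass-filtered
seeded Gaussian noise, correlation length 2 px, scaled to per-layer
brightness envelopes) split at the pleural depth: soft tissue above
(mid-grey), sub-pleural field below (darker) with a bright band
(≥ 200/255, thickness 6 px, small static sinusoidal undulation) drawn into
it so band and sub-pleural speckle translate together. Per frame, the
lower layer shifts laterally by `probe + pleural` motion and the upper by
`probe + soft-tissue` motion (waveforms in mm × scale; sub-pixel shifts by
linear interpolation of a wide static texture), then i.i.d. Gaussian noise
(SD 5 grey levels) is added from the same seeded generator. Ground truth
is the analytic waveform set; for a full-period sinusoid of amplitude A
the true excursion is exactly 2A, and it is invariant to probe and
soft-tissue settings.

Defaults encode a plausible study condition: 256 × 192 px at 10 px/mm,
20 fps, 3 s, pleural sinusoid of 2.5 mm amplitude at 0.25 Hz (a moderate
slide at a quiet-breathing rate); soft-tissue and probe motion default to
zero and are switched on per experiment (the probe-drift experiments use a
4 mm ramp, chosen so the common-mode component carries enough variance to
exceed the 0.5 correlation gate — weaker drifts are correctly left
uncorrected). No quantitative soft-tissue or probe amplitudes are
established for this measurement; these are assumptions. The
amplitude-recovery grid uses a wider 4 px/mm view so a 10 mm slide stays
in frame. Not emulated: attenuation, reverberation, A/B-lines, rib
shadows, cardiac lung-pulse motion, out-of-plane decorrelation, scan-line
geometry. Passing tests therefore demonstrate the pipeline's correctness
and noise robustness on translating speckle, not clinical performance on
real clips.

The cohort simulator draws PL movement from a gamma distribution (mean
8 mm, SD 5 mm, spanning the absent-to-extensive clinical range), samples
the ordinal sliding grade from the proportional-odds model with slope
ln 1.25 per mm and cutpoints (0.9, 1.6, 2.4) (chosen near the quartiles of
the movement distribution so all four grades are populated), and generates
the overdistention response as `70 − 12.53·x + 0.73·x²` plus Gaussian
noise (SD 15). The response is deliberately **not** clipped to [0, 100]:
censoring would bias the polynomial-recovery and AIC-selection checks;
the percentage-range invariant applies to real clinical tables. Because
the quadratic's vertex sits near the movement distribution's centre, the
synthetic movement–overdistention relation is non-monotone and its rank
correlation is near zero by symmetry — a property of this synthetic
design, not of the method.

## Inference layer

- **Proportional odds**: cumulative-logit model `P(Y ≤ k | x) =
  logistic(c_k − βx)` fitted by maximum likelihood (statsmodels
  `OrderedModel`, logit link, BFGS; cutpoint ordering enforced by its
  log-increment reparameterization). Non-convergence — including complete
  separation — is flagged on the fit and warned about; predictions from a
  non-converged fit are refused. In the two-category case the model
  reduces exactly to binary logistic regression (cross-checked in tests).
- **Classification**: predicted grade = probability argmax; confusion
  matrix rows are true grades, columns predicted; balanced accuracy is the
  unweighted mean per-class recall over grades present in the truth, with
  absent grades excluded under a warning. Both the per-grade recalls and
  the macro average are reported, since either may be the summary of
  interest.
- **Spearman**: Pearson correlation of mid-ranks (scipy), undefined for
  constant input.
- **Polynomial fits**: OLS on the Vandermonde design; `AIC = n·ln(RSS/n) +
  2k` with `k = degree + 2` (coefficients plus error variance). The
  Gaussian-likelihood constant is dropped, so only AIC *differences*
  between models fitted to the same observations are meaningful; `ΔAIC`
  refuses fits with differing n.

## Problem sizes and tolerances

Test and acceptance runs use 3 s, 60-frame clips (25 clips for the
amplitude grid), 50 cohort replicates of n = 5000 for ordinal recovery
and coverage, and 200 replicates of n = 300 for AIC selection — sizes at
which every check is stable across seeds while the full suite runs in
about a minute. Recovery tolerances: clip PL movement within 10 % of 2A
across the amplitude grid (observed ≤ ~1.3 %; the dominant bias is median-
filter attenuation of the sinusoid extrema, ~2 % of the excursion at 20 fps
and 0.5 Hz, partially offset by noise); corrected curves within 1.5 × the
1 px tracker bound of the true pleural motion; mean recovered odds ratio
within [1.20, 1.30] of the generating 1.25 with 95 % Wald coverage in
[90 %, 98 %].

## Known limitations

- Plausibility thresholds are stand-ins for expert visual review and have
  not been validated against human judgements.
- The NCC reference tracker has no appearance model; clips with strong
  gain drift or deformation favour the CSRT adapter.
- The simulator's translating-speckle model cannot probe failure modes
  caused by out-of-plane motion or acoustic artefacts.
- Cardiac lung-pulse motion is not filtered from the curves; clips where
  it dominates will report pulse excursion as PL movement.
- `analyze-clip` re-runs (redo) require caller-supplied fresh seeds; no
  automatic re-seeding strategy is provided.
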