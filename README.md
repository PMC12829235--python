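# plmotion

Quantification of **lung sliding** from lung-ultrasound video by motion
tracking of the pleural line.

On a linear-probe chest view the pleural line is the bright, quasi-horizontal
interface between chest wall and lung. Its respirophasic to-and-fro lateral
motion — lung sliding — is judged visually at the bedside (absent / doubtful /
moderate / extensive), a reading that is subjective and poorly reproducible.
`plmotion` replaces the eyeball with a number: it tracks three pleural
landmarks plus one soft-tissue landmark across the clip, converts pixel
trajectories to millimetres via a two-point ruler calibration, conditions the
curves, and reports the **maximum pleural-line lateral movement** of the clip.
It is aimed at researchers in respiratory critical care and ultrasound image
analysis who want a reproducible, scriptable version of this measurement plus
its downstream statistics.

## Method

For each clip (fixed frame rate, manual seed points):

1. **Track** the four landmarks. The default tracker is normalized
   cross-correlation (NCC) of the frame-0 template within a bounded search
   window with sub-pixel peak refinement; an adapter for OpenCV's CSRT
   discriminative-correlation-filter tracker plugs into the same contract.
2. **Calibrate**: `px_per_mm = ‖a − b‖ / d` from two ruler points a known
   `d` mm apart; only the transversal (x) axis enters the statistic.
3. **Condition** each motion–time curve `x(t)`: running median (window 5) →
   re-zero to the first sample → soft-tissue correction. If a pleural curve
   has Pearson `r ≥ 0.5` with the soft-tissue curve, the soft-tissue
   displacement is subtracted point-by-point, removing probe/chest-wall
   common-mode motion; otherwise the curve passes through unchanged.
4. **Summarize**: per-landmark excursion `max x(t) − min x(t)`; the clip's
   PL movement is the largest excursion among the pleural landmarks.
5. **Quality control**: a clip passes when ≥ 2 pleural trajectories and the
   soft-tissue trajectory are plausible and ≥ 1 s of video remains after
   trimming; a first failure triggers *redo*, a second *discard*.

The inference layer relates clip-level PL movement x to the ordinal sliding
grade Y via a proportional-odds model `P(Y ≤ k | x) = logistic(c_k − βx)`
(odds ratio `exp(β)` per mm, confusion matrix, balanced accuracy), and to a
continuous overdistention percentage via quadratic least squares with
AIC-based model comparison (`ΔAIC_i = AIC_i − min AIC` on a common dataset).

A synthetic clip simulator renders speckle-textured scenes — bright pleural
band, sub-pleural field, independent soft-tissue layer, additive probe motion
and noise — with analytic per-frame ground truth, so every stage of the
pipeline has an exact oracle.

## Worked example

```sh
plmotion simulate --out clip --seed 4
# wrote 60 frames to clip (true excursion 4.992 mm)

plmotion analyze-clip --video clip --seeds seeds.csv \
    --ruler 0,0,100,0,10 --out results
# QC pass; PL movement: 4.9893392415286115
```

The simulated clip slides its pleura sinusoidally with 2.5 mm amplitude, so
the true excursion is just under 2 × 2.5 = 5 mm (the default 3 s clip covers
three quarters of a breath); the pipeline recovers 4.989 mm, an error of
about 0.003 mm. `results/result.csv` shows the per-landmark detail:

```
# plmotion 0.1.0 config=fcc38c9a6f8c
clip_id,role,st_corr_r,corrected,excursion_mm,pl_movement_mm,representative_landmark
clip2,pleural_left,0.236835,False,4.988944,4.989339,pleural_right
clip2,pleural_central,0.236906,False,4.987769,4.989339,pleural_right
clip2,pleural_right,0.236823,False,4.989339,4.989339,pleural_right
```

Each pleural landmark's correlation with the soft-tissue curve stayed below
0.5 (`corrected,False` — there was no probe drift to remove), the three
excursions agree to ~1 µm-scale tracking noise, and the clip statistic is
the largest of the three. On a cohort table, `plmotion cohort-stats --table
cohort.csv --outcome sliding` prints the fitted odds ratio per mm, cutpoints,
confusion matrix and balanced accuracy; `--outcome od` prints Spearman's ρ,
the quadratic fit and ΔAIC against the linear model.

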