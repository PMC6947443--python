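# cervixsign

Antenatal prediction of **posterior extrauterine adhesions** (adhesions between
the posterior uterine wall and bowel, ovary, rectum or pelvic wall) in patients
with **placenta previa**, from a single angle measured on mid-sagittal
T2-weighted MRI. Such adhesions complicate exteriorisation of the uterus at
cesarean delivery, and no routine antenatal test for them exists; this package
implements a landmark-based measurement of the **cervical canal angle**, the
derived **horizontal cervix sign**, and the diagnostic-accuracy analysis used
to evaluate it. It is aimed at perinatal imaging researchers who have digitised
landmark coordinates (no image processing is performed here).

## The measurement and the statistic

On a mid-sagittal view, with points digitised by one or more raters:

- **line A** — the back line, fitted by total least squares (orthogonal
  regression) through ≥2 points on the broad of the maternal back, listed
  cranial → caudal;
- **line B** — the perpendicular to A at the internal os;
- **line C** — the cervical canal line, internal os → external os;
- **angle D** — the cervical canal angle: the signed angle between B and C in
  (−90°, 90°], 0° when the canal is perpendicular to the back, positive when
  the external os tilts toward the caudal end of the back line. The sign is
  anatomical (carried by the documented point ordering), so it is invariant to
  rotation, translation, scaling and image handedness.

Readings are taken in 5° protractor steps with a numeric ceiling
(7.5° → 10°, −7.5° → −5°); per-rater readings are averaged and re-quantised
(readings of 15° and 0° combine to 10°). A case is **horizontal-cervix-sign
positive** when the combined angle is ≤ 10° (an alternative ≤ 0° rule is a
config change). Cervix **version** (anteverted/retroverted) is classified
against the perpendicular to the anatomical conjugate (sacral promontory →
pubic symphysis) at the internal os.

The evaluation module computes 2×2 sensitivity/specificity/PPV/NPV, Fisher's
exact and Pearson chi-square association tests, Mann–Whitney group
comparisons, a ROC analysis over the quantised angle grid (trapezoidal AUC —
equal to the tie-corrected rank statistic — with the Youden-optimal cutoff and
a Hanley–McNeil 95% CI), OLS of angle on gestational age per stratum, and mean
angles by imaging-week window (≤26, 27–29, 30–32, ≥33 completed weeks).

Because no per-case data were published, a **synthetic cohort generator**
reproduces the reported population structure (96 cases, 21/96 adhesion
prevalence, angles declining ≈3.3°/week from 38.41° at 30.4 weeks in the
non-adhesion group, near-flat ≈5.95° angles under adhesions, two raters on a
5° protractor) and emits landmark geometries that measure back to their
generating readings exactly.

## Worked example

```sh
cervixsign simulate --n 96 --seed 42 --out-dir demo
cervixsign run --landmarks demo/landmarks.csv --labels demo/labels.csv \
               --out-dir demo/out --ga-max 32
```

prints (abridged):

```
== All cases (n=96, adhesions=24) ==
  sign angle_le_10: sensitivity 79.2%, specificity 98.6%, PPV 0.95, NPV 0.93
  retroverted cervix: sensitivity 50.0%, specificity 98.6%, adhesion rate 92.3% vs 14.5% (anteverted)
  ROC: AUC 0.982 (95% CI 0.944-1.000), Youden-optimal threshold 15 deg
  non-adhesion angle vs GA: -2.66 deg/week (p=1.15e-07, n=72)
== Cases imaged at <= 32 weeks (n=57, adhesions=11) ==
  sign angle_le_10: sensitivity 90.9%, specificity 100.0%, PPV 1.00, NPV 0.98
```

Reading it: of the 96 simulated cases, the ≤10° rule caught 79.2% of the 24
adhesion cases while calling 98.6% of non-adhesion cases negative; the angle
separates the groups almost completely on this draw (AUC 0.982); and the
non-adhesion angle declines with gestational age (−2.66°/week here, a sample
estimate of the generator's −3.3°/week), which is why restricting to earlier
imaging (≤32 weeks) sharpens the sign. Full-precision numbers are in
`demo/out/report.json`, per-threshold operating points in
`demo/out/operating_points.csv`.

The same `run` command works on real data: a landmark CSV (one row per
case × rater: `case_id, rater_id, b1x, b1y, …, ios_x, ios_y, eos_x, eos_y[,
prom_x, prom_y, symph_x, symph_y]`, coordinates in mm) joined to a labels CSV
(`case_id, adhesion ∈ {0,1}, ga_weeks`).

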