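# Methods

## Measurement model

The cervical canal angle is defined on four constructs in the mid-sagittal
plane: the back line **A** (total least squares through ≥2 digitised back
points), its perpendicular **B** at the internal os, the canal line **C**
(internal → external os), and the signed angle **D** between B and C.

**Sign convention.** A protractor on a displayed image reads "clockwise", but
a coordinate file has no intrinsic handedness. We therefore define the sign
anatomically: the back-point listing order (cranial → caudal) orients line A, and
D is positive when C tilts toward the caudal end of A. Concretely, with caudal
unit vector `d`, perpendicular `n`, and canal vector `c`,
`D = atan2(c·d, |c·n|)` degrees, which lies in [−90°, 90°] and maps the
parallel-to-back case to +90° so the range is (−90°, 90°]. This reproduces the
reference configurations (canal ⊥ back = 0°; a canal tilted 10° cranially =
−10°) and makes D invariant under rotation, translation, uniform scaling *and
whole-image mirroring* — mirroring transforms the caudal axis along with the
canal. Flipping only the canal's tilt across line B (back line fixed) negates
D, which is the meaningful anti-symmetry and is what the test suite checks.

**Back line from >2 points.** Orthogonal regression (principal axis of the
2×2 scatter matrix), not ordinary regression: the back line is a geometric
axis, not a response function, and the fit must not depend on the coordinate
frame.

**Quantisation.** Readings are in 5° units with a numeric ceiling: the
smallest multiple of 5° that is ≥ the raw value (7.5° → 10°). Only a positive
example of the "increase" rule is documented, so the same numeric ceiling is
applied to negative values (−7.5° → −5°), keeping the map monotone and
idempotent. Raw values within 10⁻⁹ quanta of an exact multiple are snapped to
it, so angles reconstructed through floating-point arithmetic do not spill
into the next step. Two raters' quantised readings are averaged and the mean
re-quantised (15° and 0° → 7.5° → 10°), matching the documented worked
example of quantise → average → re-quantise.

**Version.** The anatomical conjugate (promontory → symphysis) defines line ①;
its perpendicular at the internal os (line ②) splits the pelvis. The external
os is the witness point — the canal endpoint farthest from the internal os —
and the cervix is anteverted when it lies strictly on the symphysis side,
retroverted on the opposite side, anteverted when exactly on line ② (fixed,
documented tie rule for a measure-zero event).

## Diagnostic evaluation

- **Sign rules** are inclusive thresholds (angle ≤ 10°, alternative ≤ 0°),
  configurable rather than hard-coded.
- **2×2 metrics** are the standard proportions; a metric with a zero
  denominator is reported as undefined (NaN/null), never as 0.
- **ROC** uses the unique observed (quantised) angles as the threshold grid
  plus ±∞ sentinels; AUC is trapezoidal, which on this grid equals the
  tie-corrected two-sample rank statistic (ties count ½) — the test suite
  verifies the identity exhaustively on small tied samples. The optimal
  cutoff maximises Youden's J = sensitivity + specificity − 1 (the standard
  criterion when none is stated), ties broken toward the larger threshold.
  The 95% CI uses the Hanley–McNeil normal approximation; DeLong would be a
  reasonable alternative and is not implemented.
- **Association tests**: Fisher's exact (two-sided, hypergeometric-mass
  ordering) and Pearson chi-square *without* Yates continuity correction;
  Fisher is the one to prefer when any expected cell is < 5. Mann–Whitney U
  uses exact enumeration over labelings (tie-aware via midranks) when the
  pooled sample has ≤ 12 observations, else the tie-corrected normal
  approximation.
- **Regression** is OLS of the combined angle on gestational age within a
  stratum, with the two-sided slope t-test; p-values are reported at full
  precision (displayed "p = 0.00" values are treated as display rounding).
- **GA windows** use completed weeks: group 1 = floor(GA) ≤ 26, group 2 =
  27–29, group 3 = 30–32, group 4 ≥ 33. This is the obstetric convention and
  keeps the windows consistent with "between 27 and 29 weeks"-style
  definitions; empty groups are reported missing, not zero.

## Synthetic cohort

The generator emulates the study population, per case:
Bernoulli(21/96) adhesion status; gestational age from a mixture of uniforms
over [22, 26.99], [27, 29.99], [30, 32.99], [33, 37] weeks with weights
10/26/29/31 (the reported imaging-week counts; only counts and an overall
30.4 ± 3.4 weeks are available, so uniform-within-window is the least
structured choice); latent angle 38.41° + (−3.3°/week)·(GA − 30.4) + N(0, 12²)
without adhesions, 5.95° + (0.19°/week)·(GA − 30.4) + N(0, 5²) with them,
clamped to [−30°, 90°] to exclude anatomically impossible tails; per-rater
N(0, 2.5²) reading error before the 5° ceiling; and per rater a landmark
geometry (collinear back points at a random pose, os pair, conjugate) whose
measured raw angle equals the reading to 10⁻⁹°.

**Noise scales are modelling choices.** The angle scatter at fixed GA, the
adhesion-group scatter ratio (12/2.4 = 5°) and the 2.5° rater sd are not
reported anywhere; they were fixed once to give a strong-but-imperfect
separation between strata and are all overridable in `CohortParams`.

**Calibration caveat.** The reported per-window mean angles
(64.4/42.8/36.4/28.4°) are *not* collinear with the reported slope/anchor
(−3.3°/week through 38.41° at 30.4 weeks): the linear model's closed-form
window means are 57.9/44.7/34.8/23.2°, so windows 1 and 4 deviate by ≈6.5°
and ≈5.2° from the printed values while the middle windows agree within 2°.
No parameter setting satisfies both sets of published numbers; the generator
follows the regression line, and tests validate sample means against the
model's own closed form.

**Version boundary.** The quantitative link between the version call and the
canal angle is not published; synthetic conjugates are placed so the call
flips at 10° of reading (a reading exactly at the boundary classifies
anteverted, realising the tie rule; implemented with a 10⁻⁴° inward offset so
the classification is deterministic rather than decided by floating-point
sign noise at sin 0).

**What passing tests show — and don't.** Round-trip and invariance tests
validate the geometry exactly; parameter-recovery tests validate the
statistical pipeline against the generator's own truth. None of this
validates the clinical claim on real MRI: real landmark error is not
isotropic Gaussian, real angle scatter at fixed GA is unknown, rater errors
are correlated in practice, and the generator encodes the published summary
structure rather than patient-level reality.

## Numerical choices and degenerate inputs

- Quantisation: ceiling with a 10⁻⁹-quantum snap window (documented above);
  monotone, idempotent, `raw ≤ q(raw) < raw + quantum` up to the snap window.
- Back-line orientation falls back to listing-order correlation if the first
  and last points coincide.
- Degenerate geometry (coincident os points, zero-length conjugate, internal
  os level with the symphysis) raises a dedicated error, annotated with case
  and rater identifiers when raised inside the per-case protocol.
- ROC requires both classes; regression requires ≥3 cases and non-degenerate
  GA variance; the pipeline reports such sections as missing with a warning
  instead of failing the whole run (an empty GA-limited subset likewise warns
  and skips).
- Reports are serialised with sorted keys and native float repr, so identical
  inputs yield byte-identical output.

## Problem sizes

The test suite and the acceptance script use a 96-case cohort for study-scale
checks and a 5000-case cohort for parameter recovery (slope within 3 SE,
adhesion-stratum mean within 0.5°); at n=5000 the slope's standard error is
≈0.06°/week. These sizes make sampling error small relative to the tested
tolerances while keeping a full run in seconds.

## Known limitations

- No image handling: landmarks must be digitised upstream.
- The AUC confidence interval method (Hanley–McNeil) is an assumption; the
  original interval's method is unknown, and bootstrap/DeLong may differ at
  n≈96.
- The synthetic version call is tied to the angle by construction, so
  version-based metrics on synthetic cohorts are optimistic relative to an
  independently read version.
- Multivariable adjustment, PAS-invasion covariates and survival-style
  analyses are out of scope.
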