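# Methods

## Problem and procedure

An automated eGFR is computed by laboratory software from the demographics
recorded at measurement time and stored with the result. Recomputing eGFR
later from the record as currently stored can disagree with the stored
value whenever DOB, gender, race, or the creatinine itself was overwritten
in the meantime (destructive replacement). The package implements the
comparison and an inverse-enumeration attribution of each disagreement:

1. **Screen.** Both values are stored at tenth precision; the screen rounds
   the *stored* values to whole numbers and flags unequal pairs. Rounding
   the stored (not the unrounded) values matters: it guarantees a pair that
   is identical as stored can never screen discordant, so the screen is
   conservative with respect to input-rounding noise.
2. **Enumerate.** The MDRD equation is evaluated over integer ages 18–120,
   both genders, black/non-black race, and Scr 0.10–30.0 mg/dL on a 0.01
   lattice (103 × 2 × 2 × 2991 = 1,232,292 combinations). Each value is
   rounded to the nearest tenth and indexed by that key. Rounded values
   span 1.0 (attained at age 120, Scr 30.0, female, non-black, raw 0.970)
   up to well above the 251.0 clip; combinations rounding outside
   [1.0, 251.0] are kept in a separate bucket by default (a strict mode
   drops them), so soundness checks can still locate them.
3. **Best match.** All combinations reproducing the automated value are
   compared with the current record on the four parameters; only those at
   the maximal match count m\* are kept (it is a priori unlikely that many
   parameters changed at once, so the most parsimonious explanation wins).
4. **Explain.** The parameter sets on which the kept candidates still
   disagree are the explanations. One distinct set is *definitive* ("Age",
   "Race", "Gender", "1 clinical" for Scr, "2 demographics", "1 demographic
   1 clinical"); several tied sets yield a disjunction in canonical
   race/gender/age order ("Race or age"). Ties between an Scr set and a
   pure demographic set produce "Scr or ..." labels; an optional
   `prefer-demographic` tie strategy suppresses the Scr branch, since
   classic explanation taxonomies carry no such mixed rows and plausibly
   resolved these ties in favour of demographics. If m\* = 4 the current
   record itself reproduces the automated value and the pair is labelled a
   match (rounding artifact, no drift); if no combination reproduces the
   value the pair is *unexplained* — possible only for automated values not
   generated by an on-grid MDRD evaluation.

## Agreement statistics

* **Bland–Altman**: differences are automated − retrospective; limits of
  agreement are mean ± 2 sample SD (n−1 denominator); the multiplier is
  configurable.
* **Stage agreement**: CKD bands 90+/60–89/45–59/30–44/15–29/<15 as
  half-open intervals [lower, upper) so boundary tenths (44.9, 60.0) are
  classified deterministically; this coincides with inclusive integer
  bounds on whole-number eGFR. Staging uses report-precision (tenth)
  values.
* **Cohen's κ**: unweighted, (p_o − p_e)/(1 − p_e) with expected agreement
  from marginal products; the SE is the large-sample Fleiss–Cohen form with
  a 95% normal CI; reported both raw and ×100. Degenerate marginals
  (p_e = 1) return an explicit undefined result rather than a crash. The
  point estimate is cross-checked against scikit-learn in the tests.

## Rounding and numerical choices

* Rounding is half-away-from-zero (commercial rounding, the behaviour of
  clinical reporting systems: 62.7 → 63, 58.9 → 59, 62.5 → 63); half-even
  is available as a policy switch.
* Three precisions are exposed rather than one: stored/report precision
  0.1, inversion (index key) precision 0.1, and screen precision 1.0. The
  index keys are integer-scaled tenths, never floats.
* Scr match tolerance in step 3 is half the Scr grid step, so an on-grid
  creatinine matches exactly one lattice point.
* Ages are completed years at the lab date (floor), matching the integer
  age grid.
* For definitive single-parameter Age/Scr explanations the reported
  absolute parameter difference is the smallest over the tied best
  candidates (the most conservative estimate of how large the change must
  have been).

## Synthetic cohort

The generator emulates a large VA-like primary-care cohort: 90% male, race
mix 76/18/1/1/4% white/black/asian/american-indian/other, age normal
(mean 55, SD 18) truncated to [18, 120], Scr log-normal with median
0.95 mg/dL and σ_log = 0.426 (giving mean ≈ 1.04, SD ≈ 0.47 mg/dL),
quantised to the 0.01 grid step so every true record lies on the
enumeration grid; lab dates are uniform over 2013. The automated value is
the tenth-rounded MDRD result of the "then" record. Drift models:
whole-year DOB shifts of 1–30 years (either sign, bounded to keep age on
grid), black↔non-black race flips, gender flips, and additive Scr shifts of
0.05–0.50 mg/dL in grid-step multiples. Drift is mutually exclusive per
patient by default (at most one parameter changes, mirroring the dominance
of single-parameter explanations in real drift); an independent mode
exercises multi-parameter cases. DOB shifts by whole years guarantee the
integer age changes by exactly the shift.

What passing tests show — and do not: on this generator every discordant
pair has an on-grid cause, so containment recovery is exact up to rounding
coincidences. Real cohorts add off-grid creatinines, unit errors,
transcription noise, and correlated record edits; results here validate the
algorithm's logic, not its field performance.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| screen precision | 1 mL/min/1.73 m² | conservative whole-number screen |
| report/inversion precision | 0.1 | storage convention for eGFR |
| Scr grid step | 0.01 mg/dL | typical laboratory reporting precision |
| age grid | 18–120 y | adult range |
| eGFR clip | 1.0–251.0 | attainable rounded range over the grid |
| LoA multiplier | 2 | mean ± 2 SD convention |
| drift total probability (study runs) | 0.3 | produces a ~30% discordance regime |

## Known limitations

* Attribution is defined for MDRD; the CKD-EPI equation is provided for
  calculation and comparison but no CKD-EPI inverse grid is claimed.
* No cystatin-C or pediatric equations; no body-surface-area de-indexing.
* The explanation taxonomy treats race as binary because the equation does;
  non-black race detail never affects any value.
* Problem sizes in the bundled analyses (10,000 patients; full 1.23 M-point
  grid) were chosen so a complete run takes seconds on one CPU while
  leaving hundreds to thousands of discordant pairs per stratum.
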