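# egfr-discordance

Tools for a data-provenance problem in EHR-based kidney research: a
laboratory system computes and stores an **automated eGFR** at the moment a
serum creatinine is measured, using the demographics recorded *then*. Years
later, a researcher recomputing eGFR from the record as it is stored *now*
may get a different number, because DOB, race, gender — or even the
creatinine value — can be destructively overwritten in the EHR. This
package pairs the two values, quantifies their agreement, and attributes
each disagreement to the most parsimonious set of changed equation
parameters.

## The model

eGFR (mL/min/1.73 m²) comes from the IDMS-traceable MDRD study equation

```
eGFR = 175 × Scr^−1.154 × Age^−0.203 × 0.742 [if female] × 1.212 [if black]
```

(the 2009 CKD-EPI creatinine equation is also provided), with CKD staged by
eGFR band (90+, 60–89, 3a, 3b, 4, 5).

A pair is *discordant* when the stored automated value and the
retrospectively calculated value differ after conservative whole-number
rounding. For each discordant pair, the attribution algorithm:

1. enumerates the MDRD equation over every combination of integer age
   18–120, gender, black/non-black race, and Scr 0.10–30.0 mg/dL in 0.01
   steps (1,232,292 combinations; generated values rounded to tenths span
   1.0–251.0);
2. looks up all combinations reproducing the automated value;
3. keeps those agreeing with the current record on the most parameters;
4. reports the parameters on which they still disagree — a single distinct
   set is a definitive explanation ("Age", "1 clinical"), several tied sets
   a disjunction ("Race or age").

Agreement is summarised by Bland–Altman limits of agreement (mean ± 2 SD of
the differences), percent stage agreement, and Cohen's κ with a
large-sample CI. A synthetic cohort generator emulates a VA-like population
(~90% male, ~18% black, age ≈ N(55, 18), log-normal Scr) with labelled
injected drift, so the attribution can be validated against ground truth.

## Worked example

```
cd analysis
python 01_simulate_cohort.py
python 02_concordance.py
python 03_attribute_discordance.py
python 04_recovery.py
```

On the default study conditions (10,000 patients, seed 42, mutually
exclusive single-parameter drift at total probability 0.3) this prints:

```
10000 pairs; 2947 discordant (29.47%) at whole-number screening
stage agreement 88.32%, kappa 82.98 (82.07-83.89)
...
attributed 2947 discordant pairs:
  1 clinical                   n=  651   22.09%  median |dif| 27.6
  Gender                       n=  632   21.45%  median |dif| 23.6
  Age                          n=  613   20.80%  median |dif| 4.7
  Race                         n=  538   18.26%  median |dif| 19.1
  Scr or age                   n=  200    6.79%  median |dif| 4.6
...
ground-truth recovery on the synthetic cohort:
  age      n=  714  containment 1.0000  exact 0.8585
  gender   n=  742  containment 1.0000  exact 0.8518
  race     n=  741  containment 1.0000  exact 0.7260
  scr      n=  750  containment 1.0000  exact 0.8680
```

About 30% of patients drift, nearly all of them screen discordant, and for
every discordant pair the injected parameter is contained in a reported
mismatch set (containment 1.0); "exact" is the fraction where that
parameter was also the *unique* definitive explanation rather than tied
with another equally parsimonious one. The same machinery is exposed as a
CLI (`egfr-discordance simulate|analyze|attribute|run`) and as a library
(`egfr_discordance.run_pipeline`).

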