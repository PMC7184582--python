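# Methods

## Scope and design

`perioprp` evaluates how faithfully partial recording protocols (PRPs)
reproduce the full-mouth periodontitis diagnosis under the 2012 CDC/AAP and
2018 EFP/AAP case definitions. The reference standard is always the
*full-mouth rule-based diagnosis of the same definition*, never a latent
disease state: the question being answered is protocol fidelity, not
biological validity. Both rule engines are pure functions of
`(chart, site selection, parameter set)`, so the full-mouth diagnosis and
every PRP diagnosis come from the same code path with different selectors.

## Chart model

A chart holds 28 FDI tooth positions (third molars excluded by
construction) with six probing sites each; PPD and CAL are non-negative
integer millimetres with a configurable plausibility ceiling (19 mm).
"Unmeasured" is representable and distinct from 0 mm; unmeasured values
never satisfy any diagnostic criterion and never contribute to the site of
greatest loss. A chart is *complete* when every present tooth has both PPD
and CAL at all six sites; the eligibility screen excludes participants
younger than 30, medically excluded from probing, incomplete, or edentulous
(all applicable reasons reported; the flow report attributes multi-reason
exclusions to the first reason in that fixed order). Completeness as the
reading of "complete periodontal status" is a deliberate, configurable
choice — a survey wanting a weaker rule can relax it upstream.

## Case-definition engines

The 2012 tiers are checked severe → moderate → mild; site-pair criteria
marked "not on the same tooth" require the qualifying sites to lie on at
least two distinct teeth; the mild tier's CAL arm counts sites regardless
of tooth, with the distinct-teeth constraint on its paired-PPD arm.

Two 2018 rules needed interpretation:

* **Detectable interdental CAL.** The presence rule requires interdental
  attachment loss at ≥2 non-adjacent teeth without naming a threshold; we
  use CAL ≥ 1 mm, consistent with the mild staging band starting at 1 mm,
  and expose it as `Params2018.detectable_cal_mm`.
* **Adjacency** is defined on anatomical arch sequences (second molar →
  … → central incisors → … → second molar), ignoring whether intervening
  teeth are present; the two central incisors across the midline are
  adjacent. This makes the predicate data-independent.
* **Buccal/oral pathway** requires CAL ≥ 3 mm and PPD > 3 mm at the *same
  site* (the stricter of the two readings), at ≥2 teeth.
* A case established through the buccal/oral pathway alone, with no
  measurable interdental CAL, is staged mild so that "case ⇔ stage ≥ 1"
  holds; the staging rule itself uses only interdental CAL.

Because every criterion is existential over observed sites, both engines
are monotone in the site selection: a PRP can only miss disease. Hence
FP = 0 and specificity = 1 against the full-mouth reference by
construction. Published PRP evaluations on real survey data report
specificities slightly below 100%, which cannot arise from these rules on
a fixed chart; the pipeline does not imitate that (unexplained) mechanism,
and the test suite asserts the structural FP = 0 instead.

Published summary tables from such evaluations also print "DOR" values in
the 1.3–2.9 range that are inconsistent with (TP/FN)/(FP/TN) applied to the
printed sensitivities and specificities but match its log10 to print
precision; the battery therefore reports both `dor` and `log10_dor`. One
published Ramfjord AUC cell (71.2) contradicts the hard-label identity
(Se+Sp)/2 = 79.2 computed from its own row and is treated as a misprint;
the acceptance identities use internally consistent cells only.

## Indicator battery

All Table-style indicators are computed literally from the 2×2 counts.
Numerical conventions:

* **Empty denominators** (e.g. no reference positives) yield NA, never 0;
  `evaluate_protocols` propagates NA.
* **Proportion CIs** are Wilson score intervals at the requested level —
  stable at the extreme proportions (≥99%) these analyses produce. Youden
  and AUC intervals are propagated from the sensitivity/specificity bounds;
  the MCC is reported without a CI (no closed form is in common use).
* **DOR CI** is computed on the natural-log scale with
  SE = √(1/TP+1/TN+1/FP+1/FN) and exponentiated back; any zero cell
  triggers the Haldane–Anscombe +0.5 correction to all four cells, flagged
  in the output.
* **Hard-label AUC** is (Se+Sp)/2, the trapezoidal area under the
  three-point ROC. **Multiclass AUC** is the unweighted mean over all class
  pairs present in the reference of pairwise one-vs-one hard-label AUCs,
  each direction of a pair scored with the one-hot indicator of the test
  label and averaged (Hand–Till construction; ordinal stages treated as
  categorical). With two classes this reduces exactly to the binary AUC;
  scikit-learn's `roc_auc_score(multi_class="ovo")` on one-hot scores is
  used as an independent cross-check in the tests, never as the
  implementation.
* Reporting tables round percentages to 1 decimal and DOR-scale values to
  2 decimals.

## Synthetic population model

The generator emulates an NHANES-like examination sample so the entire
pipeline is testable without any data download. Per participant: a latent
severity class (healthy / mild / moderate / severe) from a mixture; each
tooth retained with probability 1 − (base + class increment); per present
tooth a shared Gaussian tooth effect plus independent site noise gives
within-tooth correlation ρ = τ²/(τ²+σ²); site CAL is the rounded, 0-floored
latent value and PPD = round(0.6·CAL + offset noise) truncated to
[0, CAL+3]. All outputs are integer mm and fully reproducible from the
seed.

Class means live on an *unbounded liability scale* and the healthy mean is
negative (−2.5 mm): after rounding and truncation a healthy mouth emits
mostly CAL = 0, which matters because the 1-mm 2018 detectability threshold
would otherwise classify essentially everyone with mild Gaussian noise as a
case. Defaults (mixture 0.45/0.20/0.20/0.15; class means −2.5/0.2/1.3/3.0;
σ = 1.0 mm, ρ = 0.45; tooth-loss base 0.02 with class increments up to
0.12; ages uniform 30–80) were chosen once so that, at n = 2000, all four
full-mouth 2012 severity classes occur with frequency ≥ 5% (needed to
exercise the multiclass AUC) and the 2018 reference contains a healthy
margin of non-cases; with them the full-mouth 2012 stage distribution is
roughly 53/12/25/10% and 2018 prevalence ≈ 69%.

What the generator does *not* emulate: demographic structure, examiner
variability, spatial clustering of disease along the arch beyond the
within-tooth effect, and real NHANES missingness patterns (a uniform
site-missingness rate is available but defaults to 0). Passing tests
therefore demonstrate correctness of the rules, metrics and pipeline
plumbing under controlled disease structure — not that any PRP's accuracy
on this synthetic population equals its accuracy on NHANES. Problem sizes
in the test and acceptance runs (2,000-participant populations, 10,000
random small charts for the brute-force cross-check) were chosen as
comfortably sufficient for the properties being asserted.

## Verification strategy

* Both rule engines are checked against an independently written
  brute-force checker that enumerates site pairs and tooth pairs explicitly
  (tests/_oracles.py), on random small charts under random site selections.
* Monotonicity under nested selectors, determinism, and order-independence
  are asserted as properties.
* The indicator battery is checked against literal re-implementations of
  each formula on 1,000 random contingency tables, and against arithmetic
  identities: AUC = (Se+Sp)/2 = (J+1)/2, F1 as the harmonic mean,
  prevalence-invariance of Se/Sp/DOR/AUC under k-fold duplication of
  negatives (and prevalence-*dependence* of accuracy/precision/F1/MCC).
* Generator calibration is verified by an exact-binomial prevalence
  recovery check across independent seeds.

## Known limitations

* 2018 grading (A–C), extent, the stage III/IV distinction and
  tooth-loss-based staging criteria are out of scope, as are survey
  weights, half-mouth/random-site PRPs (expressible via `custom_protocol`)
  and score-based ROC curves.
* The MCC is reported without a confidence interval.
* CPITN is implemented as the ten index teeth with no substitution rules
  for missing index teeth: absent teeth are simply absent evidence.
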