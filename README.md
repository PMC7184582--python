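# perioprp

Diagnostic-accuracy evaluation of periodontitis case definitions under
**full-mouth partial recording protocols (PRPs)**.

Population surveillance of periodontitis needs a case definition and a
recording protocol. Full-mouth probing — six sites (MB, B, DB, ML, L, DL) on
up to 28 teeth, third molars excluded — is the reference standard but is
slow and labour-intensive in large surveys, so epidemiologists examine a
subset of teeth and/or sites instead. `perioprp` implements, as a tested
reusable pipeline, the comparison of the **2012 CDC/AAP** and **2018
EFP/AAP** periodontitis case definitions under five classical full-mouth
PRPs, with the full-mouth diagnosis of the *same* definition as reference:

| protocol | teeth | sites |
|---|---|---|
| `RAMFJORD` | 16, 21, 24, 36, 41, 44 | all six |
| `CPITN` | 17, 16, 11, 26, 27, 36, 37, 31, 46, 47 | all six |
| `MB_B` | all 28 | MB, B |
| `MB_B_DB` | all 28 | MB, B, DB |
| `MB_B_DL` | all 28 | MB, B, DL |

## The rules and the statistics

Both case definitions are predicates over integer-mm probing pocket depth
(PPD) and clinical attachment loss (CAL) at selected sites, yielding a case
flag and an ordinal stage (0 none, 1 mild, 2 moderate, 3 severe; 2018
stages III/IV are collapsed into "severe").

* **2012 CDC/AAP** (interproximal sites only): severe = ≥2 interproximal
  sites with CAL ≥ 6 mm on ≥2 teeth **and** ≥1 site with PPD ≥ 5 mm;
  moderate = ≥2 sites CAL ≥ 4 mm on ≥2 teeth **or** ≥2 sites PPD ≥ 5 mm on
  ≥2 teeth; mild = ≥2 sites CAL ≥ 3 mm **and** (≥2 sites PPD ≥ 4 mm on
  ≥2 teeth or one site PPD ≥ 5 mm).
* **2018 EFP/AAP**: a case when detectable interdental CAL (≥ 1 mm,
  configurable) is present at ≥2 non-adjacent teeth, or buccal/oral CAL
  ≥ 3 mm with PPD > 3 mm at the same site on ≥2 teeth; staged by interdental
  CAL at the site of greatest loss (1–2 mm mild, 3–4 mm moderate, ≥5 mm
  severe).

For each (definition, protocol) pair the PRP diagnosis is cross-tabulated
against the full-mouth reference and the standard battery is computed:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, precision,
Youden's J = Se + Sp − 1, F1, Matthews correlation coefficient, the
diagnostic odds ratio DOR = (TP/FN)/(FP/TN) with its log-scale CI
(SE = √(1/TP + 1/TN + 1/FP + 1/FN)), Wilson score intervals for the
proportions, and ROC AUC. A hard-label classifier has one operating point,
so its ROC is the three-point polygon and AUC = (Se + Sp)/2 exactly; staging
accuracy uses a Hand–Till-style multiclass AUC (unweighted mean of pairwise
one-vs-one hard-label AUCs). The 2012→2018 staging reclassification
cross-tab (the matrix underlying the usual alluvial diagram) is also
produced.

Because every criterion is existential over observed sites, a PRP diagnosis
is always nested in the full-mouth one: PRPs can only miss disease, never
invent it, so FP = 0 and specificity = 1 by construction in this pipeline.

## Worked example

Charts are generated by the built-in NHANES-like synthetic population model
(severity-class mixture, class-dependent tooth loss, correlated integer-mm
site measurements — see `docs/methods.md`):

```python
from perioprp import (SyntheticConfig, generate_population, evaluate_protocols,
                      EFP_AAP_2018, CDC_AAP_2012)

charts, _ = generate_population(SyntheticConfig(n_participants=2000), seed=1)
table = evaluate_protocols(
    charts, definitions=(EFP_AAP_2018, CDC_AAP_2012),
    protocols=("RAMFJORD", "CPITN", "MB_B", "MB_B_DB", "MB_B_DL"))

cols = ["sensitivity", "accuracy", "auc", "staging_auc"]
table[cols] = (100 * table[cols]).round(1)     # report on the percent scale
print(table[["definition", "protocol"] + cols].to_string(index=False))
```

which prints:

```
  definition protocol  sensitivity  accuracy  auc  staging_auc
EFP_AAP_2018 RAMFJORD         80.6      86.6 90.3         74.0
EFP_AAP_2018    CPITN         82.9      88.1 91.4         78.9
EFP_AAP_2018     MB_B         81.8      87.4 90.9         77.7
EFP_AAP_2018  MB_B_DB         88.3      91.9 94.2         86.8
EFP_AAP_2018  MB_B_DL         87.7      91.4 93.8         86.6
CDC_AAP_2012 RAMFJORD         55.5      78.6 77.7         60.0
CDC_AAP_2012    CPITN         71.5      86.3 85.8         67.6
CDC_AAP_2012     MB_B         63.9      82.6 81.9         63.4
CDC_AAP_2012  MB_B_DB         83.6      92.1 91.8         79.3
CDC_AAP_2012  MB_B_DL         82.8      91.7 91.4         78.6
```

Each row reads: under that protocol, the share of full-mouth cases the PRP
detects (sensitivity), overall agreement with the full-mouth diagnosis
(accuracy), the presence AUC, and the staging multiclass AUC. The 2018
definition dominates the 2012 one on sensitivity and AUC for every PRP —
the 2012 rules need paired deep interproximal findings that index-teeth
protocols easily miss — and the three-site whole-dentition protocols
(MB-B-DB, MB-B-DL) are the strongest PRPs under both definitions.

The same analysis runs from the shell, end to end:

```bash
perioprp run-all --seed 1 --out results/run1          # synthetic input
perioprp evaluate --input charts.csv --out results/   # your own chart CSV
```

writing the eligibility flow, tidy indicator tables, the reclassification
cross-tab and a machine-readable run log. The chart CSV schema (long
format, one row per tooth–site) and an NHANES Universal-numbering dialect
are documented in `perioprp.chart_model`.

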