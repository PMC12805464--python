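# ruleout

Evaluation toolkit for **rule-out pre-screening** with a continuous blood
biomarker: predictiveness-curve ("integrated risk") profiling, ROC/AUC
inference with DeLong confidence intervals, prevalence-adjusted screening
metrics, rule-out cutoff selection, and clinical-trial enrollment planning.

The motivating application is plasma pTau217 (pg/mL) as a pre-screen for
amyloid pathology: patients whose biomarker falls below a rule-out cutoff
are spared a confirmatory amyloid PET scan. The package targets
biostatisticians and trial planners who need to pick such a cutoff, quantify
its consequences at a *specified* disease prevalence, and estimate the
screening economics of deploying it.

## The model

For a biomarker Y and binary disease state D (amyloid-positive vs negative),
the **predictiveness curve** reports risk as a function of the biomarker's
risk percentile v ∈ [0, 1]:

    R(v) = P(D = 1 | Y = F⁻¹(v))

together with the induced operating characteristics of thresholding at the
quantile F⁻¹(v):

    PPV(v)     = P(D = 1 | Y > F⁻¹(v))
    1 − NPV(v) = P(D = 1 | Y ≤ F⁻¹(v))

Two estimators are provided: the empirical conditional frequencies, and the
monotone nonparametric MLE (isotonic regression / pool-adjacent-violators).
When the sample's case fraction is unrepresentative, curves and metrics are
computed at an externally specified prevalence π via case/control
re-weighting, equivalent to the Bayes-form identities used for the
cutoff-level metrics (sensitivity s, specificity p):

    PPV = sπ / (sπ + (1−p)(1−π))          NPV = p(1−π) / (p(1−π) + (1−s)π)
    screen-out      = (1−s)π + p(1−π)
    extra screening = 1/s − 1
    scans saved     = 1 − (1 − screen-out)/s

AUCs use the Mann–Whitney estimator with midrank ties and DeLong
structural-components variance. A synthetic-cohort generator draws each
(cognitive status × amyloid status) stratum from a lognormal moment-matched
to published stratum means/SDs, with censoring at the assay's lower limit of
quantification (0.0693 pg/mL), so every analysis is runnable without access
to the original subject-level data.

## Worked example

```python
from ruleout import ConfusionMatrix, raw_metrics, adjusted_metrics, trial_plan

# counts at the 0.189 pg/mL rule-out cutoff in a cognitively impaired cohort
cm = ConfusionMatrix(tp=390, fn=4, fp=102, tn=42)
raw = raw_metrics(cm)
m = adjusted_metrics(raw.sensitivity, raw.specificity, prevalence=0.6994,
                     opa_raw=raw.opa_raw)
print(m.as_percent_dict())
plan = trial_plan(750, raw.sensitivity, raw.specificity, 0.6994)
print(f"PET scans: {plan.scans_without:.1f} -> {plan.scans_with:.1f}")
```

prints

```
{'sensitivity': 98.98, 'specificity': 29.17, 'prevalence': 69.94,
 'ppv': 76.48, 'npv': 92.51, 'screen_out': 9.48,
 'additional_screening': 1.03, 'scans_saved': 8.55,
 'opa_raw': 80.3, 'opa_adjusted': 78.0}
PET scans: 1072.3 -> 980.7
```

Reading: at this cutoff 9.48% of the screening population is ruled out of
PET scanning; among those ruled out, 7.49% (1 − NPV) would in fact have
amyloid pathology. Enrolling 750 amyloid-positive participants needs 980.7
expected PET scans with the pre-screen instead of 1072.3 without — 8.55%
saved — at the cost of pre-screening 1.03% more referrals.

The `examples/` directory holds one short script per capability (synthetic
cohorts, AUC forest tables, risk profiling, cutoff selection + trial
planning). A thin CLI mirrors the pipeline:

```bash
ruleout simulate --out-dir out --seed 1
ruleout evaluate --input out/ci_cohort.csv --prevalence 0.6994 --out-dir out
ruleout profile  --input out/ci_cohort.csv --cutoff 0.189 --out-dir out
ruleout plan-trial --n-enroll 750 --out-dir out
```

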