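# Methods

## Setting

A continuous plasma biomarker Y (pTau217, pg/mL) is evaluated as a rule-out
pre-screen for a binary disease state D (amyloid pathology, referenced by
amyloid-PET visual read or by Centiloid thresholds). Subjects with Y below a
cutoff c are ruled out of confirmatory PET scanning; subjects with Y ≥ c are
screened in — ties at the cutoff screen in, matching the "< c rules out"
convention. Two populations are treated separately throughout: cognitively
impaired (CI) and cognitively unimpaired (CU), because their amyloid
prevalences differ by a factor of ~5 and every predictive value depends on
prevalence.

## Screening metrics and prevalence adjustment

Sensitivity s and specificity p are prevalence-free and computed from raw
counts. PPV, NPV, and the screening-economics quantities are computed from
(s, p) at a supplied prevalence π through the Bayes identities listed in the
README. Setting π to the sample case fraction recovers the raw-count PPV/NPV
exactly (verified algebraically and by test); an externally adjusted π (e.g.
a full-cohort prevalence when the assayed subset is enrichment-biased)
substitutes cleanly. Overall percent agreement (OPA) is reported from raw
counts by default, with the π-weighted version (sπ + p(1−π)) also available —
the two differ whenever π differs from the sample fraction.

Screening economics, per enrolled (confirmed-positive) participant:
without the pre-screen, finding one positive costs 1/π PET scans in
expectation. With it, 1/(πs) referrals must be pre-screened (the 1/s factor
compensates for true positives lost below the cutoff), of which the
screened-in fraction (1 − screen-out) proceeds to PET. "Scans saved",
1 − (1 − screen-out)/s, is the relative reduction in PET scans and satisfies
scans_saved = 1 − (1 + additional_screening)(1 − screen_out) to machine
precision; the trial planner is the same algebra scaled to a target
enrollment and is therefore reported as real-valued expectations, with
rounding deferred to the report boundary (half-up to 2 decimals, applied
only when formatting percentages).

The mixture trial sweep treats the referral stream as a fraction f of
CI-like and (1−f) of CU-like subjects with fixed per-stratum (s, p, π). Both
scan counts are ratios of functions linear in f, so the savings interpolate
monotonically between the pure-population endpoints.

## Predictiveness curves

The percentile grid places one point per distinct biomarker value (tied
values share a point) plus the v = 0 endpoint, keeping the cutoff ↔
percentile map invertible: the percentile of a cutoff c is the (weighted)
population fraction with Y < c, which equals the screen-out rate at c.
Prevalence adjustment re-weights cases by π/π̂ and controls by (1−π)/(1−π̂);
with these weights the curve-level PPV(v) and 1−NPV(v) agree with the
cutoff-level adjusted metrics exactly at every achievable operating point,
and the mixture identity v·(1−NPV)(v) + (1−v)·PPV(v) = π holds on the whole
grid by construction.

Two estimators:

* **empirical** — conditional case frequency at each distinct value;
  unbiased but non-monotone in finite samples.
* **monotone** — isotonic regression (pool-adjacent-violators) of the binary
  outcome on the biomarker with the case/control weights, i.e. the
  nonparametric MLE under the assumption that risk is non-decreasing in
  pTau217. The original analysis used a constrained GAM; its basis, link and
  penalty are not recoverable, so monotonicity — the scientifically
  meaningful constraint — is imposed directly instead. PAVA preserves the
  weighted mean, so the fitted risk averages to π and 1−NPV ≤ π ≤ PPV holds
  at every interior grid point.

Curve endpoints: at v = 0, 1−NPV is defined as 0 (no one below) and PPV
equals π; at v = 1, PPV is reported as the top grid point's fitted risk (the
limit from above). Implementation: `sklearn.isotonic.IsotonicRegression`
(cross-checked in tests against exhaustive search over monotone step
functions on every 8-point instance).

## AUC inference

The AUC is the Mann–Whitney statistic with midrank ties,
P(Y₊ > Y₋) + ½P(Y₊ = Y₋). Variance uses DeLong's structural components
(placement values), with sample variances (ddof = 1) and a normal-
approximation interval clipped to [0, 1]; perfect separation yields zero
estimated variance and a flagged degenerate interval rather than an
exception. A stratified bootstrap percentile interval is provided as a
cross-check utility, not the default. "Combined" estimates pool concatenated
subjects rather than meta-analytically averaging per-cohort AUCs; with equal
per-subject weighting this matches how a single pooled sample would be
analyzed and is the interpretation adopted for multi-cohort tables.

## Rule-out cutoff selection

The selector returns the largest cutoff whose prevalence-adjusted NPV is at
least `npv_min` (default 0.90) in *both* strata at their respective
prevalences; larger is better because screen-out, and hence scans saved,
increases with the cutoff. Candidate cutoffs are the midpoints between
consecutive distinct biomarker values pooled across both cohorts: every
cutoff strictly between two observed values induces the same classification,
so midpoints enumerate all achievable operating points and avoid boundary
ambiguity at observed values. Infeasibility (no qualifying cutoff) returns
`None` — a legitimate analytic outcome, not an error.

## Synthetic cohorts

The generator emulates the statistical structure the analysis consumes and
nothing more. Each (cognitive status × amyloid status) stratum is a
lognormal — concentrations are positive and right-skewed (published medians
sit below means throughout) — with log-scale parameters moment-matched to
the stratum's published mean and SD:

    σ² = ln(1 + (sd/mean)²),  μ = ln(mean) − σ²/2

Defaults (mean, SD in pg/mL; n): CI A+ (0.835, 0.381; 394), CI A− (0.361,
0.294; 144), CU A+ (0.516, 0.235; 224), CU A− (0.220, 0.157; 1386), implying
prevalences 73.2% (CI) and 13.9% (CU); LLoQ 0.0693 pg/mL. Draws below the
LLoQ are floored there and flagged (substitution at the observed LLoQ, which
reproduces the published data floor where below-LLoQ counts are reported
separately). Because the published summaries describe *observed* (already
floored) data, matching moments before censoring is a small deliberate
approximation, visible mainly in the CU A− stratum where ~5% of draws fall
below the LLoQ.

The closed-form AUC between two strata, Φ((μ₊ − μ₋)/√(σ₊² + σ₋²)), follows
from the normality of the log-ratio and serves as the generator's oracle:
the defaults give 0.884 (CI) and 0.893 (CU). Seeding: each stratum draws
from its own `default_rng([seed, stratum_index])` stream, so resizing one
stratum never perturbs another's values, and tables are bit-reproducible
under a fixed seed.

What the generator does **not** model: covariate effects (age, sex, APOE),
between-study assay or site effects, visual-read/Centiloid disagreement
(synthetic visual reads equal the generating stratum, so reference
misclassification is absent), and any deviation from lognormality. Tests
passing on synthetic cohorts therefore validate the estimators and the
pipeline's internal consistency, not the biomarker's real-world operating
characteristics; published real-data AUCs and concordance rates are not
reproducible without the original subject-level data and are not asserted.

## Numerical choices and edge cases

* Ties: midranks everywhere (AUC, percentile grid).
* Counts at a cutoff: value ≥ cutoff ⇒ test-positive, exactly as the
  classification rule states; ±∞ sentinels bound the full cutoff grid, with
  NaN for quantities undefined there (e.g. 1/s − 1 at s = 0).
* `adjusted_metrics` rejects s = 0 (additional screening undefined) and
  prevalences outside (0, 1); grid code handles the degenerate rows
  internally instead of raising.
* Percent formatting: decimal half-up at 2 places, applied only at the
  report boundary; all internal arithmetic is double precision.
* BLOQ values enter ROC/metric computation at the substituted LLoQ (they
  are real measurements known only to be small); they are never dropped.

## Problem sizes

Test and acceptance runs use the default cohort sizes (538 CI / 1610 CU),
200 replicate cohorts for Monte Carlo AUC checks, 20,000 bootstrap
replicates for the DeLong cross-check, 10⁵-draw strata for moment-recovery
checks, and exhaustive enumeration on 8-point instances for the isotonic
oracle — sizes at which every sampling-error bound used in the tests is
comfortably resolvable in seconds.
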