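"""Predictiveness-curve (integrated risk) profiling at a rule-out cutoff.

Builds the empirical and monotone (isotonic) risk curves at the adjusted
impaired-cohort prevalence of 69.94% and reads off PPV, 1-NPV, and the
screen-out percentile at the 0.189 pg/mL rule-out cutoff.
"""

from ruleout import (
    default_ci_config,
    empirical_risk_curve,
    export_integrated_risk,
    generate_cohort,
    monotone_risk_curve,
)

CUTOFF = 0.189  # pg/mL

table = generate_cohort(default_ci_config(seed=7))
empirical = empirical_risk_curve(table, prevalence=0.6994)
monotone = monotone_risk_curve(table, prevalence=0.6994)

for curve in (empirical, monotone):
    at = curve.at_cutoff(CUTOFF)
    print(
        f"{curve.estimator:9s} estimator at {CUTOFF} pg/mL: "
        f"percentile={at['percentile']:.4f}, PPV={at['ppv']:.4f}, "
        f"1-NPV={at['one_minus_npv']:.4f}"
    )

# The cutoff's percentile equals the screen-out rate; PPV is the amyloid
# prevalence among screened-in subjects, 1-NPV among those ruled out.
frame = export_integrated_risk(empirical, monotone, CUTOFF)
print(f"\nplot-data table: {len(frame)} rows, series: {sorted(set(frame['series']))}")
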