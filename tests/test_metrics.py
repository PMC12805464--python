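"""Screening metrics, cutoff grids, rule-out selection, trial planning."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ruleout import (
    ConfusionMatrix,
    adjusted_metrics,
    confusion_at_cutoff,
    cutoff_grid,
    grid_to_frame,
    metrics_at_cutoff,
    mixture_trial_sweep,
    percent_round,
    raw_metrics,
    select_rule_out_cutoff,
    sens_spec_curves,
    trial_plan,
)

from conftest import make_table

# Published performance of the pTau217 assay at the 0.189 pg/mL rule-out
# cutoff: confusion counts and the prevalence used for adjustment.
CI_CM = ConfusionMatrix(tp=390, fn=4, fp=102, tn=42)
CU_CM = ConfusionMatrix(tp=214, fn=10, fp=683, tn=703)
PI_CI = 0.6994
PI_CU = 224 / 1610

prob = st.floats(0.01, 0.99)


class TestRawMetrics:
    def test_impaired_column(self):
        m = raw_metrics(CI_CM)
        assert m.sensitivity == pytest.approx(0.9898, abs=5e-5)
        assert m.specificity == pytest.approx(0.2917, abs=5e-5)
        assert m.opa_raw == pytest.approx(0.8030, abs=5e-5)

    def test_unimpaired_column(self):
        m = raw_metrics(CU_CM)
        assert m.sensitivity == pytest.approx(0.9554, abs=5e-5)
        assert m.specificity == pytest.approx(0.5072, abs=5e-5)
        assert m.opa_raw == pytest.approx(0.5696, abs=5e-5)

    def test_perfect_two_by_two(self):
        m = raw_metrics(ConfusionMatrix(1, 0, 0, 1))
        assert m == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_empty_margin_named(self):
        with pytest.raises(ValueError, match="tp \\+ fn"):
            raw_metrics(ConfusionMatrix(0, 0, 1, 1))
        with pytest.raises(ValueError, match="fp \\+ tn"):
            raw_metrics(ConfusionMatrix(1, 1, 0, 0))


class TestAdjustedMetrics:
    def test_impaired_column(self):
        r = raw_metrics(CI_CM)
        m = adjusted_metrics(r.sensitivity, r.specificity, PI_CI)
        assert m.ppv == pytest.approx(0.7648, abs=5e-5)
        assert m.npv == pytest.approx(0.9251, abs=5e-5)
        assert m.screen_out == pytest.approx(0.0948, abs=5e-5)
        assert m.additional_screening == pytest.approx(0.0103, abs=5e-5)
        assert m.scans_saved == pytest.approx(0.0855, abs=5e-5)

    def test_unimpaired_column(self):
        r = raw_metrics(CU_CM)
        m = adjusted_metrics(r.sensitivity, r.specificity, PI_CU)
        assert m.npv == pytest.approx(0.9860, abs=5e-5)
        assert m.screen_out == pytest.approx(0.4429, abs=5e-5)
        assert m.additional_screening == pytest.approx(0.0467, abs=5e-5)
        assert m.scans_saved == pytest.approx(0.4168, abs=5e-5)

    def test_perfect_assay(self):
        m = adjusted_metrics(1.0, 1.0, 0.3)
        assert m.ppv == m.npv == 1.0
        assert m.screen_out == pytest.approx(0.7)
        assert m.additional_screening == 0.0
        assert m.scans_saved == pytest.approx(0.7)

    def test_zero_sensitivity_rejected(self):
        with pytest.raises(ValueError, match="additional screening"):
            adjusted_metrics(0.0, 0.9, 0.5)

    @given(st.floats(0.01, 1.0), st.floats(0.0, 1.0), prob)
    def test_scans_saved_identity(self, s, p, pi):
        m = adjusted_metrics(s, p, pi)
        rhs = 1.0 - (1.0 + m.additional_screening) * (1.0 - m.screen_out)
        assert math.isclose(m.scans_saved, rhs, abs_tol=1e-12)

    def test_sample_prevalence_reproduces_raw_predictive_values(self):
        # pi = sample case fraction => Bayes-form PPV/NPV collapse to counts
        r = raw_metrics(CU_CM)
        m = adjusted_metrics(r.sensitivity, r.specificity, PI_CU)
        assert m.ppv == pytest.approx(214 / 897, abs=1e-12)
        assert m.npv == pytest.approx(703 / 713, abs=1e-12)


class TestConfusionAtCutoff:
    def test_two_record_example(self):
        table = make_table([0.10, 0.20], [False, True])
        cm = confusion_at_cutoff(table, 0.189)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 0, 0, 1)

    def test_value_at_cutoff_screens_in(self):
        table = make_table([0.189, 0.189], [True, False])
        cm = confusion_at_cutoff(table, 0.189)
        assert (cm.tp, cm.fp) == (1, 1) and (cm.fn, cm.tn) == (0, 0)

    def test_matches_per_record_enumeration(self, rng):
        values = rng.lognormal(-1, 0.6, 30)
        labels = rng.random(30) < 0.5
        labels[:2] = [True, False]
        cutoff = float(np.median(values))
        cm = confusion_at_cutoff(make_table(values, labels), cutoff)
        tp = sum(1 for v, l in zip(values, labels) if l and v >= cutoff)
        fn = sum(1 for v, l in zip(values, labels) if l and v < cutoff)
        fp = sum(1 for v, l in zip(values, labels) if not l and v >= cutoff)
        tn = sum(1 for v, l in zip(values, labels) if not l and v < cutoff)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (tp, fn, fp, tn)


class TestCutoffGrid:
    def test_min_cutoff_has_full_sensitivity(self, rng):
        values = rng.lognormal(-1, 0.6, 40)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        rows = cutoff_grid(make_table(values, labels), grid=[float(values.min())])
        assert rows[0].metrics.sensitivity == 1.0

    def test_all_grid_row_count(self, rng):
        values = np.round(rng.lognormal(-1, 0.6, 10), 1)
        labels = np.array([True] * 5 + [False] * 5)
        rows = cutoff_grid(make_table(values, labels), grid="all")
        assert len(rows) == len(np.unique(np.maximum(values, 0.0693))) + 2

    def test_rows_match_independent_recomputation(self, rng):
        values = rng.lognormal(-1, 0.6, 50)
        labels = rng.random(50) < 0.6
        labels[:2] = [True, False]
        table = make_table(values, labels)
        rows = cutoff_grid(table, prevalence=0.4, grid="all")
        for row in rows[1:-1]:  # skip sentinels (degenerate margins)
            cm = confusion_at_cutoff(table, row.cutoff)
            assert cm == row.confusion
            r = raw_metrics(cm)
            m = adjusted_metrics(r.sensitivity, r.specificity, 0.4, opa_raw=r.opa_raw)
            assert row.metrics.ppv == pytest.approx(m.ppv, abs=1e-12)
            assert row.metrics.scans_saved == pytest.approx(m.scans_saved, abs=1e-12)

    def test_monotone_sensitivity_specificity(self, rng):
        values = rng.lognormal(-1, 0.6, 80)
        labels = rng.random(80) < 0.5
        labels[:2] = [True, False]
        frame = grid_to_frame(cutoff_grid(make_table(values, labels), grid="all"))
        assert (np.diff(frame["sensitivity"]) <= 1e-12).all()
        assert (np.diff(frame["specificity"]) >= -1e-12).all()


class TestSelectRuleOutCutoff:
    def test_separated_strata_return_gap_midpoint(self):
        # prevalence high enough that ruling out any positive breaks the NPV
        ci = make_table([0.1] * 20 + [0.9] * 40, [False] * 20 + [True] * 40)
        cu = make_table([0.12] * 40 + [0.8] * 10, [False] * 40 + [True] * 10)
        cutoff = select_rule_out_cutoff(ci, cu, npv_min=0.9, pi_ci=0.7, pi_cu=0.6)
        assert cutoff == pytest.approx((0.12 + 0.8) / 2)

    def test_infeasible_returns_none(self):
        # overlapping strata cannot reach NPV ~ 1
        ci = make_table([0.1, 0.2, 0.3, 0.4], [True, False, True, False])
        cu = make_table([0.1, 0.2, 0.3, 0.4], [False, True, False, True])
        assert select_rule_out_cutoff(ci, cu, npv_min=0.999999) is None

    def test_selected_cutoff_verified_by_grid_search(self, rng):
        from ruleout import default_ci_config, default_cu_config, generate_cohort

        ci = generate_cohort(default_ci_config(seed=21))
        cu = generate_cohort(default_cu_config(seed=21))
        cutoff = select_rule_out_cutoff(ci, cu, npv_min=0.90)
        assert cutoff is not None
        for table, pi in ((ci, 0.6994), (cu, 0.1391)):
            _, pm = metrics_at_cutoff(table, cutoff, prevalence=pi)
            assert pm.npv >= 0.90
        # exhaustive check: no admissible cutoff above the selected one
        def adj_npv(table, c, pi):
            cm = confusion_at_cutoff(table, float(c))
            s = cm.tp / (cm.tp + cm.fn)
            p = cm.tn / (cm.tn + cm.fp)
            den = p * (1 - pi) + (1 - s) * pi
            return p * (1 - pi) / den if den > 0 else math.nan

        pooled = np.unique(np.concatenate([ci.ptau(), cu.ptau()]))
        mids = (pooled[:-1] + pooled[1:]) / 2
        for c in mids[mids > cutoff]:
            npvs = [adj_npv(t, c, pi) for t, pi in ((ci, 0.6994), (cu, 0.1391))]
            assert not all(v >= 0.90 for v in npvs)


class TestTrialPlan:
    def test_impaired_scenario_savings(self):
        r = raw_metrics(CI_CM)
        plan = trial_plan(750, r.sensitivity, r.specificity, PI_CI)
        assert plan.saved_fraction == pytest.approx(0.0855, abs=5e-5)

    def test_perfect_assay_scans_equal_enrollment(self):
        plan = trial_plan(750, 1.0, 1.0, 0.5)
        assert plan.scans_with == pytest.approx(750.0)

    @given(st.floats(0.05, 1.0), st.floats(0.0, 1.0), prob)
    def test_saved_fraction_equals_scans_saved(self, s, p, pi):
        plan = trial_plan(500, s, p, pi)
        assert math.isclose(
            plan.saved_fraction, adjusted_metrics(s, p, pi).scans_saved, abs_tol=1e-12
        )

    def test_mixture_sweep_endpoints_and_monotonicity(self):
        ci = (390 / 394, 42 / 144, PI_CI)
        cu = (214 / 224, 703 / 1386, PI_CU)
        sweep = mixture_trial_sweep(750, ci, cu)
        assert sweep["saved_fraction"].iloc[-1] == pytest.approx(
            trial_plan(750, *ci).saved_fraction, abs=1e-12
        )
        assert sweep["saved_fraction"].iloc[0] == pytest.approx(
            trial_plan(750, *cu).saved_fraction, abs=1e-12
        )
        diffs = np.diff(sweep["saved_fraction"])
        assert (diffs <= 1e-12).all() or (diffs >= -1e-12).all()


class TestSensSpecCurves:
    def test_endpoints(self, rng):
        values = rng.lognormal(-1, 0.6, 60)
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        frame = sens_spec_curves(make_table(values, labels))
        assert frame["sensitivity"].iloc[0] == 1.0
        assert frame["specificity"].iloc[-1] == 1.0

    def test_agrees_with_cutoff_grid(self, rng):
        values = np.round(rng.lognormal(-1, 0.6, 60), 2)
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        table = make_table(values, labels)
        frame = sens_spec_curves(table)
        for _, row in frame.iloc[1:].iterrows():
            # a cutoff just above this grid value reproduces sens/spec
            cutoff = float(row["value"]) + 1e-9
            cm = confusion_at_cutoff(table, cutoff)
            r = raw_metrics(cm)
            assert row["sensitivity"] == pytest.approx(r.sensitivity, abs=1e-9)
            assert row["specificity"] == pytest.approx(r.specificity, abs=1e-9)


class TestPercentRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.802974, 80.30), (0.92508, 92.51), (0.094775, 9.48), (0.12345, 12.35), (0.5, 50.0)],
    )
    def test_half_up_two_decimals(self, x, expected):
        assert percent_round(x) == expected
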