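"""Screening performance metrics, cutoff grids, and trial-enrollment planning.

A rule-out pre-screen classifies biomarker values below a cutoff as
test-negative (ruled out of confirmatory PET scanning) and values at or
above it as test-positive (screened in); ties at the cutoff screen in.
Sensitivity and specificity come from raw counts; PPV, NPV and the
screening-economics quantities are Bayes-form functions of (sensitivity s,
specificity p) at a supplied prevalence pi, so an externally adjusted
prevalence can replace an unrepresentative sample fraction:

* PPV = s pi / (s pi + (1-p)(1-pi))
* NPV = p (1-pi) / (p (1-pi) + (1-s) pi)
* screen-out rate = (1-s) pi + p (1-pi)
* additional screening required = 1/s - 1
* scans saved = 1 - (1 - screen_out) / s
  (equivalently 1 - (1 + additional)(1 - screen_out))

Overall percent agreement (OPA) is reported from raw counts by default; a
prevalence-adjusted OPA (s pi + p (1-pi)) is also computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, binary_reference


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


class RawMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    ppv_raw: float
    npv_raw: float
    opa_raw: float


@dataclass(frozen=True)
class PerformanceMetrics:
    """Raw-count accuracy plus prevalence-adjusted predictive/screening values."""

    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    npv: float
    screen_out: float
    additional_screening: float
    scans_saved: float
    opa_raw: float = math.nan
    opa_adjusted: float = math.nan

    def as_percent_dict(self, ndigits: int = 2) -> dict[str, float]:
        """All proportions as percentages, rounded half-up (report boundary)."""
        return {
            name: percent_round(getattr(self, name), ndigits)
            for name in (
                "sensitivity",
                "specificity",
                "prevalence",
                "ppv",
                "npv",
                "screen_out",
                "additional_screening",
                "scans_saved",
                "opa_raw",
                "opa_adjusted",
            )
        }


@dataclass(frozen=True)
class CutoffGridRow:
    cutoff: float
    confusion: ConfusionMatrix
    metrics: PerformanceMetrics


@dataclass(frozen=True)
class TrialPlan:
    """Expected screening flow for enrolling ``n_enroll`` amyloid-positive subjects."""

    n_enroll: int
    scans_without: float  # PET scans needed with no pre-screen
    prescreened: float  # blood tests performed with the pre-screen
    scans_with: float  # PET scans needed with the pre-screen
    saved_fraction: float  # relative reduction in PET scans


def percent_round(x: float, ndigits: int = 2) -> float:
    """Proportion -> percentage, rounded half-up to ``ndigits`` decimals."""
    x = float(x)
    if not math.isfinite(x):
        return math.nan
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_at_cutoff(
    table: CohortTable,
    cutoff: float,
    reference: str = "visual_read",
    cl_threshold: float = 24.0,
) -> ConfusionMatrix:
    """Counts at a rule-out cutoff: test-positive iff value >= cutoff."""
    values, labels = binary_reference(table, reference, cl_threshold)
    return _confusion_from_arrays(values, labels, cutoff)


def _confusion_from_arrays(values: np.ndarray, labels: np.ndarray, cutoff: float) -> ConfusionMatrix:
    test_pos = values >= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(test_pos & labels)),
        fn=int(np.sum(~test_pos & labels)),
        fp=int(np.sum(test_pos & ~labels)),
        tn=int(np.sum(~test_pos & ~labels)),
    )


def raw_metrics(cm: ConfusionMatrix) -> RawMetrics:
    """Count-based metrics; PPV/NPV margins with zero counts yield NaN."""
    if cm.tp + cm.fn == 0:
        raise ValueError("no positive-reference records (tp + fn = 0)")
    if cm.fp + cm.tn == 0:
        raise ValueError("no negative-reference records (fp + tn = 0)")
    s = cm.tp / (cm.tp + cm.fn)
    p = cm.tn / (cm.tn + cm.fp)
    ppv = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else math.nan
    npv = cm.tn / (cm.tn + cm.fn) if cm.tn + cm.fn else math.nan
    return RawMetrics(s, p, ppv, npv, (cm.tp + cm.tn) / cm.total)


def _adjusted_fields(s: float, p: float, pi: float) -> dict[str, float]:
    ppv_den = s * pi + (1.0 - p) * (1.0 - pi)
    npv_den = p * (1.0 - pi) + (1.0 - s) * pi
    screen_out = (1.0 - s) * pi + p * (1.0 - pi)
    return {
        "ppv": s * pi / ppv_den if ppv_den > 0 else math.nan,
        "npv": p * (1.0 - pi) / npv_den if npv_den > 0 else math.nan,
        "screen_out": screen_out,
        "additional_screening": 1.0 / s - 1.0 if s > 0 else math.nan,
        "scans_saved": 1.0 - (1.0 - screen_out) / s if s > 0 else math.nan,
        "opa_adjusted": s * pi + p * (1.0 - pi),
    }


def adjusted_metrics(
    sensitivity: float,
    specificity: float,
    prevalence: float,
    opa_raw: float = math.nan,
) -> PerformanceMetrics:
    """Prevalence-adjusted predictive values and screening economics.

    ``prevalence`` is the externally specified amyloid-positive fraction pi
    substituted into the Bayes-form expressions; with pi equal to the sample
    case fraction these reduce to the raw-count PPV/NPV.
    """
    if not 0 < sensitivity <= 1:
        raise ValueError("sensitivity must be in (0, 1]; 0 leaves additional screening undefined")
    if not 0 <= specificity <= 1:
        raise ValueError("specificity must be in [0, 1]")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    fields = _adjusted_fields(sensitivity, specificity, prevalence)
    return PerformanceMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        prevalence=prevalence,
        opa_raw=opa_raw,
        **fields,
    )


def metrics_at_cutoff(
    table: CohortTable,
    cutoff: float,
    prevalence: float | None = None,
    reference: str = "visual_read",
    cl_threshold: float = 24.0,
) -> tuple[ConfusionMatrix, PerformanceMetrics]:
    """Confusion matrix and adjusted metrics at one cutoff.

    ``prevalence=None`` adjusts at the sample case fraction (so PPV/NPV
    equal their raw-count counterparts).
    """
    values, labels = binary_reference(table, reference, cl_threshold)
    cm = _confusion_from_arrays(values, labels, cutoff)
    raw = raw_metrics(cm)
    pi = labels.mean() if prevalence is None else prevalence
    pm = adjusted_metrics(raw.sensitivity, raw.specificity, pi, opa_raw=raw.opa_raw)
    return cm, pm


def cutoff_grid(
    table: CohortTable,
    reference: str = "visual_read",
    prevalence: float | None = None,
    grid: Sequence[float] | str = "all",
    cl_threshold: float = 24.0,
) -> list[CutoffGridRow]:
    """Performance over a cutoff grid, sorted ascending.

    ``grid="all"`` uses every distinct observed value plus -inf/+inf
    sentinels (everyone screened in / everyone ruled out). Rows where a
    quantity is undefined (e.g. sensitivity 0 at the +inf sentinel) carry
    NaN in the affected fields.
    """
    values, labels = binary_reference(table, reference, cl_threshold)
    pi = labels.mean() if prevalence is None else float(prevalence)
    if isinstance(grid, str):
        if grid != "all":
            raise ValueError("grid must be a sequence of cutoffs or 'all'")
        cutoffs = np.concatenate([[-np.inf], np.unique(values), [np.inf]])
    else:
        cutoffs = np.sort(np.asarray(grid, dtype=float))
    rows: list[CutoffGridRow] = []
    for c in cutoffs:
        cm = _confusion_from_arrays(values, labels, c)
        raw = raw_metrics(cm)
        fields = _adjusted_fields(raw.sensitivity, raw.specificity, pi)
        pm = PerformanceMetrics(
            sensitivity=raw.sensitivity,
            specificity=raw.specificity,
            prevalence=pi,
            opa_raw=raw.opa_raw,
            **fields,
        )
        rows.append(CutoffGridRow(float(c), cm, pm))
    return rows


def grid_to_frame(rows: list[CutoffGridRow]) -> pd.DataFrame:
    """Cutoff grid as a flat DataFrame (supplementary-table layout)."""
    return pd.DataFrame(
        {
            "cutoff": [r.cutoff for r in rows],
            "tp": [r.confusion.tp for r in rows],
            "fn": [r.confusion.fn for r in rows],
            "fp": [r.confusion.fp for r in rows],
            "tn": [r.confusion.tn for r in rows],
            "sensitivity": [r.metrics.sensitivity for r in rows],
            "specificity": [r.metrics.specificity for r in rows],
            "ppv": [r.metrics.ppv for r in rows],
            "npv": [r.metrics.npv for r in rows],
            "opa_raw": [r.metrics.opa_raw for r in rows],
            "screen_out": [r.metrics.screen_out for r in rows],
            "additional_screening": [r.metrics.additional_screening for r in rows],
            "scans_saved": [r.metrics.scans_saved for r in rows],
        }
    )


def select_rule_out_cutoff(
    ci_table: CohortTable,
    cu_table: CohortTable,
    npv_min: float = 0.90,
    pi_ci: float = 0.6994,
    pi_cu: float = 0.1391,
    reference: str = "visual_read",
    cl_threshold: float = 24.0,
) -> float | None:
    """Largest cutoff whose adjusted NPV meets ``npv_min`` in both strata.

    Candidates are midpoints between consecutive distinct biomarker values
    pooled across both tables: any cutoff strictly between two observed
    values classifies subjects identically, so midpoints enumerate every
    achievable operating point. Maximizing the cutoff maximizes the
    screen-out rate; returns None when no cutoff qualifies.
    """
    if not 0 < npv_min < 1:
        raise ValueError("npv_min must be in (0, 1)")
    strata = [
        binary_reference(ci_table, reference, cl_threshold) + (pi_ci,),
        binary_reference(cu_table, reference, cl_threshold) + (pi_cu,),
    ]
    pooled = np.unique(np.concatenate([strata[0][0], strata[1][0]]))
    if pooled.size < 2:
        return None
    candidates = (pooled[:-1] + pooled[1:]) / 2.0
    for c in candidates[::-1]:
        ok = True
        for values, labels, pi in strata:
            below = values < c
            n_pos, n_neg = labels.sum(), (~labels).sum()
            if not below.any() or n_pos == 0 or n_neg == 0:
                ok = False
                break
            s = np.sum(labels & ~below) / n_pos
            p = np.sum(below & ~labels) / n_neg
            den = p * (1.0 - pi) + (1.0 - s) * pi
            npv = p * (1.0 - pi) / den if den > 0 else math.nan
            if not npv >= npv_min:
                ok = False
                break
        if ok:
            return float(c)
    return None


def trial_plan(n_enroll: int, sensitivity: float, specificity: float, prevalence: float) -> TrialPlan:
    """Expected screening economics for a trial enrolling ``n_enroll`` subjects.

    Without a pre-screen, every referred subject is PET-scanned until
    ``n_enroll`` amyloid positives are found (``n_enroll / pi`` scans). With
    the biomarker pre-screen only screened-in subjects are scanned; true
    positives lost below the cutoff inflate the number pre-screened by
    ``1/s``. Counts are real-valued expectations.
    """
    if n_enroll < 1:
        raise ValueError("n_enroll must be >= 1")
    pm = adjusted_metrics(sensitivity, specificity, prevalence)
    scans_without = n_enroll / prevalence
    prescreened = n_enroll / (prevalence * sensitivity)
    scans_with = prescreened * (1.0 - pm.screen_out)
    return TrialPlan(
        n_enroll=n_enroll,
        scans_without=scans_without,
        prescreened=prescreened,
        scans_with=scans_with,
        saved_fraction=1.0 - scans_with / scans_without,
    )


def mixture_trial_sweep(
    n_enroll: int,
    ci_params: tuple[float, float, float],
    cu_params: tuple[float, float, float],
    fractions: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Scan savings across CI:CU referral mixtures.

    ``ci_params``/``cu_params`` are (sensitivity, specificity, prevalence)
    per stratum; ``fractions`` are the CI shares of the referred population
    (default 0 to 1 in steps of 0.05), bracketing the pure-population
    endpoints, where the sweep equals the per-stratum ``trial_plan``.
    """
    if fractions is None:
        fractions = np.linspace(0.0, 1.0, 21)
    s_ci, p_ci, pi_ci = ci_params
    s_cu, p_cu, pi_cu = cu_params
    so_ci = adjusted_metrics(s_ci, p_ci, pi_ci).screen_out
    so_cu = adjusted_metrics(s_cu, p_cu, pi_cu).screen_out
    rows = []
    for f in fractions:
        pi_mix = f * pi_ci + (1.0 - f) * pi_cu
        enroll_rate = f * s_ci * pi_ci + (1.0 - f) * s_cu * pi_cu
        screen_in = f * (1.0 - so_ci) + (1.0 - f) * (1.0 - so_cu)
        scans_without = n_enroll / pi_mix
        prescreened = n_enroll / enroll_rate
        scans_with = prescreened * screen_in
        rows.append(
            {
                "fraction_ci": float(f),
                "scans_without": scans_without,
                "prescreened": prescreened,
                "scans_with": scans_with,
                "saved_fraction": 1.0 - scans_with / scans_without,
            }
        )
    return pd.DataFrame(rows)


def sens_spec_curves(
    table: CohortTable,
    reference: str = "visual_read",
    cl_threshold: float = 24.0,
) -> pd.DataFrame:
    """Sensitivity and specificity vs biomarker percentile (plot data).

    Grid point k (percentile = fraction of subjects with value <= the k-th
    distinct value) corresponds to cutoffs in the half-open interval above
    that value: sensitivity is the positive fraction screened in above it,
    specificity the negative fraction ruled out at or below it. Percentile
    0 gives sensitivity 1; percentile 1 gives specificity 1.
    """
    values, labels = binary_reference(table, reference, cl_threshold)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one record of each reference class")
    y, inv = np.unique(values, return_inverse=True)
    counts = np.bincount(inv)
    pos_counts = np.bincount(inv, weights=labels.astype(float))
    cum = np.cumsum(counts) / values.size
    cum_pos = np.cumsum(pos_counts)
    cum_neg = np.cumsum(counts - pos_counts)
    return pd.DataFrame(
        {
            "percentile": np.concatenate([[0.0], cum]),
            "value": np.concatenate([[np.nan], y]),
            "sensitivity": np.concatenate([[1.0], (n_pos - cum_pos) / n_pos]),
            "specificity": np.concatenate([[0.0], cum_neg / n_neg]),
        }
    )
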