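"""Predictiveness-curve estimation: the integrated risk plot's data layer.

The predictiveness curve reports the risk of amyloid positivity,
R(v) = P(D = POS | Y at quantile v), as a function of the biomarker's risk
percentile v, together with the induced screening quantities
PPV(v) = P(D | Y > quantile v) and 1 - NPV(v) = P(D | Y <= quantile v). Two
estimators are provided:

* ``empirical`` — conditional frequencies at each distinct biomarker value;
* ``monotone`` — the isotonic (pool-adjacent-violators) fit of the binary
  outcome on the biomarker, the nonparametric maximum-likelihood estimator
  under the assumption that risk is non-decreasing in the biomarker.

When the sample's case fraction is unrepresentative, curves can be computed
at an externally specified prevalence pi via case/control importance
re-weighting (cases weighted pi/pi_hat, controls (1-pi)/(1-pi_hat)), which
reproduces prevalence-adjusted PPV/NPV exactly at every cutoff.

The percentile grid has one point per distinct biomarker value plus the 0
endpoint, so the cutoff <-> percentile mapping stays invertible; tied values
share a grid point. At every grid point the mixture identity
``v * (1-NPV)(v) + (1-v) * PPV(v) = pi`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .cohort import CohortTable, binary_reference
from .roc import as_bool_labels


@dataclass(frozen=True)
class RiskCurve:
    """Risk, PPV, and 1-NPV on a shared percentile grid.

    ``percentiles`` has K+1 entries starting at 0; entry k >= 1 is the
    (weighted) population fraction with biomarker <= ``values[k-1]``.
    ``risk[k]``, ``ppv[k]`` and ``one_minus_npv[k]`` are aligned with the
    grid; ``mass[k-1]`` is the weighted population share of the k-th
    distinct value.
    """

    percentiles: np.ndarray
    risk: np.ndarray
    ppv: np.ndarray
    one_minus_npv: np.ndarray
    values: np.ndarray  # distinct biomarker values, ascending
    mass: np.ndarray
    estimator: str
    prevalence: float

    def mean_risk(self) -> float:
        """Mass-weighted mean of the fitted risk; equals the prevalence."""
        return float(np.sum(self.mass * self.risk[1:]))

    def _index_at_cutoff(self, cutoff: float) -> int:
        # grid point whose "above" side is exactly {Y >= cutoff}
        return int(np.searchsorted(self.values, cutoff, side="left"))

    def percentile_at_cutoff(self, cutoff: float) -> float:
        """Weighted fraction of the population with biomarker < cutoff."""
        return float(self.percentiles[self._index_at_cutoff(cutoff)])

    def at_cutoff(self, cutoff: float) -> dict[str, float]:
        """Curve quantities at a biomarker cutoff (rule-out below, screen-in at/above)."""
        j = self._index_at_cutoff(cutoff)
        return {
            "percentile": float(self.percentiles[j]),
            "risk": float(self.risk[j]),
            "ppv": float(self.ppv[j]),
            "one_minus_npv": float(self.one_minus_npv[j]),
        }


def _curve_from_arrays(values, labels, prevalence, estimator: str) -> RiskCurve:
    values = np.asarray(values, dtype=float)
    labels = as_bool_labels(labels)
    if values.size == 0:
        raise ValueError("empty input")
    pi_hat = labels.mean()
    if not 0 < pi_hat < 1:
        raise ValueError("need at least one record of each reference class")
    pi = pi_hat if prevalence is None else float(prevalence)
    if not 0 < pi < 1:
        raise ValueError("prevalence must be in (0, 1)")

    w = np.where(labels, pi / pi_hat, (1.0 - pi) / (1.0 - pi_hat))
    y, inv = np.unique(values, return_inverse=True)
    total_w = w.sum()
    mass = np.bincount(inv, weights=w) / total_w
    if estimator == "empirical":
        pos_mass = np.bincount(inv, weights=w * labels) / total_w
        r = pos_mass / mass
    elif estimator == "monotone":
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(values, labels.astype(float), sample_weight=w)
        r = np.asarray(iso.predict(y), dtype=float)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    cum_mass = np.cumsum(mass)
    cum_mass[-1] = 1.0
    cum_pos = np.cumsum(mass * r)
    total_pos = cum_pos[-1]

    percentiles = np.concatenate([[0.0], cum_mass])
    one_minus_npv = np.concatenate([[0.0], cum_pos / cum_mass])
    rem_mass = 1.0 - np.concatenate([[0.0], cum_mass])
    rem_pos = total_pos - np.concatenate([[0.0], cum_pos])
    ppv = np.empty_like(percentiles)
    ppv[:-1] = rem_pos[:-1] / rem_mass[:-1]
    ppv[-1] = r[-1]  # limit from above the top value
    risk = np.concatenate([[r[0]], r])

    clip = lambda a: np.clip(a, 0.0, 1.0)  # noqa: E731 - guard float wobble only
    return RiskCurve(
        percentiles=percentiles,
        risk=clip(risk),
        ppv=clip(ppv),
        one_minus_npv=clip(one_minus_npv),
        values=y,
        mass=mass,
        estimator=estimator,
        prevalence=pi,
    )


def empirical_risk_curve(
    table: CohortTable,
    reference: str = "visual_read",
    prevalence: float | None = None,
    cl_threshold: float = 24.0,
) -> RiskCurve:
    """Nonparametric predictiveness curve (conditional frequencies).

    ``prevalence=None`` uses the sample's observed case fraction; a float in
    (0, 1) re-weights cases/controls to that prevalence.
    """
    values, labels = binary_reference(table, reference, cl_threshold)
    return _curve_from_arrays(values, labels, prevalence, "empirical")


def monotone_risk_curve(
    table: CohortTable,
    reference: str = "visual_read",
    prevalence: float | None = None,
    cl_threshold: float = 24.0,
) -> RiskCurve:
    """Monotone (isotonic / PAVA) predictiveness curve.

    The fitted risk is non-decreasing in the biomarker and preserves the
    weighted case fraction, so 1-NPV <= prevalence <= PPV holds at every
    interior grid point.
    """
    values, labels = binary_reference(table, reference, cl_threshold)
    return _curve_from_arrays(values, labels, prevalence, "monotone")


def export_integrated_risk(
    empirical: RiskCurve,
    monotone: RiskCurve,
    cutoff: float,
    path=None,
) -> pd.DataFrame:
    """Long-format plot data for the integrated risk figure.

    Emits (percentile, series, value) rows for both estimators' risk, PPV
    and 1-NPV series, plus reference series: the prevalence horizontal line,
    the perfect-assay step (risk 0 below percentile 1-pi, 1 above), and the
    rule-out cutoff's percentile marker. Writes TSV when ``path`` is given.
    """
    if not np.array_equal(empirical.values, monotone.values):
        raise ValueError("curves must share the same biomarker grid")
    lo, hi = empirical.values[0], empirical.values[-1]
    if not lo <= cutoff <= hi:
        raise ValueError(f"cutoff {cutoff} outside observed range [{lo}, {hi}]")

    rows: list[tuple[float, str, float]] = []
    for curve in (empirical, monotone):
        for name, series in (
            ("risk", curve.risk),
            ("ppv", curve.ppv),
            ("one_minus_npv", curve.one_minus_npv),
        ):
            rows += [
                (float(p), f"{name}_{curve.estimator}", float(v))
                for p, v in zip(curve.percentiles, series)
            ]
    pi = empirical.prevalence
    rows += [(0.0, "prevalence", pi), (1.0, "prevalence", pi)]
    rows += [
        (0.0, "perfect", 0.0),
        (1.0 - pi, "perfect", 0.0),
        (1.0 - pi, "perfect", 1.0),
        (1.0, "perfect", 1.0),
    ]
    vc = empirical.percentile_at_cutoff(cutoff)
    rows.append((vc, "cutoff", vc))

    frame = pd.DataFrame(rows, columns=["percentile", "series", "value"])
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
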