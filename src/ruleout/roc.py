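"""ROC/AUC estimation with DeLong confidence intervals and forest tables.

The AUC is the Mann-Whitney two-sample statistic with midrank tie handling,
P(Y+ > Y-) + 0.5 P(Y+ = Y-), equal to the trapezoidal area under the
empirical ROC curve. Confidence intervals use DeLong's nonparametric
structural-components variance with a normal approximation, clipped to
[0, 1]; a stratified-bootstrap percentile interval is provided as an
independent cross-check utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    level: float
    n_pos: int
    n_neg: int
    label: str = ""
    degenerate: bool = False  # zero DeLong variance (e.g. perfect separation)


def as_bool_labels(labels) -> np.ndarray:
    """Normalize POS/NEG strings, {0,1} ints, or booleans to a bool array."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    if arr.dtype.kind in "US":
        bad = set(np.unique(arr)) - {"POS", "NEG"}
        if bad:
            raise ValueError(f"labels must be POS/NEG, got {sorted(bad)}")
        return arr == "POS"
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise ValueError("numeric labels must be 0/1")
    return arr.astype(bool)


def _split(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    mask = as_bool_labels(labels)
    if values.shape != mask.shape:
        raise ValueError("values and labels must have equal length")
    pos, neg = values[mask], values[~mask]
    if pos.size == 0:
        raise ValueError("no POS records: AUC undefined")
    if neg.size == 0:
        raise ValueError("no NEG records: AUC undefined")
    return pos, neg


def empirical_auc(values, labels) -> float:
    """Mann-Whitney AUC with midrank ties; area under the empirical ROC."""
    pos, neg = _split(values, labels)
    m, n = pos.size, neg.size
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def _structural_components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_variance(values, labels) -> float:
    """DeLong structural-components variance of the empirical AUC."""
    pos, neg = _split(values, labels)
    _, v10, v01 = _structural_components(pos, neg)
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    return float(s10 / pos.size + s01 / neg.size)


def delong_ci(values, labels, level: float = 0.95, label: str = "") -> AucEstimate:
    """AUC with a DeLong normal-approximation interval clipped to [0, 1].

    Zero estimated variance (e.g. perfect separation) yields a degenerate
    [auc, auc] interval flagged via ``degenerate`` with a warning.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    pos, neg = _split(values, labels)
    auc, v10, v01 = _structural_components(pos, neg)
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    var = s10 / pos.size + s01 / neg.size
    if var <= 0:
        warnings.warn(
            f"zero DeLong variance for {label or 'cohort'}: degenerate interval",
            stacklevel=2,
        )
        return AucEstimate(auc, auc, auc, level, pos.size, neg.size, label, degenerate=True)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return AucEstimate(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        level=level,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        label=label,
    )


def forest_table(cohorts, pooled_label: str = "Combined", level: float = 0.95) -> list[AucEstimate]:
    """Per-cohort AUC estimates plus a pooled estimate on concatenated subjects.

    ``cohorts`` is an iterable of ``(label, values, labels)``. The pooled
    ("combined") estimate treats all subjects as one sample rather than
    meta-analytically weighting the per-cohort AUCs.
    """
    estimates: list[AucEstimate] = []
    all_values: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for label, values, labels in cohorts:
        try:
            estimates.append(delong_ci(values, labels, level=level, label=str(label)))
        except ValueError as err:
            raise ValueError(f"cohort {label!r}: {err}") from err
        all_values.append(np.asarray(values, dtype=float))
        all_labels.append(as_bool_labels(labels))
    if not estimates:
        raise ValueError("no cohorts supplied")
    pooled = delong_ci(
        np.concatenate(all_values), np.concatenate(all_labels), level=level, label=pooled_label
    )
    estimates.append(pooled)
    return estimates


def forest_to_frame(estimates: list[AucEstimate]) -> pd.DataFrame:
    """Forest table as a DataFrame (label, n_pos, n_neg, auc, ci_low, ci_high)."""
    return pd.DataFrame(
        {
            "label": [e.label for e in estimates],
            "n_pos": [e.n_pos for e in estimates],
            "n_neg": [e.n_neg for e in estimates],
            "auc": [e.auc for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
        }
    )


def bootstrap_auc_ci(
    values, labels, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Stratified-bootstrap percentile interval for the AUC (cross-check).

    Positives and negatives are resampled separately, preserving class
    sizes; vectorized over replicates.
    """
    pos, neg = _split(values, labels)
    m, n = pos.size, neg.size
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    batch = max(1, int(2_000_000 / (m + n)))
    done = 0
    while done < n_boot:
        b = min(batch, n_boot - done)
        pos_s = pos[rng.integers(0, m, size=(b, m))]
        neg_s = neg[rng.integers(0, n, size=(b, n))]
        ranks = stats.rankdata(np.concatenate([pos_s, neg_s], axis=1), axis=1)
        u = ranks[:, :m].sum(axis=1) - m * (m + 1) / 2.0
        aucs[done : done + b] = u / (m * n)
        done += b
    lo, hi = np.quantile(aucs, [0.5 - level / 2.0, 0.5 + level / 2.0])
    return float(lo), float(hi)
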