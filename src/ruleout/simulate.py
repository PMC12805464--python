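"""Synthetic cohort generation calibrated to published stratum summaries.

Plasma pTau217 concentrations are positive and right-skewed (the published
stratum medians sit below the means throughout), so each stratum — a
(cognitive status, amyloid status) cell — is modelled as a lognormal whose
log-scale parameters are moment-matched to the stratum's printed mean and
SD. Amyloid prevalence is controlled through the stratum sample sizes, and
draws below the assay LLoQ are floored there and flagged, mirroring how the
real data are reported.

Default calibration (mean pg/mL, SD pg/mL, n):

* cognitively impaired, amyloid-positive:   0.835, 0.381, 394
* cognitively impaired, amyloid-negative:   0.361, 0.294, 144
* cognitively unimpaired, amyloid-positive: 0.516, 0.235, 224
* cognitively unimpaired, amyloid-negative: 0.220, 0.157, 1386

Moment matching is applied to the observed (already floored) summaries, so
censoring the matched draws again is a small, documented approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import DEFAULT_LLOQ, CohortTable, SubjectRecord


@dataclass(frozen=True)
class StratumSpec:
    """One (cognitive status, amyloid status) cell of the mixture."""

    cognitive_status: str  # "CI" or "CU"
    amyloid_status: str  # "POS" or "NEG"
    target_mean: float  # pg/mL
    target_sd: float  # pg/mL
    n: int

    def __post_init__(self) -> None:
        if self.target_mean <= 0:
            raise ValueError("target_mean must be > 0")
        if self.target_sd < 0:
            raise ValueError("target_sd must be >= 0")
        if self.n < 0:
            raise ValueError("n must be >= 0")


#: Default cognitively-impaired strata (visual-read positive/negative).
CI_STRATA = (
    StratumSpec("CI", "POS", 0.835, 0.381, 394),
    StratumSpec("CI", "NEG", 0.361, 0.294, 144),
)

#: Default cognitively-unimpaired strata.
CU_STRATA = (
    StratumSpec("CU", "POS", 0.516, 0.235, 224),
    StratumSpec("CU", "NEG", 0.220, 0.157, 1386),
)


@dataclass(frozen=True)
class GeneratorConfig:
    strata: tuple[StratumSpec, ...]
    lloq: float = DEFAULT_LLOQ
    seed: int = 0
    cohort_label: str = "SYNTH"

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ValueError("lloq must be > 0")
        if sum(s.n for s in self.strata) < 1:
            raise ValueError("total n must be >= 1")

    @property
    def prevalence(self) -> float:
        """Amyloid-positive fraction implied by the stratum sizes."""
        total = sum(s.n for s in self.strata)
        pos = sum(s.n for s in self.strata if s.amyloid_status == "POS")
        return pos / total


def default_ci_config(seed: int = 0, lloq: float = DEFAULT_LLOQ) -> GeneratorConfig:
    return GeneratorConfig(CI_STRATA, lloq=lloq, seed=seed, cohort_label="SYNTH-CI")


def default_cu_config(seed: int = 0, lloq: float = DEFAULT_LLOQ) -> GeneratorConfig:
    return GeneratorConfig(CU_STRATA, lloq=lloq, seed=seed, cohort_label="SYNTH-CU")


def moment_match_lognormal(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal with the given mean and SD.

    sigma^2 = ln(1 + (sd/mean)^2) and mu = ln(mean) - sigma^2 / 2; the
    matched distribution has the supplied arithmetic mean and SD exactly.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd <= 0:
        raise ValueError("sd must be > 0; a zero-SD stratum is a point mass, not a lognormal")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def analytic_auc(spec_pos: StratumSpec, spec_neg: StratumSpec) -> float:
    """Closed-form AUC between two moment-matched lognormal strata.

    P(Y+ > Y-) = Phi((mu+ - mu-) / sqrt(sigma+^2 + sigma-^2)), since the
    log-ratio of two independent lognormals is normal.
    """
    mu_p, sg_p = moment_match_lognormal(spec_pos.target_mean, spec_pos.target_sd)
    mu_n, sg_n = moment_match_lognormal(spec_neg.target_mean, spec_neg.target_sd)
    return float(stats.norm.cdf((mu_p - mu_n) / np.hypot(sg_p, sg_n)))


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw one synthetic cohort.

    Each record's visual read is its stratum's amyloid status; biomarker
    values come from the stratum's moment-matched lognormal and are floored
    at the LLoQ with the BLOQ flag set. Every stratum uses its own RNG
    stream derived from (seed, stratum index), so resizing one stratum does
    not perturb the draws of the others. Deterministic under a fixed seed.
    """
    records: list[SubjectRecord] = []
    for idx, spec in enumerate(config.strata):
        rng = np.random.default_rng([config.seed, idx])
        if spec.n == 0:
            continue
        if spec.target_sd == 0:
            draws = np.full(spec.n, spec.target_mean)
        else:
            mu, sigma = moment_match_lognormal(spec.target_mean, spec.target_sd)
            draws = rng.lognormal(mean=mu, sigma=sigma, size=spec.n)
        bloq = draws < config.lloq
        values = np.where(bloq, config.lloq, draws)
        for i in range(spec.n):
            records.append(
                SubjectRecord(
                    subject_id=f"{config.cohort_label}-{idx}-{i:05d}",
                    cohort=config.cohort_label,
                    cognitive_status=spec.cognitive_status,
                    ptau217=float(values[i]),
                    bloq=bool(bloq[i]),
                    visual_read=spec.amyloid_status,
                )
            )
    return CohortTable(
        records,
        lloq=config.lloq,
        provenance=f"generate_cohort(seed={config.seed}, label={config.cohort_label})",
    )
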