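import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ruleout import CohortTable, SubjectRecord


def make_table(values, labels, lloq=0.0693, status="CI", cohort="TEST", centiloids=None):
    """Build a CohortTable from parallel value/label sequences."""
    records = []
    for i, (v, lab) in enumerate(zip(values, labels)):
        vr = lab if isinstance(lab, str) or lab is None else ("POS" if lab else "NEG")
        records.append(
            SubjectRecord(
                subject_id=f"S{i:04d}",
                cohort=cohort,
                cognitive_status=status,
                ptau217=float(max(v, lloq)),
                bloq=v < lloq,
                visual_read=vr,
                centiloid=None if centiloids is None else centiloids[i],
            )
        )
    return CohortTable(records, lloq=lloq)


@pytest.fixture
def table2_ci_cohort():
    """Cohort engineered to have Table-2's CI confusion matrix at cutoff 0.189.

    390 true positives and 102 false positives sit above the cutoff; 4 false
    negatives and 42 true negatives sit below it.
    """
    values = [0.5] * 390 + [0.1] * 4 + [0.5] * 102 + [0.1] * 42
    labels = [True] * 394 + [False] * 144
    return make_table(values, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
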