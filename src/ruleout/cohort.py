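"""Cohort data model and I/O for plasma-biomarker screening evaluation.

A cohort table holds one row per participant: a continuous plasma biomarker
concentration (pTau217, pg/mL), the amyloid-PET visual read used as the
binary reference standard, and optionally a Centiloid (CL) value supporting
alternative quantitative definitions of amyloid positivity. Measurements
below the assay's lower limit of quantification (LLoQ) are floored at the
observed LLoQ and flagged, so the data floor of a loaded table always equals
the LLoQ.

CSV dialect: comma-separated, UTF-8, header required (case-insensitive
column names); ``""`` or ``"NA"`` denote missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Observed lower limit of quantification of the pTau217 assay, pg/mL.
DEFAULT_LLOQ = 0.0693

REQUIRED_COLUMNS = ("subject_id", "cohort", "cognitive_status", "ptau217", "visual_read")
OPTIONAL_COLUMNS = ("bloq", "centiloid", "age", "sex")
_COLUMN_ORDER = REQUIRED_COLUMNS[:4] + ("bloq", "visual_read", "centiloid", "age", "sex")

_MISSING_TOKENS = {"", "NA"}
_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f"}


class CohortSchemaError(ValueError):
    """The CSV header does not match the cohort schema."""


class RowValidationError(ValueError):
    """A row holds a value that cannot enter the analysis."""


@dataclass
class SubjectRecord:
    """One participant.

    ``visual_read`` is the binary amyloid-PET reference ("POS"/"NEG");
    ``centiloid`` the optional quantitative amyloid burden (CL units).
    ``bloq`` marks a biomarker measurement below the LLoQ, in which case
    ``ptau217`` equals the LLoQ substitution value.
    """

    subject_id: str
    cohort: str
    cognitive_status: str  # "CI" or "CU"
    ptau217: float  # pg/mL, > 0
    bloq: bool = False
    visual_read: str | None = None  # "POS", "NEG", or None
    centiloid: float | None = None
    age: float | None = None
    sex: str | None = None  # "F", "M", or None


@dataclass
class CohortTable:
    """An ordered collection of subject records sharing one LLoQ."""

    records: list[SubjectRecord]
    lloq: float = DEFAULT_LLOQ
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ValueError("lloq must be > 0")
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_id in seen:
                raise ValueError(f"duplicate subject_id {rec.subject_id!r}")
            seen.add(rec.subject_id)
            if rec.ptau217 <= 0:
                raise ValueError(f"subject {rec.subject_id!r}: ptau217 must be > 0")
            if rec.bloq and rec.ptau217 != self.lloq:
                raise ValueError(
                    f"subject {rec.subject_id!r}: BLOQ record must carry the LLoQ value"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SubjectRecord:
        return self.records[i]

    def ptau(self) -> np.ndarray:
        return np.array([r.ptau217 for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": r.subject_id,
                "cohort": r.cohort,
                "cognitive_status": r.cognitive_status,
                "ptau217": r.ptau217,
                "bloq": r.bloq,
                "visual_read": r.visual_read,
                "centiloid": r.centiloid,
                "age": r.age,
                "sex": r.sex,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(_COLUMN_ORDER))


def _parse_missing(token: str) -> str | None:
    token = token.strip()
    return None if token in _MISSING_TOKENS else token


def _parse_bool(token: str, row: int) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS or low in {t.lower() for t in _MISSING_TOKENS}:
        return False
    raise RowValidationError(f"row {row}: cannot parse bloq flag {token!r}")


def read_cohort_csv(path, lloq: float = DEFAULT_LLOQ) -> CohortTable:
    """Load and validate a cohort CSV.

    Values below ``lloq`` (and rows carrying an explicit ``bloq`` flag) are
    substituted with ``lloq`` and flagged, reproducing the observed data
    floor. Row order is preserved.

    Raises
    ------
    CohortSchemaError
        If a required column is absent (the message names it).
    RowValidationError
        If ``ptau217`` is missing, non-numeric, or non-positive, or an
        enum-valued field holds an unknown token (the message carries the
        0-based data row index).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[SubjectRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        raw = row["ptau217"].strip()
        if raw in _MISSING_TOKENS:
            raise RowValidationError(f"row {i}: ptau217 is missing")
        try:
            value = float(raw)
        except ValueError:
            raise RowValidationError(f"row {i}: ptau217 {raw!r} is not numeric") from None
        if not math.isfinite(value) or value <= 0:
            raise RowValidationError(f"row {i}: ptau217 must be positive, got {raw!r}")

        status = row["cognitive_status"].strip().upper()
        if status not in {"CI", "CU"}:
            raise RowValidationError(f"row {i}: cognitive_status must be CI or CU, got {status!r}")

        vr = _parse_missing(row["visual_read"])
        if vr is not None:
            vr = vr.upper()
            if vr not in {"POS", "NEG"}:
                raise RowValidationError(f"row {i}: visual_read must be POS/NEG/missing")

        cl_tok = _parse_missing(row.get("centiloid", ""))
        centiloid = float(cl_tok) if cl_tok is not None else None
        age_tok = _parse_missing(row.get("age", ""))
        age = float(age_tok) if age_tok is not None else None
        sex = _parse_missing(row.get("sex", ""))
        if sex is not None:
            sex = sex.upper()
            if sex not in {"F", "M"}:
                raise RowValidationError(f"row {i}: sex must be F/M/missing")

        bloq = _parse_bool(row.get("bloq", ""), i)
        if value < lloq:
            bloq = True
        if bloq:
            value = lloq

        records.append(
            SubjectRecord(
                subject_id=row["subject_id"].strip(),
                cohort=row["cohort"].strip(),
                cognitive_status=status,
                ptau217=value,
                bloq=bloq,
                visual_read=vr,
                centiloid=centiloid,
                age=age,
                sex=sex,
            )
        )
    return CohortTable(records, lloq=lloq, provenance=str(path))


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a cohort table; a subsequent read round-trips field-wise."""
    df = table.to_frame()
    df["bloq"] = np.where(df["bloq"].astype(bool), "true", "false")
    df.to_csv(path, index=False, na_rep="")


def classify_centiloid(cl: float | None, threshold: float) -> str:
    """Binary amyloid classification on the Centiloid scale.

    POS iff ``cl >= threshold`` (closed lower bound); conventional
    thresholds are 24 and 40 CL.
    """
    if cl is None or (isinstance(cl, float) and math.isnan(cl)):
        raise ValueError("Centiloid value missing: record is unclassifiable")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return "POS" if cl >= threshold else "NEG"


def concordance_opa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Overall percent agreement between two binary label sequences.

    Missing pairs must be dropped by the caller; the sequences are compared
    position-wise.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("cannot compute concordance on empty input")
    return float(np.mean(a == b))


def linear_suvr_to_centiloid(suvr: float, slope: float, intercept: float) -> float:
    """Generic linear SUVr -> Centiloid map, ``slope * suvr + intercept``.

    Tracer-specific calibration coefficients are supplied by the user.
    """
    if slope == 0:
        raise ValueError("slope must be non-zero")
    return slope * suvr + intercept


def binary_reference(
    table: CohortTable,
    reference: str = "visual_read",
    cl_threshold: float = 24.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (biomarker values, boolean amyloid labels) for one reference.

    ``reference`` is ``"visual_read"`` or ``"centiloid"`` (positivity at
    ``cl_threshold``). Records missing the chosen reference are excluded.
    """
    values: list[float] = []
    labels: list[bool] = []
    if reference == "visual_read":
        for r in table:
            if r.visual_read is not None:
                values.append(r.ptau217)
                labels.append(r.visual_read == "POS")
    elif reference == "centiloid":
        for r in table:
            if r.centiloid is not None:
                values.append(r.ptau217)
                labels.append(classify_centiloid(r.centiloid, cl_threshold) == "POS")
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if not values:
        raise ValueError(f"no records carry a non-missing {reference} reference")
    return np.asarray(values, dtype=float), np.asarray(labels, dtype=bool)
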