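"""Domain types, validation and CSV I/O for long-format cortical morphometrics.

The canonical table has one row per subject x hemisphere x region of interest
(ROI) and carries the three primary surface variables produced by a
FreeSurfer-style extraction: average cortical thickness ``T`` (mm), total pial
area ``A_T`` (mm^2) and exposed hull area ``A_E`` (mm^2), optionally a local
gyrification index.  This module is the single place where unit and vocabulary
conventions are fixed:

* units are mm / mm^2, ages in years;
* hemispheres are ``left`` / ``right`` and analysed as separate observations;
* ROIs are ``hemisphere``, ``frontal``, ``temporal``, ``parietal``,
  ``occipital`` (``lateral`` is accepted on input as an alias of
  ``parietal``);
* CSV dialect: comma separated, UTF-8, ``.`` decimal, header required,
  column names case-insensitive on read.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from numbers import Real
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HEMISPHERES = ("left", "right")
ROIS = ("hemisphere", "frontal", "temporal", "parietal", "occipital")
ROI_ALIASES = {"lateral": "parietal"}
SEXES = ("F", "M", "unknown")
AGE_RANGE = (0.0, 120.0)

REQUIRED_COLUMNS = (
    "subject_id",
    "sample",
    "group",
    "sex",
    "age_years",
    "hemisphere",
    "roi",
    "avg_thickness_mm",
    "total_area_mm2",
    "exposed_area_mm2",
)
#: Canonical on-disk column order.
CANONICAL_COLUMNS = REQUIRED_COLUMNS + ("local_gi",)

#: The three primary measurement columns, in conventional order (T, A_T, A_E).
PRIMARY_VARIABLES = ("avg_thickness_mm", "total_area_mm2", "exposed_area_mm2")


class MorphValidationError(ValueError):
    """Raised on fatal table problems (e.g. a missing required column)."""


@dataclass(frozen=True)
class AgeInterval:
    """An age range [low, high] in years; used when a cohort releases only
    age brackets, in which case the interval midpoint stands in for the age."""

    low_years: float
    high_years: float

    def __post_init__(self) -> None:
        if not (self.low_years < self.high_years):
            raise ValueError(
                f"AgeInterval requires low < high, got [{self.low_years}, {self.high_years}]"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low_years + self.high_years)


def resolve_age(age) -> float:
    """Return an exact age in years.

    Exact ages pass through unchanged; an :class:`AgeInterval` maps to its
    midpoint (e.g. the bracket [22, 36] resolves to 29.0).
    """
    if isinstance(age, AgeInterval):
        return age.midpoint
    if isinstance(age, Real):
        return float(age)
    raise TypeError(f"cannot resolve age from {type(age).__name__}")


@dataclass(frozen=True)
class RepeatedMeasureSet:
    """Repeated measurements of one variable on one subject under identical
    conditions (e.g. back-to-back structural acquisitions)."""

    subject_id: str
    variable: str
    values: tuple

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if any(not math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite repeated measure for {self.subject_id}")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MorphRecord:
    """One observation: a (subject, hemisphere, ROI) triple with its
    morphometrics.  ``avg_thickness_mm``/``total_area_mm2``/``exposed_area_mm2``
    must be strictly positive so that base-10 logs exist."""

    subject_id: str
    sample: str
    group: str
    sex: str
    age_years: float
    hemisphere: str
    roi: str
    avg_thickness_mm: float
    total_area_mm2: float
    exposed_area_mm2: float
    local_gi: float | None = None

    def hard_problems(self) -> list[str]:
        """Violations that always reject the record."""
        out = []
        if not self.subject_id:
            out.append("empty subject_id")
        if not self.sample:
            out.append("empty sample")
        if not self.group:
            out.append("empty group")
        if self.sex not in SEXES:
            out.append(f"unknown sex {self.sex!r}")
        if self.hemisphere not in HEMISPHERES:
            out.append(f"unknown hemisphere {self.hemisphere!r}")
        if self.roi not in ROIS:
            out.append(f"unknown roi {self.roi!r}")
        if not (AGE_RANGE[0] <= self.age_years <= AGE_RANGE[1]):
            out.append(f"age {self.age_years} outside {AGE_RANGE}")
        for name in PRIMARY_VARIABLES:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                out.append(f"non-positive area or thickness: {name}={v}")
        if self.local_gi is not None and not (
            math.isfinite(self.local_gi) and self.local_gi > 0
        ):
            out.append(f"non-positive local_gi={self.local_gi}")
        return out

    def soft_problems(self) -> list[str]:
        """A folded surface must exceed its hull, so A_T >= A_E for the whole
        hemisphere.  For lobes curvature-corrected areas may legitimately
        deviate, so there the check is only a warning either way."""
        out = []
        if (
            self.roi == "hemisphere"
            and math.isfinite(self.total_area_mm2)
            and math.isfinite(self.exposed_area_mm2)
            and 0 < self.total_area_mm2 < self.exposed_area_mm2
        ):
            out.append(
                f"total area {self.total_area_mm2} below exposed area "
                f"{self.exposed_area_mm2} for hemisphere ROI"
            )
        return out


@dataclass
class ValidationReport:
    n_input: int = 0
    n_valid: int = 0
    rejected: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    @property
    def empty(self) -> bool:
        return not self.rejected and not self.warnings

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _normalise_row(row: dict) -> dict:
    """Map a raw CSV row onto MorphRecord fields (case/alias normalisation)."""
    sex = str(row.get("sex", "") or "").strip()
    sex = {"f": "F", "m": "M", "": "unknown"}.get(sex.lower(), sex)
    if sex not in SEXES and sex.lower() in ("unknown", "u", "nan"):
        sex = "unknown"
    roi = str(row.get("roi", "") or "").strip().lower()
    roi = ROI_ALIASES.get(roi, roi)
    gi = row.get("local_gi", None)
    if gi is not None and (gi == "" or (isinstance(gi, float) and math.isnan(gi))):
        gi = None
    out = dict(
        subject_id=str(row.get("subject_id", "") or "").strip(),
        sample=str(row.get("sample", "") or "").strip(),
        group=str(row.get("group", "") or "").strip(),
        sex=sex,
        hemisphere=str(row.get("hemisphere", "") or "").strip().lower(),
        roi=roi,
        local_gi=None if gi is None else float(gi),
    )
    for name in ("age_years",) + tuple(PRIMARY_VARIABLES):
        try:
            out[name] = float(row.get(name))
        except (TypeError, ValueError):
            out[name] = math.nan
    return out


def validate_frame(df: pd.DataFrame, strict: bool = True):
    """Validate a raw table; return ``(records, report)``.

    Rows violating hard invariants are rejected into the report in both
    modes; ``strict`` additionally rejects hemisphere rows with A_T < A_E
    (lenient mode only warns about them).  Validation is row-local, hence
    order independent up to the row indices quoted in the report.
    """
    cols = {str(c).strip().lower(): c for c in df.columns}
    missing = [c for c in REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise MorphValidationError(f"missing required column(s): {', '.join(missing)}")

    report = ValidationReport(n_input=len(df))
    records: list[MorphRecord] = []
    for idx, raw in zip(df.index, df.to_dict("records")):
        row = {k: raw.get(cols.get(k)) for k in cols}
        try:
            rec = MorphRecord(**_normalise_row(row))
        except (TypeError, ValueError) as exc:  # pragma: no cover - defensive
            report.rejected.append({"row": int(idx), "reason": str(exc)})
            continue
        hard = rec.hard_problems()
        soft = rec.soft_problems()
        if hard or (strict and soft):
            report.rejected.append({"row": int(idx), "reason": "; ".join(hard + soft)})
            continue
        for msg in soft:
            report.warnings.append({"row": int(idx), "message": msg})
        records.append(rec)
    report.n_valid = len(records)
    if not strict and report.n_rejected:
        logger.warning("dropped %d invalid row(s)", report.n_rejected)
    return records, report


def read_morph_table(path, strict: bool = True):
    """Read a morphometrics CSV; return ``(records, report)``.

    A missing required column is fatal; per-row invariant violations are
    collected in the :class:`ValidationReport`.
    """
    df = pd.read_csv(path)
    return validate_frame(df, strict=strict)


def records_to_frame(records: Iterable[MorphRecord]) -> pd.DataFrame:
    """Records -> canonical DataFrame; ``local_gi`` is omitted when absent
    from every record."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    if df["local_gi"].isna().all():
        df = df.drop(columns=["local_gi"])
    return df


def frame_to_records(df: pd.DataFrame, strict: bool = True):
    return validate_frame(df, strict=strict)


def write_morph_table(records, path) -> None:
    """Write records (or an equivalent DataFrame) to CSV.

    Values are formatted with 12 significant digits so that
    ``read_morph_table(write_morph_table(x))`` round-trips losslessly for all
    practical purposes (field-by-field agreement well below 1e-9 relative).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.12g")


def as_frame(data) -> pd.DataFrame:
    """Accept either a DataFrame or a MorphRecord collection."""
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(list(data))
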