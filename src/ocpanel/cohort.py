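"""Cohort domain model and serial-sample table I/O.

A cohort is a nested case-control serum collection: case women diagnosed
with ovarian cancer (Type I, including borderline tumours, or Type II) and
matched control women, each contributing serial serum samples collected at
known times before the case's diagnosis (tDx, in days).  Marker
concentrations live on the samples; epidemiological covariates and survival
live on the subjects.

The on-disk format is a flat CSV/TSV, one row per sample, with fixed
snake-case column names (see :data:`REQUIRED_COLUMNS`).  Missing values are
empty cells, never zeros.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: Calendar-average month length in days (365.25 / 12), used everywhere a
#: month-denominated window has to be converted to day offsets.
DAYS_PER_MONTH = 30.4375

#: Canonical marker names mapped to their concentration column and unit.
MARKER_COLUMNS: dict[str, tuple[str, str]] = {
    "igfbp2": ("igfbp2_ng_ml", "ng/ml"),
    "lcat": ("lcat_ug_ml", "ug/ml"),
    "shbg": ("shbg_nmol_l", "nmol/l"),
    "grp78": ("grp78_conc", "au"),
    "calprotectin": ("calprotectin_conc", "au"),
    "ca125": ("ca125_u_ml", "U/ml"),
}

REQUIRED_COLUMNS = [
    "sample_id",
    "subject_id",
    "group",
    "subtype",
    "tdx_days",
    "igfbp2_ng_ml",
    "lcat_ug_ml",
    "shbg_nmol_l",
    "grp78_conc",
    "calprotectin_conc",
    "ca125_u_ml",
    "age_at_sample",
    "bmi",
    "hrt_recruitment",
    "hrt_followup",
    "ocp_ever",
    "smoker_ever",
    "survival_days",
    "death_event",
    "matched_case_id",
]

BINARY_COVARIATES = ("hrt_recruitment", "hrt_followup", "ocp_ever", "smoker_ever")


class Group(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class Subtype(str, enum.Enum):
    TYPE1 = "type1"
    TYPE2 = "type2"
    NONE = "none"


@dataclass
class Subject:
    """One woman in the cohort; carries diagnosis, covariates and survival."""

    subject_id: str
    group: Group
    subtype: Subtype = Subtype.NONE
    raw_subtype: Optional[str] = None
    age_at_recruitment: Optional[float] = None
    bmi: Optional[float] = None
    hrt_recruitment: Optional[bool] = None
    hrt_followup: Optional[bool] = None
    ocp_ever: Optional[bool] = None
    smoker_ever: Optional[bool] = None
    diagnosis_date_offset: Optional[float] = None
    survival_days: Optional[float] = None
    death_event: Optional[bool] = None
    matched_case_id: Optional[str] = None

    def validate(self) -> None:
        if self.group is Group.CONTROL:
            if self.subtype is not Subtype.NONE:
                raise IntegrityError(
                    f"control subject {self.subject_id!r} carries subtype "
                    f"{self.subtype.value!r}"
                )
            if self.diagnosis_date_offset is not None:
                raise IntegrityError(
                    f"control subject {self.subject_id!r} carries a diagnosis offset"
                )
            if self.survival_days is not None or self.death_event is not None:
                raise IntegrityError(
                    f"control subject {self.subject_id!r} carries survival data"
                )
        else:
            if self.subtype not in (Subtype.TYPE1, Subtype.TYPE2):
                raise IntegrityError(
                    f"case subject {self.subject_id!r} must be type1 or type2"
                )
        if self.survival_days is not None and self.survival_days < 0:
            raise IntegrityError(
                f"subject {self.subject_id!r}: survival_days must be >= 0"
            )


@dataclass
class Sample:
    """One serum sample: marker concentrations at a time before diagnosis.

    For case samples ``tdx_days`` is the woman's own time-to-diagnosis; for
    control samples it is an optional pseudo-tDx inherited from the matched
    case's diagnosis reference.
    """

    sample_id: str
    subject_id: str
    tdx_days: Optional[float]
    markers: dict[str, Optional[float]] = field(default_factory=dict)
    age_at_sample: Optional[float] = None
    extra: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for name, value in self.markers.items():
            if value is None:
                continue
            if not math.isfinite(value) or value < 0:
                raise IntegrityError(
                    f"sample {self.sample_id!r}: marker {name!r} value {value!r} "
                    "must be finite and >= 0"
                )
        if self.tdx_days is not None and self.tdx_days < 0:
            raise IntegrityError(f"sample {self.sample_id!r}: tdx_days must be >= 0")


@dataclass
class Cohort:
    """A validated collection of subjects and their serial samples."""

    subjects: list[Subject]
    samples: list[Sample]
    marker_units: dict[str, str] = field(
        default_factory=lambda: {m: u for m, (_, u) in MARKER_COLUMNS.items()}
    )

    def validate(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise IntegrityError("duplicate subject_id in cohort")
        sample_ids = [s.sample_id for s in self.samples]
        if len(sample_ids) != len(set(sample_ids)):
            dupes = {x for x in sample_ids if sample_ids.count(x) > 1}
            raise IntegrityError(f"duplicate sample_id: {sorted(dupes)}")
        by_id = self.subjects_by_id()
        for sample in self.samples:
            if sample.subject_id not in by_id:
                raise IntegrityError(
                    f"sample {sample.sample_id!r} references unknown subject "
                    f"{sample.subject_id!r}"
                )
            sample.validate()
            subject = by_id[sample.subject_id]
            if subject.group is Group.CASE and sample.tdx_days is None:
                raise IntegrityError(
                    f"case sample {sample.sample_id!r} is missing tdx_days"
                )
            for name in sample.markers:
                if name not in self.marker_units:
                    raise IntegrityError(f"marker {name!r} has no declared unit")
        for subject in self.subjects:
            subject.validate()

    # -- convenience accessors -------------------------------------------

    def subjects_by_id(self) -> dict[str, Subject]:
        return {s.subject_id: s for s in self.subjects}

    def cases(self) -> list[Subject]:
        return [s for s in self.subjects if s.group is Group.CASE]

    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if s.group is Group.CONTROL]

    def samples_of(self, subject_id: str) -> list[Sample]:
        return [s for s in self.samples if s.subject_id == subject_id]

    def case_samples(self) -> list[Sample]:
        by_id = self.subjects_by_id()
        return [s for s in self.samples if by_id[s.subject_id].group is Group.CASE]

    def control_samples(self) -> list[Sample]:
        by_id = self.subjects_by_id()
        return [s for s in self.samples if by_id[s.subject_id].group is Group.CONTROL]

    def case_samples_of_subtype(self, subtype: str) -> list[Sample]:
        """Case samples for stratum 'type1', 'type2' or 'pan'."""
        by_id = self.subjects_by_id()
        out = []
        for s in self.samples:
            subj = by_id[s.subject_id]
            if subj.group is not Group.CASE:
                continue
            if subtype == "pan" or subj.subtype.value == subtype:
                out.append(s)
        return out

    def marker_values(self, marker: str, samples: Optional[Iterable[Sample]] = None):
        """Non-missing values of one marker over the given samples."""
        pool = self.samples if samples is None else samples
        return [
            s.markers[marker]
            for s in pool
            if s.markers.get(marker) is not None
        ]


@dataclass(frozen=True)
class SplitSpec:
    """Discovery-split windows, in months before diagnosis.

    The discovery design keeps (at most) one sample per woman close to
    diagnosis (< ``near_max_months``) and one far from it
    (> ``far_min_months``).
    """

    near_max_months: float = 14.0
    far_min_months: float = 32.0

    def __post_init__(self) -> None:
        if not self.near_max_months < self.far_min_months:
            raise ValueError("near_max_months must be < far_min_months")

    @property
    def near_max_days(self) -> float:
        return self.near_max_months * DAYS_PER_MONTH

    @property
    def far_min_days(self) -> float:
        return self.far_min_months * DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# Parsing helpers


def _parse_float(raw, column: str, row: int) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"row {row}: column {column!r}: cannot parse {text!r} as a number"
        ) from None


def _parse_bool(raw, column: str, row: int) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip().lower()
    if text == "":
        return None
    if text in ("1", "true", "yes", "y", "1.0"):
        return True
    if text in ("0", "false", "no", "n", "0.0"):
        return False
    raise ParseError(f"row {row}: column {column!r}: cannot parse {text!r} as boolean")


def _subtype_from_label(label: Optional[str]) -> tuple[Subtype, Optional[str]]:
    if label is None:
        return Subtype.NONE, None
    text = str(label).strip().lower()
    if text in ("", "none", "nan"):
        return Subtype.NONE, None
    if text in ("type1", "type_1", "type i", "i", "1", "1.0"):
        return Subtype.TYPE1, text
    if text in ("type2", "type_2", "type ii", "ii", "2", "2.0"):
        return Subtype.TYPE2, text
    if text == "borderline":
        # Borderline tumours are grouped with Type I for analysis; the raw
        # label is preserved on the subject.
        return Subtype.TYPE1, text
    raise ParseError(f"unknown subtype label {label!r}")


def read_cohort(path: str | Path, dialect: Optional[str] = None) -> Cohort:
    """Read a serial-sample cohort table from CSV or TSV.

    Parameters
    ----------
    path:
        File with one row per serum sample (columns per
        :data:`REQUIRED_COLUMNS`).  Unknown columns are preserved verbatim as
        per-sample covariates.
    dialect:
        ``"csv"`` or ``"tsv"``; inferred from the extension when omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    extra_cols = [
        c for c in frame.columns
        if c not in REQUIRED_COLUMNS and c != "diagnosis_offset_days"
    ]

    subjects: dict[str, Subject] = {}
    samples: list[Sample] = []
    seen_sample_ids: set[str] = set()

    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1 = header
        rec = dict(zip(frame.columns, row))
        sample_id = rec["sample_id"].strip()
        subject_id = rec["subject_id"].strip()
        if sample_id in seen_sample_ids:
            raise IntegrityError(f"duplicate sample_id {sample_id!r} (row {i})")
        seen_sample_ids.add(sample_id)

        group_text = rec["group"].strip().lower()
        if group_text not in ("case", "control"):
            raise ParseError(f"row {i}: unknown group {rec['group']!r}")
        group = Group(group_text)

        if subject_id not in subjects:
            subtype, raw_label = _subtype_from_label(rec["subtype"])
            subjects[subject_id] = Subject(
                subject_id=subject_id,
                group=group,
                subtype=subtype,
                raw_subtype=raw_label,
                bmi=_parse_float(rec["bmi"], "bmi", i),
                hrt_recruitment=_parse_bool(rec["hrt_recruitment"], "hrt_recruitment", i),
                hrt_followup=_parse_bool(rec["hrt_followup"], "hrt_followup", i),
                ocp_ever=_parse_bool(rec["ocp_ever"], "ocp_ever", i),
                smoker_ever=_parse_bool(rec["smoker_ever"], "smoker_ever", i),
                diagnosis_date_offset=_parse_float(
                    rec.get("diagnosis_offset_days"), "diagnosis_offset_days", i
                ),
                survival_days=_parse_float(rec["survival_days"], "survival_days", i),
                death_event=_parse_bool(rec["death_event"], "death_event", i),
                matched_case_id=rec["matched_case_id"].strip() or None,
            )
        elif subjects[subject_id].group is not group:
            raise IntegrityError(
                f"row {i}: subject {subject_id!r} changes group mid-file"
            )

        markers = {
            name: _parse_float(rec[col], col, i)
            for name, (col, _) in MARKER_COLUMNS.items()
        }
        samples.append(
            Sample(
                sample_id=sample_id,
                subject_id=subject_id,
                tdx_days=_parse_float(rec["tdx_days"], "tdx_days", i),
                markers=markers,
                age_at_sample=_parse_float(rec["age_at_sample"], "age_at_sample", i),
                extra={c: rec[c] for c in extra_cols if rec[c] != ""},
            )
        )

    cohort = Cohort(subjects=list(subjects.values()), samples=samples)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path: str | Path, dialect: Optional[str] = None) -> None:
    """Write a cohort back to the flat one-row-per-sample table.

    ``read_cohort(write_cohort(c))`` reproduces ``c`` field for field;
    missing values become empty cells.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if dialect == "tsv" else ","

    by_id = cohort.subjects_by_id()
    has_offset = any(s.diagnosis_date_offset is not None for s in cohort.subjects)
    extra_cols = sorted({c for s in cohort.samples for c in s.extra})

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "1" if value else "0"
        if isinstance(value, (int, float)) or hasattr(value, "item"):  # numpy scalars
            v = float(value)
            if v == int(v) and abs(v) < 1e15:
                return str(int(v))
            return repr(v)
        return str(value)

    rows = []
    for sample in cohort.samples:
        subj = by_id[sample.subject_id]
        raw_subtype = subj.raw_subtype
        if subj.group is Group.CASE and raw_subtype is None:
            raw_subtype = subj.subtype.value
        row = {
            "sample_id": sample.sample_id,
            "subject_id": sample.subject_id,
            "group": subj.group.value,
            "subtype": raw_subtype or "",
            "tdx_days": fmt(sample.tdx_days),
            "age_at_sample": fmt(sample.age_at_sample),
            "bmi": fmt(subj.bmi),
            "hrt_recruitment": fmt(subj.hrt_recruitment),
            "hrt_followup": fmt(subj.hrt_followup),
            "ocp_ever": fmt(subj.ocp_ever),
            "smoker_ever": fmt(subj.smoker_ever),
            "survival_days": fmt(subj.survival_days),
            "death_event": fmt(subj.death_event),
            "matched_case_id": subj.matched_case_id or "",
        }
        for name, (col, _) in MARKER_COLUMNS.items():
            row[col] = fmt(sample.markers.get(name))
        if has_offset:
            row["diagnosis_offset_days"] = fmt(subj.diagnosis_date_offset)
        for c in extra_cols:
            row[c] = sample.extra.get(c, "")
        rows.append(row)

    columns = list(REQUIRED_COLUMNS)
    if has_offset:
        columns.append("diagnosis_offset_days")
    columns.extend(extra_cols)
    frame = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    frame.to_csv(path, sep=sep, index=False)


def make_discovery_set(cohort: Cohort, spec: SplitSpec = SplitSpec()) -> Cohort:
    """Reduce a cohort to its discovery split.

    Per subject, at most one sample with tDx below the near window bound and
    one with tDx above the far bound are retained, each the nearest to
    diagnosis within its window.  Controls are windowed on their pseudo-tDx.
    Subjects lacking one or both windows keep what they have; a warning is
    logged.  The operation is idempotent and returns a sub-multiset of the
    input samples.
    """
    keep: list[Sample] = []
    for subject in cohort.subjects:
        subject_samples = [
            s for s in cohort.samples_of(subject.subject_id) if s.tdx_days is not None
        ]
        near = [s for s in subject_samples if s.tdx_days < spec.near_max_days]
        far = [s for s in subject_samples if s.tdx_days > spec.far_min_days]
        chosen = []
        if near:
            chosen.append(min(near, key=lambda s: s.tdx_days))
        if far:
            chosen.append(min(far, key=lambda s: s.tdx_days))
        if len(chosen) < 2:
            logger.warning(
                "discovery split: subject %s has %d of 2 windows populated",
                subject.subject_id,
                len(chosen),
            )
        keep.extend(chosen)
    keep_ids = {s.sample_id for s in keep}
    return Cohort(
        subjects=[replace(s) for s in cohort.subjects],
        samples=[s for s in cohort.samples if s.sample_id in keep_ids],
        marker_units=dict(cohort.marker_units),
    )
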