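"""Cohort data model, tabular I/O and validation.

Three delimiter-separated tables describe a cohort:

* a subjects table (``subject_id, group, age, sex, site_id, disease_duration``),
* a volumes table (``subject_id`` + one column per ROI, in ml, + ``tiv``),
* a long-format motor table (``subject_id, timepoint, item_id, score``).

``.csv`` files are comma-separated, ``.tsv`` tab-separated; both UTF-8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .roi import ITEM_IDS

__all__ = [
    "SubjectRecord", "ROIVolumeTable", "MotorAssessment",
    "CohortError", "SchemaError", "IntegrityError",
    "read_cohort", "write_cohort", "validate_cohort", "ValidationReport",
]


class CohortError(ValueError):
    """Base class for cohort data errors."""


class SchemaError(CohortError):
    """A required column is missing or mistyped."""


class IntegrityError(CohortError):
    """Cross-table or uniqueness constraint violated."""


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str              # "HC" or "PD"
    age: float              # years
    sex: str                # "male" or "female"
    site_id: str
    disease_duration: float | None = None  # months; PD only

    def __post_init__(self) -> None:
        if self.group not in ("HC", "PD"):
            raise CohortError(f"group must be HC or PD, got {self.group!r}")
        if self.sex not in ("male", "female"):
            raise CohortError(f"sex must be male or female, got {self.sex!r}")
        if not self.age > 0:
            raise CohortError(f"age must be positive, got {self.age}")


@dataclass
class ROIVolumeTable:
    """Subjects x ROIs gray-matter volumes (ml) with per-subject TIV (ml)."""

    subject_ids: list[str]
    roi_names: list[str]
    volumes: np.ndarray     # (n_subjects, n_rois)
    tiv: np.ndarray         # (n_subjects,)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.tiv = np.asarray(self.tiv, dtype=float)
        n, p = self.volumes.shape
        if len(self.subject_ids) != n or len(self.roi_names) != p:
            raise SchemaError("volume matrix shape does not match labels")
        if len(set(self.subject_ids)) != n:
            raise IntegrityError("duplicate subject_id in volume table")
        if len(set(self.roi_names)) != p:
            raise IntegrityError("duplicate roi name in volume table")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.volumes, columns=self.roi_names)
        df.insert(0, "subject_id", self.subject_ids)
        df["tiv"] = self.tiv
        return df

    def row(self, subject_id: str) -> np.ndarray:
        return self.volumes[self.subject_ids.index(subject_id)]


@dataclass
class MotorAssessment:
    """One motor examination: per-item integer scores plus their total."""

    subject_id: str
    timepoint: str          # "baseline" or "month48"
    items: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in ("baseline", "month48"):
            raise CohortError(f"unknown timepoint {self.timepoint!r}")

    @property
    def total(self) -> int:
        return int(sum(self.items.values()))


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def read_cohort(
    subjects_path: str | Path,
    volumes_path: str | Path,
    motor_path: str | Path,
    roi_names: list[str] | None = None,
) -> tuple[list[SubjectRecord], ROIVolumeTable, list[MotorAssessment]]:
    """Read the three cohort tables, cross-key them and validate basics.

    If ``roi_names`` is None, every volume column other than ``subject_id``
    and ``tiv`` is taken as a ROI, in file order.
    """
    subjects_path, volumes_path, motor_path = (
        Path(subjects_path), Path(volumes_path), Path(motor_path))

    sdf = _read_table(subjects_path,
                      ["subject_id", "group", "age", "sex", "site_id"])
    if sdf["subject_id"].duplicated().any():
        dup = sdf.loc[sdf["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise IntegrityError(f"duplicate subject_id {dup!r} in subjects table")
    subjects = []
    for _, r in sdf.iterrows():
        dd = r.get("disease_duration", np.nan)
        subjects.append(SubjectRecord(
            subject_id=str(r["subject_id"]), group=str(r["group"]),
            age=float(r["age"]), sex=str(r["sex"]),
            site_id=str(r["site_id"]),
            disease_duration=None if pd.isna(dd) else float(dd)))

    vdf = _read_table(volumes_path, ["subject_id", "tiv"])
    roi_cols = roi_names or [c for c in vdf.columns
                             if c not in ("subject_id", "tiv")]
    for c in roi_cols:
        if c not in vdf.columns:
            raise SchemaError(f"{volumes_path.name}: missing ROI column {c!r}")
        bad = pd.to_numeric(vdf[c], errors="coerce").isna() & vdf[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortError(
                f"{volumes_path.name}: non-numeric volume at row {row}, "
                f"column {c!r}")
    volumes = ROIVolumeTable(
        subject_ids=[str(s) for s in vdf["subject_id"]],
        roi_names=list(roi_cols),
        volumes=vdf[roi_cols].to_numpy(dtype=float),
        tiv=vdf["tiv"].to_numpy(dtype=float))

    mdf = _read_table(motor_path, ["subject_id", "timepoint", "item_id", "score"])
    assessments: list[MotorAssessment] = []
    for (sid, tp), grp in mdf.groupby(["subject_id", "timepoint"], sort=False):
        assessments.append(MotorAssessment(
            subject_id=str(sid), timepoint=str(tp),
            items={str(i): int(s)
                   for i, s in zip(grp["item_id"], grp["score"])}))
    return subjects, volumes, assessments


def write_cohort(
    subjects: list[SubjectRecord],
    volumes: ROIVolumeTable,
    assessments: list[MotorAssessment],
    subjects_path: str | Path,
    volumes_path: str | Path,
    motor_path: str | Path,
) -> None:
    """Write the three cohort tables; inverse of :func:`read_cohort`."""
    subjects_path, volumes_path, motor_path = (
        Path(subjects_path), Path(volumes_path), Path(motor_path))
    sdf = pd.DataFrame([{
        "subject_id": s.subject_id, "group": s.group, "age": s.age,
        "sex": s.sex, "site_id": s.site_id,
        "disease_duration": s.disease_duration,
    } for s in subjects])
    sdf.to_csv(subjects_path, sep=_sep(subjects_path), index=False)
    volumes.to_frame().to_csv(volumes_path, sep=_sep(volumes_path),
                              index=False)
    rows = [{"subject_id": a.subject_id, "timepoint": a.timepoint,
             "item_id": i, "score": v}
            for a in assessments for i, v in a.items.items()]
    pd.DataFrame(rows).to_csv(motor_path, sep=_sep(motor_path), index=False)


@dataclass
class ValidationReport:
    """Per-rule pass/fail outcomes with human-readable messages."""

    results: dict[str, bool] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.results.values())

    def record(self, rule: str, ok: bool, msg: str = "") -> None:
        self.results[rule] = self.results.get(rule, True) and ok
        if not ok and msg:
            self.messages.append(f"{rule}: {msg}")

    def to_json(self) -> str:
        return json.dumps({"passed": self.passed, "rules": self.results,
                           "messages": self.messages}, indent=2)


def validate_cohort(
    subjects: list[SubjectRecord],
    volumes: ROIVolumeTable,
    assessments: list[MotorAssessment],
    expected_items: tuple[str, ...] = ITEM_IDS,
) -> ValidationReport:
    """Check every cohort invariant; never raises, reports failures."""
    rep = ValidationReport()
    sids = [s.subject_id for s in subjects]
    rep.record("unique subject ids", len(set(sids)) == len(sids))
    rep.record("volume table keyed", set(volumes.subject_ids) == set(sids),
               "volume table subject ids differ from subjects table")
    rep.record("positive volumes", bool((volumes.volumes > 0).all()),
               "non-positive ROI volume present")
    rep.record("positive tiv", bool((volumes.tiv > 0).all()))
    rep.record("tiv exceeds roi volumes",
               bool((volumes.volumes < volumes.tiv[:, None]).all()),
               "a single ROI volume exceeds TIV")

    groups = {s.subject_id: s.group for s in subjects}
    for s in subjects:
        if s.group == "PD" and s.disease_duration is None:
            rep.record("disease duration present", False,
                       f"PD subject {s.subject_id} missing disease_duration")
    rep.record("disease duration present",
               rep.results.get("disease duration present", True))

    by_subj: dict[str, set[str]] = {}
    for a in assessments:
        by_subj.setdefault(a.subject_id, set()).add(a.timepoint)
        ok_range = all(0 <= v <= 4 for v in a.items.values())
        rep.record("item scores in range", ok_range,
                   f"{a.subject_id}/{a.timepoint} has out-of-range item")
        missing = set(expected_items) - set(a.items)
        rep.record("complete item set", not missing,
                   f"{a.subject_id}/{a.timepoint} missing items "
                   f"{sorted(missing)[:3]}")
    rep.record("item scores in range",
               rep.results.get("item scores in range", True))
    rep.record("complete item set",
               rep.results.get("complete item set", True))
    for sid, g in groups.items():
        if g == "PD":
            tps = by_subj.get(sid, set())
            rep.record("paired timepoints",
                       {"baseline", "month48"} <= tps,
                       f"PD subject {sid} lacks paired assessments")
    rep.record("paired timepoints", rep.results.get("paired timepoints", True))
    return rep
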