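"""Head-size normalization, motor-change outcomes and demographic statistics.

GMV_N = GMV / TIV removes inter-subject head-size variation.  Motor change
over 48 months is the month-48 score minus baseline (positive = worsening),
computed for the total and for five symptom-family subscores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import MotorAssessment, ROIVolumeTable
from .roi import SUBSCORE_ITEMS, SUBSCORE_NAMES

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedVolumeTable", "OutcomeDelta", "normalize_tiv", "subscore",
    "compute_deltas", "welch_t", "chi_square_2x2",
]


class NormalizedVolumeTable(ROIVolumeTable):
    """ROI table whose values are GMV_N = GMV / TIV, a fraction in (0, 1)."""


@dataclass(frozen=True)
class OutcomeDelta:
    subject_id: str
    delta_total: int
    delta_rigidity: int
    delta_bradykinesia: int
    delta_pig: int
    delta_postural_kinetic: int
    delta_rest: int

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.delta_total,
            "rigidity": self.delta_rigidity,
            "bradykinesia": self.delta_bradykinesia,
            "pig": self.delta_pig,
            "postural_kinetic": self.delta_postural_kinetic,
            "rest": self.delta_rest,
        }


def normalize_tiv(volumes: ROIVolumeTable) -> NormalizedVolumeTable:
    """Divide each subject's ROI volumes by their total intracranial volume."""
    if np.any(volumes.tiv <= 0):
        raise ValueError("TIV must be strictly positive for every subject")
    return NormalizedVolumeTable(
        subject_ids=list(volumes.subject_ids),
        roi_names=list(volumes.roi_names),
        volumes=volumes.volumes / volumes.tiv[:, None],
        tiv=volumes.tiv.copy())


def subscore(items: dict[str, int], which: str) -> int:
    """Sum the item scores of one symptom family (or ``"total"``).

    Families: rigidity (item 3.3 across five body parts), bradykinesia
    (items 3.4-3.8, both sides), postural instability and gait (items
    3.10-3.13), postural-kinetic tremor (items 3.15-3.16) and resting
    tremor (item 3.17 across five body parts).
    """
    if which == "total":
        return int(sum(items.values()))
    try:
        wanted = SUBSCORE_ITEMS[which]
    except KeyError:
        raise KeyError(f"unknown subscore {which!r}; "
                       f"expected one of {SUBSCORE_NAMES} or 'total'") from None
    missing = [i for i in wanted if i not in items]
    if missing:
        raise ValueError(f"incomplete assessment: missing item {missing[0]!r}")
    return int(sum(items[i] for i in wanted))


def compute_deltas(assessments: list[MotorAssessment],
                   pd_ids: list[str] | None = None) -> list[OutcomeDelta]:
    """Month-48 minus baseline for the total and every subscore.

    Subjects without both timepoints are excluded with a logged warning.
    If ``pd_ids`` is given, only those subjects are scored.
    """
    by_subj: dict[str, dict[str, MotorAssessment]] = {}
    for a in assessments:
        by_subj.setdefault(a.subject_id, {})[a.timepoint] = a
    out: list[OutcomeDelta] = []
    ids = pd_ids if pd_ids is not None else list(by_subj)
    for sid in ids:
        tps = by_subj.get(sid, {})
        if "baseline" not in tps or "month48" not in tps:
            log.warning("subject %s lacks paired assessments; excluded", sid)
            continue
        b, m = tps["baseline"], tps["month48"]
        out.append(OutcomeDelta(
            subject_id=sid,
            delta_total=m.total - b.total,
            delta_rigidity=subscore(m.items, "rigidity")
            - subscore(b.items, "rigidity"),
            delta_bradykinesia=subscore(m.items, "bradykinesia")
            - subscore(b.items, "bradykinesia"),
            delta_pig=subscore(m.items, "pig") - subscore(b.items, "pig"),
            delta_postural_kinetic=subscore(m.items, "postural_kinetic")
            - subscore(b.items, "postural_kinetic"),
            delta_rest=subscore(m.items, "rest") - subscore(b.items, "rest")))
    return out


def welch_t(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> tuple[float, float, float]:
    """Unequal-variance two-sample t test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-tailed p).  Defined as t = 0
    when both standard deviations are zero and the means are equal.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, df = 1.

    No continuity correction by default; pass ``correction=True`` for the
    Yates-corrected variant.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total: chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)
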