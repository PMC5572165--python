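"""Kaplan-Meier estimation and threshold-breach prognostic stratification.

A case woman is a *breacher* of a panel if any of her serial samples is
called positive.  Splitting post-diagnosis survival (time from diagnosis to
death, right-censored) by breach status asks whether the panel is
prognostic: if the panel preferentially fires on aggressive tumours, the
breacher Kaplan-Meier curve sits below the non-breacher curve and the
log-rank test rejects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from .cohort import Cohort, Subject
from .panels import PanelModel
from .leadtime import first_breach
from .stats import TestResult, logrank

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival estimate with right censoring."""

    times: list[float]          # event/censor times where the estimate changes
    survival: list[float]       # S(t) just after each time
    at_risk: list[int]
    n_events: int
    n_subjects: int
    median_survival_days: Optional[float]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for time, val in zip(self.times, self.survival):
            if time <= t:
                s = val
            else:
                break
        return s


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator (deaths precede censorings at ties)."""
    t = np.asarray(list(times), dtype=float)
    e = np.asarray([bool(x) for x in events])
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    step_rows = table[table["observed"] > 0]
    sf = kmf.survival_function_["KM_estimate"]
    step_times = [float(x) for x in step_rows.index]
    survival = [float(sf.loc[x]) for x in step_rows.index]
    at_risk = [int(x) for x in step_rows["at_risk"]]
    median = kmf.median_survival_time_
    return KMCurve(
        times=step_times,
        survival=survival,
        at_risk=at_risk,
        n_events=int(e.sum()),
        n_subjects=int(t.size),
        median_survival_days=None if np.isinf(median) else float(median),
    )


def stratify_by_breach(
    cohort: Cohort,
    panel: PanelModel,
    stratum: str = "type2",
    missing_policy: str = "negative",
) -> tuple[Optional[KMCurve], Optional[KMCurve], Optional[TestResult]]:
    """Split a case stratum's survival by whether any serial sample breaches.

    Returns (breacher curve, non-breacher curve, log-rank result); an empty
    arm yields None for its curve and skips the test with a warning.
    Subjects without survival data are excluded (logged count).
    """
    subjects = [
        s for s in cohort.cases()
        if stratum == "pan" or s.subtype.value == stratum
    ]
    usable: list[tuple[Subject, bool]] = []
    n_missing = 0
    for subj in subjects:
        if subj.survival_days is None or subj.death_event is None:
            n_missing += 1
            continue
        breach = first_breach(panel, cohort.samples_of(subj.subject_id), missing_policy)
        usable.append((subj, breach is not None))
    if n_missing:
        logger.warning(
            "prognosis: excluded %d subject(s) without survival data", n_missing
        )

    arms: dict[bool, list[tuple[float, bool]]] = {True: [], False: []}
    for subj, is_breacher in usable:
        arms[is_breacher].append((subj.survival_days, subj.death_event))

    curves: dict[bool, Optional[KMCurve]] = {}
    for key, data in arms.items():
        curves[key] = (
            km_estimate([t for t, _ in data], [e for _, e in data]) if data else None
        )
    test: Optional[TestResult] = None
    if arms[True] and arms[False]:
        test = logrank(arms[True], arms[False])
    else:
        logger.warning(
            "prognosis: one arm empty for panel %s in stratum %s; log-rank skipped",
            panel.name, stratum,
        )
    return curves[True], curves[False], test
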