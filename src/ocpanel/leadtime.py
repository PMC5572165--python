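"""Per-subject first-breach detection and lead-time comparison.

Lead time is measured as the time-to-diagnosis of the earliest serial
sample at which a panel first calls a woman positive — the larger the tDx
of the first breaching sample, the earlier the detection.  Model-level
summaries average over each model's own detected subjects (or over the
either-detected set, configurable), and paired significance runs on the
subjects detected by both models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cohort import Cohort, Group, Sample
from .panels import PanelModel, evaluate_sample
from .stats import TestResult, paired_t

logger = logging.getLogger(__name__)


@dataclass
class LeadTimeResult:
    panel: str
    stratum: str
    n_detected: int
    n_never_detected: int
    per_subject_first_breach_tdx: dict[str, float] = field(default_factory=dict)
    mean_lead_days: Optional[float] = None
    paired_comparison: Optional[TestResult] = None
    n_detected_earlier_than_ref: int = 0
    n_detected_ref_missed: int = 0
    gain_pct: Optional[int] = None
    reference: Optional[str] = None
    reference_mean_lead_days: Optional[float] = None


def first_breach(
    panel: PanelModel,
    samples_of_subject: Sequence[Sample],
    missing_policy: str = "negative",
) -> Optional[float]:
    """tDx of the earliest (largest-tDx) breaching sample; None if never."""
    if not samples_of_subject:
        logger.warning("first_breach called with no samples")
        return None
    breach_tdx = [
        s.tdx_days
        for s in samples_of_subject
        if s.tdx_days is not None and evaluate_sample(panel, s, missing_policy)
    ]
    return max(breach_tdx) if breach_tdx else None


def _first_breaches(
    cohort: Cohort, panel: PanelModel, stratum: str, missing_policy: str
) -> tuple[dict[str, Optional[float]], list[str]]:
    subject_ids = [
        s.subject_id
        for s in cohort.cases()
        if stratum == "pan" or s.subtype.value == stratum
    ]
    breaches = {
        sid: first_breach(panel, cohort.samples_of(sid), missing_policy)
        for sid in subject_ids
    }
    return breaches, subject_ids


def lead_time_summary(
    cohort: Cohort,
    panel: PanelModel,
    reference: PanelModel,
    stratum: str = "pan",
    mode: str = "model",
    missing_policy: str = "negative",
) -> LeadTimeResult:
    """Summarise first-breach lead times of ``panel`` against ``reference``.

    ``mode='model'`` averages each model's lead over its own detected
    subjects; ``mode='either'`` averages over the subjects detected by
    either model (each model still contributing only where it has a
    breach).  A subject counts as detected earlier than the reference if
    the reference missed her entirely or her panel first breach precedes
    the reference's (larger tDx).  ``gain_pct`` is the
    detected-earlier count as a rounded percentage of the stratum's case
    count.  The paired t-test runs on the both-detected intersection.
    """
    if mode not in ("model", "either"):
        raise ValueError(f"unknown mode {mode!r}")
    breaches, subject_ids = _first_breaches(cohort, panel, stratum, missing_policy)
    ref_breaches, _ = _first_breaches(cohort, reference, stratum, missing_policy)

    detected = [sid for sid in subject_ids if breaches[sid] is not None]
    ref_detected = {sid for sid in subject_ids if ref_breaches[sid] is not None}
    either = [sid for sid in subject_ids if sid in ref_detected or breaches[sid] is not None]
    averaging_set = detected if mode == "model" else [s for s in either if breaches[s] is not None]
    ref_averaging = (
        sorted(ref_detected) if mode == "model"
        else [s for s in either if ref_breaches[s] is not None]
    )

    mean_lead = (
        sum(breaches[s] for s in averaging_set) / len(averaging_set)
        if averaging_set
        else None
    )
    ref_mean_lead = (
        sum(ref_breaches[s] for s in ref_averaging) / len(ref_averaging)
        if ref_averaging
        else None
    )
    if mean_lead is None:
        logger.warning("panel %s detected no subjects in stratum %s", panel.name, stratum)

    earlier = [
        sid for sid in detected
        if sid not in ref_detected or breaches[sid] > ref_breaches[sid]
    ]
    ref_missed = [sid for sid in detected if sid not in ref_detected]

    both = [sid for sid in detected if sid in ref_detected]
    paired: Optional[TestResult] = None
    if len(both) >= 2:
        x = [breaches[s] for s in both]
        y = [ref_breaches[s] for s in both]
        try:
            paired = paired_t(x, y)
        except ValueError:
            logger.warning(
                "paired lead-time test degenerate for %s vs %s in %s",
                panel.name, reference.name, stratum,
            )

    n_stratum = len(subject_ids)
    gain = int(round(100.0 * len(earlier) / n_stratum)) if n_stratum else None
    return LeadTimeResult(
        panel=panel.name,
        stratum=stratum,
        n_detected=len(detected),
        n_never_detected=n_stratum - len(detected),
        per_subject_first_breach_tdx={s: breaches[s] for s in detected},
        mean_lead_days=mean_lead,
        paired_comparison=paired,
        n_detected_earlier_than_ref=len(earlier),
        n_detected_ref_missed=len(ref_missed),
        gain_pct=gain,
        reference=reference.name,
        reference_mean_lead_days=ref_mean_lead,
    )


def detection_gain_pct(n_gained: int, n_stratum: int) -> int:
    """Detection gain as a whole-number percentage of the stratum size."""
    if n_stratum <= 0:
        raise ValueError("stratum size must be positive")
    return int(round(100.0 * n_gained / n_stratum))


def pooled_mean_lead(per_stratum: Sequence[tuple[float, int]]) -> float:
    """Subject-weighted pooling of per-stratum mean lead times.

    ``sum(mean_i * n_i) / sum(n_i)`` — exactly the mean over the
    concatenated detected subjects.
    """
    if not per_stratum:
        raise ValueError("need at least one stratum")
    total_n = sum(n for _, n in per_stratum)
    if total_n <= 0:
        raise ValueError("total detected count must be positive")
    return sum(mean * n for mean, n in per_stratum) / total_n
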