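"""OR-rule threshold panels: calibration, evaluation, performance, ROC.

The core classifier of the pipeline is a *threshold model*: each marker has
a directional concentration cutoff (above for up-regulated markers, below
for down-regulated ones), and a panel calls a sample positive when ANY of
its rules is breached (logical OR).  Breach uses strict inequality, so a
value exactly at the threshold is negative.

Cutoffs are either fixed (the published operating points, e.g. the
35 U/ml CA125 referral level) or calibrated on control samples at a target
false-positive rate alpha via an order statistic of the control values, so
that the in-sample FPR never exceeds alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cohort import Cohort, Group, Sample
from .errors import ConfigurationError
from .preprocess import TimeBin, assign_bins
from .stats import TestResult, mcnemar

logger = logging.getLogger(__name__)

#: Published operating thresholds of the study panel, in native units.
PUBLISHED_THRESHOLDS = {
    "igfbp2": ("above", 78.5),   # ng/ml
    "lcat": ("below", 8.831),    # ug/ml
    "shbg": ("below", 16.1),     # nmol/l
    "ca125": ("above", 35.0),    # U/ml referral level
}

#: Regulation direction of each marker in cases (drives rule direction).
MARKER_DIRECTIONS = {name: d for name, (d, _) in PUBLISHED_THRESHOLDS.items()}

STRATA = ("type1", "type2", "pan")


@dataclass(frozen=True)
class MarkerRule:
    """One directional concentration cutoff in the marker's native units."""

    marker: str
    direction: str  # "above" | "below"
    threshold: float
    provenance: str = "fixed"

    def __post_init__(self):
        if self.direction not in ("above", "below"):
            raise ValueError(f"direction must be 'above' or 'below', got {self.direction!r}")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def breached(self, value: Optional[float]) -> Optional[bool]:
        """Strict-inequality breach; None for a missing value."""
        if value is None:
            return None
        if self.direction == "above":
            return value > self.threshold
        return value < self.threshold


@dataclass(frozen=True)
class PanelModel:
    """A named OR-combination of marker rules (the study's threshold model)."""

    name: str
    rules: tuple[MarkerRule, ...]
    combiner: str = "OR"

    def __post_init__(self):
        if not self.rules:
            raise ValueError("panel needs at least one rule")
        markers = [r.marker for r in self.rules]
        if len(markers) != len(set(markers)):
            raise ValueError(f"panel {self.name!r}: duplicate marker in rules")
        if self.combiner != "OR":
            raise ValueError("only the OR combiner is supported")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(r.marker for r in self.rules)


@dataclass
class BinnedPerformance:
    """Sensitivity/specificity of one panel in one stratum x time bin cell."""

    panel: str
    stratum: str          # "type1" | "type2" | "pan"
    bin: str              # bin label or "pooled"
    n_case_samples: int
    n_control_samples: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    mcnemar_vs_ref: Optional[TestResult] = None


def calibrate_threshold(
    control_values: Sequence[float], direction: str, alpha: float, marker: str = ""
) -> MarkerRule:
    """Place a directional cutoff at the empirical control quantile for FPR alpha.

    For ``direction='above'`` the threshold is the k-th order statistic of
    the control values with k = ceil((1-alpha) * n); for ``'below'`` the
    mirror image, k = floor(alpha * n) + 1.  With strict-inequality breach
    this guarantees the in-sample FPR on the calibration controls is at
    most alpha.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    values = np.sort(np.asarray(list(control_values), dtype=float))
    n = values.size
    if n == 0:
        raise ValueError("no control values to calibrate on")
    if n < 20:
        logger.warning(
            "calibrating %s on only %d controls; quantile is unstable", marker or "marker", n
        )
    if direction == "above":
        k = math.ceil((1.0 - alpha) * n)
        threshold = float(values[k - 1])
    elif direction == "below":
        k = math.floor(alpha * n) + 1
        threshold = float(values[k - 1])
    else:
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    return MarkerRule(
        marker=marker, direction=direction, threshold=threshold,
        provenance=f"calibrated({alpha:g})",
    )


def published_panel(markers: Iterable[str], name: Optional[str] = None) -> PanelModel:
    """Build a panel from the published fixed thresholds for the given markers."""
    markers = list(markers)
    rules = []
    for m in markers:
        if m not in PUBLISHED_THRESHOLDS:
            raise KeyError(f"no published threshold for marker {m!r}")
        direction, thr = PUBLISHED_THRESHOLDS[m]
        rules.append(MarkerRule(m, direction, thr, provenance="fixed"))
    return PanelModel(name or ":".join(m.upper() for m in markers), tuple(rules))


def calibrate_panel(
    cohort: Cohort,
    markers: Iterable[str],
    alpha: float = 0.05,
    fixed: Optional[dict[str, float]] = None,
    name: Optional[str] = None,
) -> PanelModel:
    """Calibrate a panel on the cohort's control samples at FPR ``alpha``.

    Markers listed in ``fixed`` keep their fixed threshold (by default CA125
    stays at the 35 U/ml referral level when included); all others get the
    order-statistic cutoff in their regulation direction.
    """
    if fixed is None:
        fixed = {"ca125": PUBLISHED_THRESHOLDS["ca125"][1]}
    controls = cohort.control_samples()
    rules = []
    for m in markers:
        direction = MARKER_DIRECTIONS.get(m)
        if direction is None:
            raise KeyError(f"no declared regulation direction for marker {m!r}")
        if m in fixed:
            rules.append(MarkerRule(m, direction, float(fixed[m]), provenance="fixed"))
        else:
            values = cohort.marker_values(m, controls)
            rules.append(calibrate_threshold(values, direction, alpha, marker=m))
    return PanelModel(name or ":".join(r.marker.upper() for r in rules), tuple(rules))


def evaluate_sample(
    panel: PanelModel, sample: Sample, missing_policy: str = "negative"
) -> bool:
    """True iff any rule of the panel is breached by the sample.

    A missing marker value contributes a negative under the default
    ``missing_policy='negative'`` (logged); ``'error'`` raises instead.
    """
    positive = False
    for rule in panel.rules:
        breach = rule.breached(sample.markers.get(rule.marker))
        if breach is None:
            if missing_policy == "error":
                raise ValueError(
                    f"sample {sample.sample_id!r} missing marker {rule.marker!r}"
                )
            logger.debug(
                "sample %s: missing %s treated as negative", sample.sample_id, rule.marker
            )
            continue
        positive = positive or breach
    return positive


def _detection_vector(
    panel: PanelModel, samples: Sequence[Sample], missing_policy: str
) -> np.ndarray:
    return np.array(
        [evaluate_sample(panel, s, missing_policy) for s in samples], dtype=bool
    )


def performance_table(
    cohort: Cohort,
    panels: Sequence[PanelModel],
    bins: Optional[Sequence[TimeBin]] = None,
    strata: Sequence[str] = STRATA,
    reference_panel: Optional[str] = None,
    specificity_mode: str = "pooled",
    sensitivity_unit: str = "per_sample",
    missing_policy: str = "negative",
) -> list[BinnedPerformance]:
    """Per panel x stratum x time-bin sensitivity/specificity table.

    ``bins=None`` produces the pooled ("triage", no temporal information)
    table with a single row per panel and stratum.  Sensitivity is computed
    over case samples in the cell (or per woman when
    ``sensitivity_unit='per_subject'``: a woman counts positive if any of
    her samples in the cell breaches).  Specificity defaults to one pooled
    value over all control samples; ``specificity_mode='binned'`` restricts
    the denominator to pseudo-tDx-matched control samples per bin.  When a
    reference panel is named, each cell carries a McNemar comparison on the
    paired per-sample detection calls.  Empty cells are emitted with n = 0
    and undefined rates, never dropped.
    """
    if specificity_mode not in ("pooled", "binned"):
        raise ConfigurationError(f"unknown specificity_mode {specificity_mode!r}")
    if sensitivity_unit not in ("per_sample", "per_subject"):
        raise ConfigurationError(f"unknown sensitivity_unit {sensitivity_unit!r}")
    by_name = {p.name: p for p in panels}
    if reference_panel is not None and reference_panel not in by_name:
        raise ConfigurationError(f"reference panel {reference_panel!r} not in panel list")

    controls = cohort.control_samples()
    bin_labels: list[str]
    bin_of: dict[str, str] = {}
    if bins is None:
        bin_labels = ["pooled"]
    else:
        bin_of = assign_bins(cohort, bins, include_controls=True)
        bin_labels = [b.label for b in sorted(bins, key=lambda b: b.lower_days)]

    detect = {p.name: {} for p in panels}  # panel -> sample_id -> bool

    def calls(panel: PanelModel, samples: Sequence[Sample]) -> np.ndarray:
        cache = detect[panel.name]
        out = np.empty(len(samples), dtype=bool)
        for i, s in enumerate(samples):
            if s.sample_id not in cache:
                cache[s.sample_id] = evaluate_sample(panel, s, missing_policy)
            out[i] = cache[s.sample_id]
        return out

    subjects_of = {s.sample_id: s.subject_id for s in cohort.samples}
    rows: list[BinnedPerformance] = []
    for panel in panels:
        for stratum in strata:
            stratum_cases = cohort.case_samples_of_subtype(stratum)
            for label in bin_labels:
                if bins is None:
                    cell_cases = stratum_cases
                    cell_controls = controls
                else:
                    cell_cases = [
                        s for s in stratum_cases if bin_of.get(s.sample_id) == label
                    ]
                    cell_controls = (
                        [s for s in controls if bin_of.get(s.sample_id) == label]
                        if specificity_mode == "binned"
                        else controls
                    )
                case_calls = calls(panel, cell_cases)
                control_calls = calls(panel, cell_controls)

                if sensitivity_unit == "per_subject" and cell_cases:
                    pos_subjects, all_subjects = set(), set()
                    for s, hit in zip(cell_cases, case_calls):
                        all_subjects.add(subjects_of[s.sample_id])
                        if hit:
                            pos_subjects.add(subjects_of[s.sample_id])
                    n_case = len(all_subjects)
                    sens = len(pos_subjects) / n_case if n_case else None
                else:
                    n_case = len(cell_cases)
                    sens = float(case_calls.mean()) if n_case else None

                n_control = len(cell_controls)
                spec = float(1.0 - control_calls.mean()) if n_control else None
                if n_case == 0 or n_control == 0:
                    logger.warning(
                        "empty cell: panel=%s stratum=%s bin=%s (n_case=%d, n_control=%d)",
                        panel.name, stratum, label, n_case, n_control,
                    )

                mc = None
                if reference_panel is not None and cell_cases:
                    ref_calls = calls(by_name[reference_panel], cell_cases)
                    b = int(np.sum(case_calls & ~ref_calls))
                    c = int(np.sum(~case_calls & ref_calls))
                    mc = mcnemar(b, c)
                rows.append(
                    BinnedPerformance(
                        panel=panel.name, stratum=stratum, bin=label,
                        n_case_samples=n_case, n_control_samples=n_control,
                        sensitivity=sens, specificity=spec, mcnemar_vs_ref=mc,
                    )
                )
    return rows


def roc_curve(
    cohort: Cohort,
    marker_directions: dict[str, str],
    alphas: Sequence[float],
    stratum: str = "pan",
    missing_policy: str = "negative",
) -> tuple[list[tuple[float, float]], float]:
    """Empirical ROC of an OR-rule panel swept through calibration FPR alpha.

    All rules (CA125 included, on its own control-quantile scale) are
    recalibrated at each alpha on the cohort's control samples, the OR panel
    is evaluated, and the empirical (FPR, TPR) pair recorded.  The curve is
    anchored at (0,0) and (1,1); AUC is the trapezoid over FPR.
    """
    alphas = sorted(set(float(a) for a in alphas))
    if len(alphas) < 2:
        raise ValueError("need at least 2 alpha grid points")
    if any(not (0.0 < a < 1.0) for a in alphas):
        raise ValueError("alphas must lie in (0, 1)")
    controls = cohort.control_samples()
    cases = cohort.case_samples_of_subtype(stratum)
    if not controls or not cases:
        raise ValueError("ROC needs both case and control samples")

    points = {(0.0, 0.0), (1.0, 1.0)}
    for a in alphas:
        rules = tuple(
            calibrate_threshold(cohort.marker_values(m, controls), d, a, marker=m)
            for m, d in marker_directions.items()
        )
        panel = PanelModel(f"roc@{a:g}", rules)
        fpr = float(_detection_vector(panel, controls, missing_policy).mean())
        tpr = float(_detection_vector(panel, cases, missing_policy).mean())
        points.add((fpr, tpr))
    curve = sorted(points)
    xs = np.array([p[0] for p in curve])
    ys = np.array([p[1] for p in curve])
    # enforce monotone TPR over the empirical staircase before integrating
    ys = np.maximum.accumulate(ys)
    auc = float(np.trapezoid(ys, xs))
    return list(zip(xs.tolist(), ys.tolist())), auc
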