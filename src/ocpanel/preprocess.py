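"""Log/unit-variance scaling of marker levels and time-to-diagnosis binning.

Concentrations are natural-log transformed and centred/scaled by the mean
and SD of a reference stratum (all samples by default, controls-only as a
sensitivity analysis) so that markers with different units can be compared
on one axis.  Serial samples are assigned to yearly time-to-diagnosis bins,
with everything beyond four years grouped into one open-ended bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, Group
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TimeBin:
    """Half-open time-to-diagnosis interval [lower_days, upper_days) in days."""

    label: str
    lower_days: float
    upper_days: float  # math.inf for the open-ended last bin

    def __post_init__(self):
        if not self.lower_days < self.upper_days:
            raise ConfigurationError(
                f"bin {self.label!r}: lower bound must be < upper bound"
            )

    def contains(self, tdx: float) -> bool:
        return self.lower_days <= tdx < self.upper_days


@dataclass
class ScaledMatrix:
    """Scaled log-levels (samples x markers) plus the scaling parameters used."""

    values: pd.DataFrame
    scaling_params: dict[str, tuple[float, float]]  # marker -> (log mean, log sd)


def default_bins() -> list[TimeBin]:
    """Yearly tDx bins: <1y, 1-2y, 2-3y, 3-4y and the pooled >4y bin."""
    y = DAYS_PER_YEAR
    return [
        TimeBin("<1y", 0.0, y),
        TimeBin("1-2y", y, 2 * y),
        TimeBin("2-3y", 2 * y, 3 * y),
        TimeBin("3-4y", 3 * y, 4 * y),
        TimeBin(">4y", 4 * y, np.inf),
    ]


def _check_partition(bins: Sequence[TimeBin]) -> list[TimeBin]:
    if not bins:
        raise ConfigurationError("bin list must be non-empty")
    ordered = sorted(bins, key=lambda b: b.lower_days)
    if ordered[0].lower_days != 0.0:
        raise ConfigurationError("bins must start at 0 days")
    for a, b in zip(ordered, ordered[1:]):
        if a.upper_days > b.lower_days:
            raise ConfigurationError(f"bins {a.label!r} and {b.label!r} overlap")
        if a.upper_days < b.lower_days:
            raise ConfigurationError(f"gap between bins {a.label!r} and {b.label!r}")
    if not np.isinf(ordered[-1].upper_days):
        raise ConfigurationError("last bin must be open-ended (upper bound inf)")
    return ordered


def assign_bins(
    cohort: Cohort,
    bins: Optional[Sequence[TimeBin]] = None,
    include_controls: bool = True,
) -> dict[str, str]:
    """Map sample_id -> bin label by time to diagnosis.

    Bins must partition [0, inf).  Case samples always carry tDx; control
    samples are binned on their pseudo-tDx when present and
    ``include_controls`` is set, otherwise they are left out (pooled-control
    mode).
    """
    ordered = _check_partition(bins if bins is not None else default_bins())
    by_id = cohort.subjects_by_id()
    lowers = [b.lower_days for b in ordered]
    assignment: dict[str, str] = {}
    for sample in cohort.samples:
        is_control = by_id[sample.subject_id].group is Group.CONTROL
        if sample.tdx_days is None or (is_control and not include_controls):
            continue
        idx = int(np.searchsorted(lowers, sample.tdx_days, side="right")) - 1
        assignment[sample.sample_id] = ordered[idx].label
    return assignment


def log_scale(
    cohort: Cohort,
    markers: Iterable[str],
    reference: str = "all_samples",
    strict: bool = False,
) -> ScaledMatrix:
    """Natural-log transform then centre/scale each marker to unit variance.

    The mean/SD are estimated on the reference stratum (``all_samples`` or
    ``controls_only``) and applied to every sample.  Non-positive
    concentrations are floored at half the smallest positive observed value
    for that marker (logged), or rejected when ``strict``.
    """
    if reference not in ("all_samples", "controls_only"):
        raise ValueError(f"unknown reference stratum {reference!r}")
    markers = list(markers)
    for m in markers:
        if m not in cohort.marker_units:
            raise KeyError(f"marker {m!r} not present in cohort")

    control_ids = {s.sample_id for s in cohort.control_samples()}
    index = [s.sample_id for s in cohort.samples]
    raw = pd.DataFrame(
        {m: [s.markers.get(m) for s in cohort.samples] for m in markers},
        index=index,
        dtype=float,
    )

    logged = pd.DataFrame(index=index, columns=markers, dtype=float)
    params: dict[str, tuple[float, float]] = {}
    for m in markers:
        col = raw[m].to_numpy()
        nonpos = np.isfinite(col) & (col <= 0)
        if nonpos.any():
            if strict:
                raise ValueError(f"marker {m!r}: non-positive values in strict mode")
            positive = col[np.isfinite(col) & (col > 0)]
            if positive.size == 0:
                raise ValueError(f"marker {m!r}: no positive values to anchor floor")
            floor = 0.5 * positive.min()
            logger.warning(
                "marker %s: %d non-positive value(s) floored at %g",
                m, int(nonpos.sum()), floor,
            )
            col = col.copy()
            col[nonpos] = floor
        logs = np.log(col)
        ref_mask = (
            np.ones(len(index), dtype=bool)
            if reference == "all_samples"
            else np.array([sid in control_ids for sid in index])
        )
        ref_logs = logs[ref_mask & np.isfinite(logs)]
        if ref_logs.size < 2:
            raise ValueError(f"marker {m!r}: reference stratum too small to scale")
        mean = float(ref_logs.mean())
        sd = float(ref_logs.std(ddof=0))  # population SD: reference stratum gets variance exactly 1
        if sd == 0:
            raise ValueError(f"marker {m!r}: zero variance in reference stratum")
        logged[m] = (logs - mean) / sd
        params[m] = (mean, sd)
    return ScaledMatrix(values=logged, scaling_params=params)
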