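"""Differential marker-level comparisons and the epidemiological screen.

Three comparison designs mirror the analysis stages of the motivating
study: *discovery* (two samples per woman, one near and one far from
diagnosis), *triage* (all samples pooled, no temporal information) and
*screening* (serial samples in yearly time-to-diagnosis bins).  Each marker
is compared between case strata (Type I, Type II, pan) and controls with
the Mann-Whitney test on raw concentrations — rank tests are invariant to
the log/unit-variance display scaling, so testing raw values is
consequence-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Optional, Sequence

from .cohort import Cohort, Group, Sample, SplitSpec, make_discovery_set
from .preprocess import TimeBin, assign_bins, default_bins
from .stats import TestResult, fisher_exact_2x2, mann_whitney, pearson_correlation

logger = logging.getLogger(__name__)

#: Markers carried into the corroboration analyses; GRP78 and calprotectin
#: participate only in the discovery design by default.
CORROBORATION_MARKERS = ("igfbp2", "lcat", "shbg", "ca125")
DISCOVERY_MARKERS = ("igfbp2", "lcat", "shbg", "grp78", "calprotectin", "ca125")

CONTINUOUS_COVARIATES = ("age_at_sample", "bmi")
BINARY_COVARIATES = ("hrt_recruitment", "hrt_followup", "ocp_ever", "smoker_ever")


@dataclass
class ComparisonRow:
    marker: str
    stratum: str                 # "type1" | "type2" | "pan"
    bin: str                     # bin label, "pooled", "discovery:<14m"/">32m"
    direction: Optional[str]     # "up" | "down" (cases vs controls)
    test: Optional[TestResult]
    n_case: int
    n_control: int
    flagged_empty: bool = False


def _direction(case_vals: Sequence[float], control_vals: Sequence[float]) -> Optional[str]:
    if not case_vals or not control_vals:
        return None
    diff = median(case_vals) - median(control_vals)
    return "up" if diff > 0 else "down"


def _compare_cell(
    cohort: Cohort,
    marker: str,
    stratum: str,
    bin_label: str,
    case_samples: Sequence[Sample],
    control_samples: Sequence[Sample],
) -> ComparisonRow:
    case_vals = cohort.marker_values(marker, case_samples)
    control_vals = cohort.marker_values(marker, control_samples)
    if not case_vals or not control_vals:
        logger.warning(
            "empty comparison cell: marker=%s stratum=%s bin=%s", marker, stratum, bin_label
        )
        return ComparisonRow(
            marker, stratum, bin_label, None, None,
            len(case_vals), len(control_vals), flagged_empty=True,
        )
    return ComparisonRow(
        marker=marker,
        stratum=stratum,
        bin=bin_label,
        direction=_direction(case_vals, control_vals),
        test=mann_whitney(case_vals, control_vals),
        n_case=len(case_vals),
        n_control=len(control_vals),
    )


def compare_levels(
    cohort: Cohort,
    markers: Sequence[str],
    design: str,
    bins: Optional[Sequence[TimeBin]] = None,
    split: SplitSpec = SplitSpec(),
    strata: Sequence[str] = ("type1", "type2", "pan"),
    binned_controls: bool = True,
) -> list[ComparisonRow]:
    """Mann-Whitney case-vs-control comparison per marker x stratum x cell.

    ``design`` is one of ``'discovery'`` (near/far windows of the discovery
    split, controls windowed on pseudo-tDx), ``'triage_pooled'`` (all
    samples, one pooled cell) or ``'screening_binned'`` (yearly tDx bins;
    controls binned on pseudo-tDx when ``binned_controls``, else pooled).
    """
    rows: list[ComparisonRow] = []
    if design == "discovery":
        disc = make_discovery_set(cohort, split)
        windows = {
            f"discovery:<{split.near_max_months:g}m": (
                lambda s: s.tdx_days is not None and s.tdx_days < split.near_max_days
            ),
            f"discovery:>{split.far_min_months:g}m": (
                lambda s: s.tdx_days is not None and s.tdx_days > split.far_min_days
            ),
        }
        for label, pred in windows.items():
            controls = [s for s in disc.control_samples() if pred(s)]
            for marker in markers:
                for stratum in strata:
                    cases = [s for s in disc.case_samples_of_subtype(stratum) if pred(s)]
                    rows.append(_compare_cell(disc, marker, stratum, label, cases, controls))
    elif design == "triage_pooled":
        controls = cohort.control_samples()
        for marker in markers:
            for stratum in strata:
                cases = cohort.case_samples_of_subtype(stratum)
                rows.append(_compare_cell(cohort, marker, stratum, "pooled", cases, controls))
    elif design == "screening_binned":
        bin_list = list(bins) if bins is not None else default_bins()
        bin_of = assign_bins(cohort, bin_list, include_controls=binned_controls)
        all_controls = cohort.control_samples()
        for marker in markers:
            for stratum in strata:
                stratum_cases = cohort.case_samples_of_subtype(stratum)
                for b in sorted(bin_list, key=lambda x: x.lower_days):
                    cases = [s for s in stratum_cases if bin_of.get(s.sample_id) == b.label]
                    controls = (
                        [s for s in all_controls if bin_of.get(s.sample_id) == b.label]
                        if binned_controls
                        else all_controls
                    )
                    rows.append(_compare_cell(cohort, marker, stratum, b.label, cases, controls))
    else:
        raise ValueError(f"unknown design {design!r}")
    return rows


def covariate_screen(
    cohort: Cohort,
    markers: Sequence[str],
    covariates: Optional[Sequence[str]] = None,
    split: SplitSpec = SplitSpec(),
) -> list[ComparisonRow]:
    """Pearson screen of marker levels against epidemiological covariates.

    Runs on the discovery split.  Continuous covariates (age at sample,
    BMI) and 0/1-coded binary covariates (HRT, OCP ever, smoking) are both
    handled by the product-moment correlation; a Fisher's exact check of
    each binary covariate against case/control status is appended with the
    pseudo-marker name ``'diagnosis'``.
    """
    if covariates is None:
        covariates = CONTINUOUS_COVARIATES + BINARY_COVARIATES
    disc = make_discovery_set(cohort, split)
    by_id = disc.subjects_by_id()
    rows: list[ComparisonRow] = []
    for cov in covariates:
        pairs_per_marker: dict[str, list[tuple[float, float]]] = {m: [] for m in markers}
        for sample in disc.samples:
            subj = by_id[sample.subject_id]
            if cov == "age_at_sample":
                value = sample.age_at_sample
            else:
                value = getattr(subj, cov, None)
            if value is None:
                continue
            value = float(value)
            for m in markers:
                conc = sample.markers.get(m)
                if conc is not None:
                    pairs_per_marker[m].append((value, conc))
        for m in markers:
            pairs = pairs_per_marker[m]
            if len(pairs) < 3:
                logger.warning("covariate %s: too few pairs for marker %s; skipped", cov, m)
                rows.append(ComparisonRow(m, "pan", cov, None, None, len(pairs), 0, True))
                continue
            xs = [p[0] for p in pairs]
            ys = [p[1] for p in pairs]
            try:
                res = pearson_correlation(xs, ys)
            except ValueError:
                rows.append(ComparisonRow(m, "pan", cov, None, None, len(pairs), 0, True))
                continue
            rows.append(
                ComparisonRow(
                    marker=m, stratum="pan", bin=cov,
                    direction="up" if res.statistic > 0 else "down",
                    test=res, n_case=len(pairs), n_control=0,
                )
            )
        if cov in BINARY_COVARIATES:
            table = [[0, 0], [0, 0]]
            for subj in disc.subjects:
                flag = getattr(subj, cov, None)
                if flag is None:
                    continue
                i = 0 if subj.group is Group.CASE else 1
                j = 0 if flag else 1
                table[i][j] += 1
            if sum(sum(r) for r in table) > 0:
                rows.append(
                    ComparisonRow(
                        marker="diagnosis", stratum="pan", bin=cov,
                        direction=None, test=fisher_exact_2x2(table),
                        n_case=sum(table[0]), n_control=sum(table[1]),
                    )
                )
    return rows
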