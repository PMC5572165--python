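"""End-to-end orchestration: ingest/simulate through report assembly.

`run_pipeline` executes every stage on one cohort — discovery comparisons,
covariate screen, triage and screening performance tables, ROC/AUC,
lead-time estimation and breach-stratified prognosis — and writes TSV
tables plus a JSON run manifest into a report directory.  Identical
config + seed produce byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cohort import Cohort, SplitSpec, read_cohort, write_cohort
from .compare import (
    CORROBORATION_MARKERS,
    DISCOVERY_MARKERS,
    ComparisonRow,
    compare_levels,
    covariate_screen,
)
from .config import (
    HEADLINE_PANEL_NAME,
    REFERENCE_PANEL_NAME,
    PipelineConfig,
    bins_from_edges,
)
from .errors import ConfigurationError
from .leadtime import LeadTimeResult, lead_time_summary, pooled_mean_lead
from .panels import (
    BinnedPerformance,
    MARKER_DIRECTIONS,
    PanelModel,
    calibrate_panel,
    performance_table,
    published_panel,
    roc_curve,
)
from .preprocess import default_bins
from .simulate import CohortDesign, simulate_cohort
from .survival import stratify_by_breach

logger = logging.getLogger(__name__)


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def build_panels(cohort: Cohort, config: PipelineConfig) -> list[PanelModel]:
    """Construct the configured panels, calibrated or published-fixed."""
    panels = []
    for markers in config.panels:
        if config.use_published_thresholds:
            panels.append(published_panel(markers))
        else:
            panels.append(
                calibrate_panel(
                    cohort, markers, alpha=config.alpha, fixed=config.fixed_thresholds
                )
            )
    return panels


def _fmt(value, digits=6):
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.{digits}g}"
    return str(value)


def _comparison_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": r.marker,
                "stratum": r.stratum,
                "bin": r.bin,
                "direction": r.direction or "",
                "p_value": _fmt(r.test.p_value if r.test else None),
                "statistic": _fmt(r.test.statistic if r.test else None),
                "method": r.test.method if r.test else "",
                "n_case": r.n_case,
                "n_control": r.n_control,
                "flagged_empty": int(r.flagged_empty),
            }
            for r in rows
        ]
    )


def _performance_frame(rows: Sequence[BinnedPerformance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "panel": r.panel,
                "stratum": r.stratum,
                "bin": r.bin,
                "n_case_samples": r.n_case_samples,
                "n_control_samples": r.n_control_samples,
                "sensitivity": _fmt(r.sensitivity),
                "specificity": _fmt(r.specificity),
                "mcnemar_p_vs_ref": _fmt(
                    r.mcnemar_vs_ref.p_value if r.mcnemar_vs_ref else None
                ),
            }
            for r in rows
        ]
    )


def _leadtime_frame(results: Sequence[LeadTimeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "panel": r.panel,
                "stratum": r.stratum,
                "n_detected": r.n_detected,
                "n_missed": r.n_never_detected,
                "mean_lead_days": _fmt(r.mean_lead_days),
                "ref_mean_lead_days": _fmt(r.reference_mean_lead_days),
                "n_earlier_than_ref": r.n_detected_earlier_than_ref,
                "n_ref_missed": r.n_detected_ref_missed,
                "gain_pct": "" if r.gain_pct is None else r.gain_pct,
                "paired_p": _fmt(
                    r.paired_comparison.p_value if r.paired_comparison else None
                ),
            }
            for r in results
        ]
    )


def run_pipeline(config: PipelineConfig, cohort: Optional[Cohort] = None) -> Path:
    """Run every analysis stage and write the report directory.

    A pre-loaded cohort may be passed directly; otherwise it is read from
    ``config.input_path`` or simulated from the default design at
    ``config.seed``.
    """
    config.validate()
    counter = _WarningCounter()
    logging.getLogger("ocpanel").addHandler(counter)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        stage = "ingest"
        if cohort is None:
            if config.input_path is not None:
                cohort = read_cohort(config.input_path)
            else:
                cohort = simulate_cohort(CohortDesign(seed=config.seed))
                write_cohort(cohort, outdir / "cohort.csv")

        split = SplitSpec()
        bins = (
            bins_from_edges(config.bin_edges_days)
            if config.bin_edges_days
            else default_bins()
        )

        stage = "discovery comparison"
        disc_rows = compare_levels(cohort, DISCOVERY_MARKERS, "discovery", split=split)
        _comparison_frame(disc_rows).to_csv(
            outdir / "discovery_comparison.tsv", sep="\t", index=False
        )

        stage = "covariate screen"
        cov_rows = covariate_screen(cohort, DISCOVERY_MARKERS, split=split)
        _comparison_frame(cov_rows).to_csv(
            outdir / "covariate_screen.tsv", sep="\t", index=False
        )

        stage = "triage comparison"
        triage_rows = compare_levels(cohort, CORROBORATION_MARKERS, "triage_pooled")
        _comparison_frame(triage_rows).to_csv(
            outdir / "triage_comparison.tsv", sep="\t", index=False
        )

        stage = "screening comparison"
        screen_rows = compare_levels(
            cohort, CORROBORATION_MARKERS, "screening_binned", bins=bins
        )
        _comparison_frame(screen_rows).to_csv(
            outdir / "screening_comparison.tsv", sep="\t", index=False
        )

        stage = "panel calibration"
        panels = build_panels(cohort, config)
        panel_frame = pd.DataFrame(
            [
                {
                    "panel": p.name,
                    "marker": r.marker,
                    "direction": r.direction,
                    "threshold": _fmt(r.threshold),
                    "provenance": r.provenance,
                }
                for p in panels
                for r in p.rules
            ]
        )
        panel_frame.to_csv(outdir / "panel_thresholds.tsv", sep="\t", index=False)

        stage = "triage performance"
        triage_perf = performance_table(
            cohort, panels, bins=None,
            reference_panel=REFERENCE_PANEL_NAME,
            specificity_mode="pooled",
            sensitivity_unit=config.sensitivity_unit,
            missing_policy=config.missing_policy,
        )
        _performance_frame(triage_perf).to_csv(
            outdir / "triage_performance.tsv", sep="\t", index=False
        )

        stage = "screening performance"
        screen_perf = performance_table(
            cohort, panels, bins=bins,
            reference_panel=REFERENCE_PANEL_NAME,
            specificity_mode=config.specificity_mode,
            sensitivity_unit=config.sensitivity_unit,
            missing_policy=config.missing_policy,
        )
        _performance_frame(screen_perf).to_csv(
            outdir / "screening_performance.tsv", sep="\t", index=False
        )

        stage = "roc"
        alphas = [i / 100 for i in range(1, 100)]
        roc_summary = []
        for panel in panels:
            directions = {m: MARKER_DIRECTIONS[m] for m in panel.markers}
            _, auc = roc_curve(cohort, directions, alphas, missing_policy=config.missing_policy)
            roc_summary.append({"panel": panel.name, "auc": _fmt(auc)})
        pd.DataFrame(roc_summary).to_csv(outdir / "roc_auc.tsv", sep="\t", index=False)

        stage = "lead time"
        by_name = {p.name: p for p in panels}
        reference = by_name[REFERENCE_PANEL_NAME]
        lead_results: list[LeadTimeResult] = []
        for panel in panels:
            if panel.name == REFERENCE_PANEL_NAME:
                continue
            for stratum in ("type1", "type2", "pan"):
                lead_results.append(
                    lead_time_summary(
                        cohort, panel, reference, stratum=stratum,
                        mode=config.leadtime_mode,
                        missing_policy=config.missing_policy,
                    )
                )
        _leadtime_frame(lead_results).to_csv(
            outdir / "lead_time.tsv", sep="\t", index=False
        )

        stage = "prognosis"
        headline = by_name.get(HEADLINE_PANEL_NAME, panels[-1])
        survival_rows = []
        for panel in (headline, reference):
            breachers, non_breachers, test = stratify_by_breach(
                cohort, panel, stratum="type2", missing_policy=config.missing_policy
            )
            for arm, curve in (("breach", breachers), ("no_breach", non_breachers)):
                if curve is None:
                    continue
                for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
                    survival_rows.append(
                        {
                            "panel": panel.name, "arm": arm,
                            "time_days": _fmt(t), "survival": _fmt(s), "at_risk": r,
                            "logrank_p": _fmt(test.p_value if test else None),
                        }
                    )
            if config.make_plots:
                from .plotting import plot_km_pair

                plot_km_pair(
                    breachers, non_breachers,
                    outdir / f"survival_{panel.name.replace(':', '_')}.png",
                    title=f"Type II survival by {panel.name} breach",
                )
        pd.DataFrame(survival_rows).to_csv(
            outdir / "survival_curves.tsv", sep="\t", index=False
        )

        if config.make_plots:
            from .plotting import plot_sensitivity_by_bin

            plot_sensitivity_by_bin(
                screen_perf, [b.label for b in bins],
                outdir / "sensitivity_by_bin.png",
            )

        stage = "manifest"
        manifest = {
            "ocpanel_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "n_subjects": len(cohort.subjects),
            "n_cases": len(cohort.cases()),
            "n_controls": len(cohort.controls()),
            "n_samples": len(cohort.samples),
            "warnings": counter.count,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except ConfigurationError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logging.getLogger("ocpanel").removeHandler(counter)
    return outdir
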