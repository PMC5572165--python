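"""Threshold calibration, OR-panel evaluation, performance tables, ROC."""

import math

import numpy as np
import pytest

from ocpanel import (
    Cohort,
    Group,
    calibrate_threshold,
    evaluate_sample,
    performance_table,
    published_panel,
    roc_curve,
)
from ocpanel.cohort import Sample, Subject, Subtype
from ocpanel.panels import MarkerRule, PanelModel
from tests.conftest import make_sample


class TestCalibration:
    def test_above_order_statistic(self):
        rule = calibrate_threshold(range(1, 101), "above", 0.05, marker="m")
        assert rule.threshold == 95
        breaches = sum(v > rule.threshold for v in range(1, 101))
        assert breaches == 5  # exactly alpha * n calibration controls breach

    def test_below_mirror(self):
        rule = calibrate_threshold(range(1, 101), "below", 0.05, marker="m")
        assert rule.threshold == 6
        assert [v for v in range(1, 101) if v < rule.threshold] == [1, 2, 3, 4, 5]

    def test_in_sample_fpr_never_exceeds_alpha(self):
        r = np.random.default_rng(0)
        for trial in range(50):
            n = int(r.integers(20, 300))
            alpha = float(r.uniform(0.01, 0.3))
            values = r.normal(size=n)
            direction = "above" if trial % 2 else "below"
            rule = calibrate_threshold(values, direction, alpha)
            fpr = np.mean([rule.breached(v) for v in values])
            assert fpr <= alpha + 1e-12

    def test_out_of_sample_fpr_converges(self):
        r = np.random.default_rng(1)
        train = r.normal(size=10_000)
        test = r.normal(size=10_000)
        rule = calibrate_threshold(train, "above", 0.05)
        fpr = np.mean([rule.breached(v) for v in test])
        se = math.sqrt(0.05 * 0.95 / 10_000)
        assert abs(fpr - 0.05) < 3 * se

    def test_alpha_domain_error(self):
        with pytest.raises(ValueError):
            calibrate_threshold([1, 2, 3], "above", 1.5)

    def test_few_controls_warns(self, caplog):
        with caplog.at_level("WARNING", logger="ocpanel.panels"):
            calibrate_threshold(range(10), "above", 0.05, marker="m")
        assert any("unstable" in r.message for r in caplog.records)


class TestEvaluateSample:
    combined = published_panel(["igfbp2", "lcat", "ca125"])

    def test_single_rule_panel_is_raw_threshold(self):
        panel = PanelModel("one", (MarkerRule("ca125", "above", 35.0),))
        assert evaluate_sample(panel, make_sample("s", "w", 0, ca125=36.0))
        assert not evaluate_sample(panel, make_sample("s", "w", 0, ca125=34.0))

    def test_published_combined_panel_fires_on_igfbp2_alone(self):
        sample = make_sample("s", "w", 0, igfbp2=80.0, lcat=9.0, ca125=20.0)
        assert evaluate_sample(self.combined, sample)

    def test_values_exactly_at_thresholds_are_negative(self):
        sample = make_sample("s", "w", 0, igfbp2=78.5, lcat=8.831, ca125=35.0)
        assert not evaluate_sample(self.combined, sample)

    def test_missing_marker_negative_by_default(self):
        sample = make_sample("s", "w", 0, igfbp2=None, lcat=None, ca125=10.0)
        assert not evaluate_sample(self.combined, sample)

    def test_missing_marker_error_policy(self):
        sample = make_sample("s", "w", 0, ca125=10.0)
        with pytest.raises(ValueError, match="missing"):
            evaluate_sample(self.combined, sample, missing_policy="error")

    def test_duplicate_marker_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PanelModel("bad", (
                MarkerRule("ca125", "above", 35.0),
                MarkerRule("ca125", "above", 20.0),
            ))


def two_level_cohort():
    """4 case samples (2 breach CA125>35), 4 control samples (1 breaches)."""
    subjects = [
        Subject("w1", Group.CASE, Subtype.TYPE2, raw_subtype="type2"),
        Subject("w2", Group.CONTROL),
    ]
    case_vals = [50.0, 40.0, 20.0, 10.0]
    ctrl_vals = [36.0, 20.0, 15.0, 5.0]
    samples = [
        make_sample(f"c{i}", "w1", 100.0 * i, ca125=v) for i, v in enumerate(case_vals)
    ] + [
        make_sample(f"k{i}", "w2", 100.0 * i, ca125=v) for i, v in enumerate(ctrl_vals)
    ]
    return Cohort(subjects=subjects, samples=samples)


class TestPerformanceTable:
    ca125 = published_panel(["ca125"], name="CA125")

    def test_sensitivity_specificity_counts(self):
        rows = performance_table(two_level_cohort(), [self.ca125], strata=["pan"])
        (row,) = rows
        assert row.n_case_samples == 4 and row.n_control_samples == 4
        assert row.sensitivity == pytest.approx(0.5)
        assert row.specificity == pytest.approx(0.75)

    def test_reference_vs_itself_mcnemar_p_one(self, default_cohort):
        rows = performance_table(
            default_cohort, [self.ca125], reference_panel="CA125"
        )
        assert all(
            r.mcnemar_vs_ref.p_value == 1.0
            for r in rows if r.mcnemar_vs_ref is not None
        )

    def test_or_monotonicity_on_synthetic_cohort(self, default_cohort):
        base = published_panel(["ca125"], name="base")
        superset = published_panel(["igfbp2", "lcat", "ca125"], name="super")
        rows = performance_table(default_cohort, [base, superset])
        by_cell = {}
        for r in rows:
            by_cell.setdefault((r.stratum, r.bin), {})[r.panel] = r
        for cell in by_cell.values():
            b, s = cell["base"], cell["super"]
            if b.sensitivity is not None:
                assert s.sensitivity >= b.sensitivity
            if b.specificity is not None:
                assert s.specificity <= b.specificity

    def test_sensitivity_equals_mean_of_evaluate(self, default_cohort):
        panel = published_panel(["igfbp2", "ca125"], name="p")
        (row,) = performance_table(default_cohort, [panel], strata=["type2"])
        cases = default_cohort.case_samples_of_subtype("type2")
        direct = np.mean([evaluate_sample(panel, s) for s in cases])
        assert row.sensitivity == pytest.approx(direct)

    def test_empty_cell_emitted_flagged(self, caplog):
        cohort = two_level_cohort()  # has no type1 subjects
        with caplog.at_level("WARNING", logger="ocpanel.panels"):
            rows = performance_table(cohort, [self.ca125], strata=["type1"])
        (row,) = rows
        assert row.n_case_samples == 0
        assert row.sensitivity is None
        assert any("empty cell" in r.message for r in caplog.records)

    def test_per_subject_unit(self):
        cohort = two_level_cohort()
        (row,) = performance_table(
            cohort, [self.ca125], strata=["pan"], sensitivity_unit="per_subject"
        )
        # the one case woman breaches at some sample -> subject-level sens 1
        assert row.n_case_samples == 1
        assert row.sensitivity == 1.0


class TestRandomisedPanelProperties:
    def test_or_monotonicity_random_cohorts(self):
        """Adding a rule never lowers sensitivity nor raises specificity."""
        r = np.random.default_rng(99)
        for _ in range(200):
            n_case, n_ctrl = int(r.integers(2, 20)), int(r.integers(2, 20))
            case_vals = r.lognormal(3, 1, size=(n_case, 3))
            ctrl_vals = r.lognormal(3, 1, size=(n_ctrl, 3))
            markers = ["a", "b", "c"]
            rules = tuple(
                MarkerRule(m, "above" if r.random() < 0.5 else "below",
                           float(r.lognormal(3, 1)))
                for m in markers[:2]
            )
            extra = MarkerRule("c", "above", float(r.lognormal(3, 1)))
            base, sup = PanelModel("b", rules), PanelModel("s", rules + (extra,))

            def rates(panel):
                def hit(vals):
                    return any(
                        rule.breached(v)
                        for rule, v in zip(panel.rules, vals[: len(panel.rules)])
                    )
                sens = np.mean([
                    any(rule.breached(row[markers.index(rule.marker)])
                        for rule in panel.rules)
                    for row in case_vals
                ])
                spec = 1 - np.mean([
                    any(rule.breached(row[markers.index(rule.marker)])
                        for rule in panel.rules)
                    for row in ctrl_vals
                ])
                return sens, spec

            sens_b, spec_b = rates(base)
            sens_s, spec_s = rates(sup)
            assert sens_s >= sens_b
            assert spec_s <= spec_b


class TestROC:
    def test_complete_separation_auc_one(self):
        subjects = [
            Subject("w1", Group.CASE, Subtype.TYPE1, raw_subtype="type1"),
            Subject("w2", Group.CONTROL),
        ]
        samples = [
            make_sample(f"c{i}", "w1", float(i), ca125=100.0 + i) for i in range(10)
        ] + [
            make_sample(f"k{i}", "w2", float(i), ca125=1.0 + i) for i in range(10)
        ]
        cohort = Cohort(subjects=subjects, samples=samples)
        # alpha=0.05 on 10 controls places the cutoff at the control maximum,
        # giving the (FPR 0, TPR 1) operating point of a separated marker
        curve, auc = roc_curve(cohort, {"ca125": "above"}, [0.05, 0.3, 0.5, 0.7, 0.9])
        assert auc == pytest.approx(1.0)
        assert (0.0, 1.0) in curve

    def test_null_marker_auc_half(self):
        r = np.random.default_rng(4)
        subjects = [
            Subject("w1", Group.CASE, Subtype.TYPE1, raw_subtype="type1"),
            Subject("w2", Group.CONTROL),
        ]
        n = 600
        samples = [
            make_sample(f"c{i}", "w1", float(i), ca125=float(v))
            for i, v in enumerate(r.lognormal(2, 0.5, n))
        ] + [
            make_sample(f"k{i}", "w2", float(i), ca125=float(v))
            for i, v in enumerate(r.lognormal(2, 0.5, n))
        ]
        cohort = Cohort(subjects=subjects, samples=samples)
        _, auc = roc_curve(cohort, {"ca125": "above"}, np.linspace(0.02, 0.98, 30))
        assert abs(auc - 0.5) < 0.05

    def test_uninformative_or_panel_tracks_closed_form(self):
        """k null markers OR-combined: TPR(alpha) = FPR(alpha) = 1-(1-a)^k."""
        r = np.random.default_rng(6)
        k, n = 3, 4000
        subjects = [
            Subject("w1", Group.CASE, Subtype.TYPE1, raw_subtype="type1"),
            Subject("w2", Group.CONTROL),
        ]
        names = ["igfbp2", "lcat", "shbg"]
        dirs = {"igfbp2": "above", "lcat": "below", "shbg": "below"}

        def mk(prefix, subj):
            return [
                Sample(
                    f"{prefix}{i}", subj, float(i),
                    markers={m: float(v) for m, v in zip(names, r.lognormal(2, 0.5, k))},
                )
                for i in range(n)
            ]

        cohort = Cohort(subjects=subjects, samples=mk("c", "w1") + mk("k", "w2"))
        alphas = [0.05, 0.1, 0.2]
        curve, auc = roc_curve(cohort, dirs, alphas)
        by_fpr = {round(f, 3): t for f, t in curve}
        for a in alphas:
            expected = 1 - (1 - a) ** k
            se = math.sqrt(expected * (1 - expected) / n)
            observed = [t for f, t in curve if abs(f - expected) < 4 * se]
            assert observed, f"no curve point near FPR {expected}"
            assert min(abs(t - expected) for t in observed) < 4 * se

    def test_monotone_and_bounded(self, default_cohort):
        curve, auc = roc_curve(
            default_cohort, {"igfbp2": "above", "ca125": "above"},
            np.linspace(0.05, 0.95, 10),
        )
        xs = [p[0] for p in curve]
        ys = [p[1] for p in curve]
        assert xs == sorted(xs) and ys == sorted(ys)
        assert 0.0 <= auc <= 1.0
        assert curve[0] == (0.0, 0.0) and curve[-1] == (1.0, 1.0)

    def test_degenerate_grid_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            roc_curve(default_cohort, {"ca125": "above"}, [0.5])
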