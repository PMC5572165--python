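"""Significance machinery checked against independent enumeration oracles.

Each oracle below recomputes the null distribution from first principles
(exhaustive enumeration of group assignments, binomial tail sums, direct
observed-minus-expected tabulation, label permutation) so the package's
call paths through scipy/statsmodels/lifelines are verified bit-for-bit on
small instances and within Monte-Carlo error on permutation checks.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom, t as t_dist

from ocpanel import (
    fisher_exact_2x2,
    logrank,
    mann_whitney,
    mcnemar,
    paired_t,
    pearson_correlation,
)

rng = np.random.default_rng(20260923)


# -- oracles ----------------------------------------------------------------

def mw_exact_oracle(x, y):
    """Two-tailed exact Mann-Whitney p by full enumeration of assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    n1n2 = n1 * len(y)
    lo, hi = min(u_obs, n1n2 - u_obs), max(u_obs, n1n2 - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


def fisher_oracle(table):
    """Two-tailed Fisher p: sum hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = hypergeom.pmf(k, n, r1, c1)
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(1.0, total)


def mcnemar_exact_oracle(b, c):
    """Two-tailed binomial(b+c, 1/2) tail doubling, clipped at 1."""
    n = b + c
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2**n
    return min(1.0, 2 * tail)


def paired_t_oracle(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return t, 2 * t_dist.sf(abs(t), n - 1)


def logrank_oracle(group1, group2):
    """Chi-square from a hand O-E/variance tabulation over event times."""
    data = [(t, e, 0) for t, e in group1] + [(t, e, 1) for t, e in group2]
    event_times = sorted({t for t, e, _ in data if e})
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = [(t, e, g) for t, e, g in data if t >= et]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for t, e, _ in at_risk if t == et and e)
        d1 = sum(1 for t, e, g in at_risk if t == et and e and g == 0)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


# -- Mann-Whitney -----------------------------------------------------------

class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(mw_exact_oracle([1, 2, 3], [4, 5, 6]))

    def test_identical_multisets_p_one(self):
        res = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_group_relabelling_symmetry(self):
        x = list(rng.normal(size=7))
        y = list(rng.normal(size=5))
        assert mann_whitney(x, y).p_value == pytest.approx(mann_whitney(y, x).p_value)

    @pytest.mark.parametrize("trial", range(30))
    def test_exact_matches_enumeration(self, trial):
        r = np.random.default_rng(trial)
        n1, n2 = int(r.integers(2, 6)), int(r.integers(2, 6))
        x = list(np.round(r.normal(size=n1), 6))
        y = list(np.round(r.normal(size=n2), 6))
        res = mann_whitney(x, y, mode="exact")
        assert res.p_value == pytest.approx(mw_exact_oracle(x, y), abs=1e-10)

    def test_normal_approx_close_to_exact(self):
        for trial in range(20):
            r = np.random.default_rng(1000 + trial)
            x = list(r.normal(size=8))
            y = list(r.normal(size=8))
            exact = mann_whitney(x, y, mode="exact").p_value
            approx = mann_whitney(x, y, mode="normal_approx").p_value
            assert abs(exact - approx) < 0.02

    def test_auto_switches_on_ties(self):
        x = [1.0, 2.0, 2.0, 3.0] * 3
        y = [2.0, 3.0, 3.0, 4.0] * 3
        res = mann_whitney(x, y, mode="auto")
        assert "asymptotic" in res.method


# -- Fisher -----------------------------------------------------------------

class TestFisherExact:
    def test_degenerate_all_zero(self):
        assert fisher_exact_2x2([[0, 0], [0, 0]]).p_value == 1.0

    def test_diagonal_table_vs_enumeration(self):
        res = fisher_exact_2x2([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(fisher_oracle([[5, 0], [0, 5]]))
        assert res.p_value == pytest.approx(2 / math.comb(10, 5))

    def test_row_swap_invariance(self):
        t1 = [[3, 7], [5, 2]]
        t2 = [[5, 2], [3, 7]]
        assert fisher_exact_2x2(t1).p_value == pytest.approx(fisher_exact_2x2(t2).p_value)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_exhaustive_small_tables(self):
        """All 2x2 tables with cells <= 3 agree with the hypergeometric oracle."""
        for cells in itertools.product(range(4), repeat=4):
            table = [[cells[0], cells[1]], [cells[2], cells[3]]]
            if sum(cells) == 0:
                continue
            assert fisher_exact_2x2(table).p_value == pytest.approx(
                fisher_oracle(table), abs=1e-10
            ), table


# -- Pearson ----------------------------------------------------------------

class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v + 1 for v in x]).statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_p_close_to_permutation(self):
        r = np.random.default_rng(3)
        x = r.normal(size=20)
        y = 0.5 * x + r.normal(size=20)
        res = pearson_correlation(x, y)
        obs = abs(np.corrcoef(x, y)[0, 1])
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            count += abs(np.corrcoef(x, r.permutation(y))[0, 1]) >= obs
        assert abs(res.p_value - count / n_perm) < 0.02


# -- McNemar ----------------------------------------------------------------

class TestMcNemar:
    def test_printed_discordant_example(self):
        res = mcnemar(1, 5, mode="exact")
        assert res.p_value == pytest.approx(0.21875)
        assert res.p_value == pytest.approx(mcnemar_exact_oracle(1, 5))

    def test_balanced_discordance(self):
        assert mcnemar(4, 4, mode="exact").p_value == pytest.approx(1.0)
        # continuity correction moves the statistic to 1/(2n), so p is high
        # but strictly below 1 at finite counts
        assert mcnemar(30, 30, mode="cc_chi2").p_value > 0.8

    def test_no_discordance_warns(self, caplog):
        with caplog.at_level("WARNING", logger="ocpanel.stats"):
            res = mcnemar(0, 0)
        assert res.p_value == 1.0
        assert any("no discordant" in r.message for r in caplog.records)

    def test_exhaustive_exact_vs_binomial_oracle(self):
        for b in range(13):
            for c in range(13):
                if b + c == 0:
                    continue
                assert mcnemar(b, c, mode="exact").p_value == pytest.approx(
                    mcnemar_exact_oracle(b, c), abs=1e-12
                ), (b, c)

    def test_auto_mode_threshold(self):
        assert "exact" in mcnemar(10, 10).method
        assert "chi2" in mcnemar(15, 15).method


# -- paired t ---------------------------------------------------------------

class TestPairedT:
    def test_identical_inputs_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_hand_computed_example(self):
        # differences {1,2,3}: mean 2, sd 1, t = 2*sqrt(3), df 2
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * math.sqrt(3))

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_formula_oracle(self, trial):
        r = np.random.default_rng(trial)
        n = int(r.integers(3, 13))
        x = r.normal(size=n)
        y = x + r.normal(size=n)
        res = paired_t(x, y)
        t_ref, p_ref = paired_t_oracle(x, y)
        assert res.statistic == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_null_rejection_rate_calibrated(self):
        rejections = 0
        n_reps = 2000
        r = np.random.default_rng(11)
        for _ in range(n_reps):
            x = r.normal(size=10)
            y = r.normal(size=10)
            rejections += paired_t(x, y).p_value < 0.05
        rate = rejections / n_reps
        band = 2.576 * math.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < band


# -- log-rank ---------------------------------------------------------------

class TestLogrank:
    def test_identical_groups(self):
        g = [(1.0, True), (2.0, True), (3.0, False)]
        res = logrank(g, list(g))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_tabulated_statistic(self):
        g1 = [(1.0, True), (2.0, True)]
        g2 = [(3.0, True), (4.0, True)]
        res = logrank(g1, g2)
        assert res.statistic == pytest.approx(logrank_oracle(g1, g2), abs=1e-8)

    def test_no_events_warns(self, caplog):
        with caplog.at_level("WARNING", logger="ocpanel.stats"):
            res = logrank([(1.0, False)], [(2.0, False)])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_oe_oracle(self, trial):
        r = np.random.default_rng(trial)
        n1, n2 = int(r.integers(2, 7)), int(r.integers(2, 7))
        g1 = [(float(t), bool(e)) for t, e in zip(r.exponential(5, n1), r.random(n1) < 0.8)]
        g2 = [(float(t), bool(e)) for t, e in zip(r.exponential(8, n2), r.random(n2) < 0.8)]
        if not any(e for _, e in g1 + g2):
            return
        res = logrank(g1, g2)
        assert res.statistic == pytest.approx(logrank_oracle(g1, g2), abs=1e-8)

    def test_p_close_to_label_permutation(self):
        r = np.random.default_rng(9)
        times = list(r.exponential(5, 10))
        events = [True] * 10
        labels = [0] * 5 + [1] * 5
        data = list(zip(times, events))
        split = lambda lab: (
            [d for d, g in zip(data, lab) if g == 0],
            [d for d, g in zip(data, lab) if g == 1],
        )
        obs = logrank(*split(labels)).statistic
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = r.permutation(labels)
            count += logrank_oracle(*split(perm)) >= obs - 1e-12
        # the 1-df chi-square reference at n=10 with all events is accurate
        # to several percentage points against the exact permutation law
        assert abs(logrank(*split(labels)).p_value - count / n_perm) < 0.08


def test_all_p_values_within_unit_interval():
    r = np.random.default_rng(0)
    for _ in range(20):
        x, y = r.normal(size=6), r.normal(size=6)
        assert 0 <= mann_whitney(x, y).p_value <= 1
        assert 0 <= paired_t(x, y).p_value <= 1
        table = r.integers(0, 8, size=(2, 2))
        assert 0 <= fisher_exact_2x2(table).p_value <= 1
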