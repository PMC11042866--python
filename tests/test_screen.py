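"""Biomarker screen statistics: t-test, fold change, Pearson p, ddCt, selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sixmodel import (
    BiomarkerScreen,
    QpcrRecord,
    ddct_ratio,
    fold_change,
    pearson_with_p,
    screen_biomarkers,
    simulate_expression,
    unpaired_t_test,
)
from sixmodel.simulate import ExpressionScenario, default_scenario

IC50S = np.array([0.5, 1.2, 2.0, 3.0, 8.0, 9.0, 10.0])  # 4 sensitive, 3 resistant


class TestTTest:
    def test_identical_groups_give_p_one(self):
        assert unpaired_t_test([1, 2, 3], [1, 2, 3], flavor="student") == pytest.approx(1.0)

    def test_student_matches_textbook_pooled_formula(self):
        r, s = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        sp2 = ((len(r) - 1) * r.var(ddof=1) + (len(s) - 1) * s.var(ddof=1)) / (
            len(r) + len(s) - 2
        )
        t = (r.mean() - s.mean()) / math.sqrt(sp2 * (1 / len(r) + 1 / len(s)))
        expected = 2 * stats.t.sf(abs(t), df=len(r) + len(s) - 2)
        assert unpaired_t_test(r, s, flavor="student") == pytest.approx(expected, rel=1e-12)

    def test_welch_equals_student_for_balanced_equal_variance_groups(self):
        p_w = unpaired_t_test([1, 2, 3], [4, 5, 6], flavor="welch")
        p_s = unpaired_t_test([1, 2, 3], [4, 5, 6], flavor="student")
        assert p_w == pytest.approx(p_s, abs=1e-12)

    def test_degenerate_zero_variance(self):
        assert unpaired_t_test([2, 2, 2], [2, 2, 2]) == 1.0
        assert unpaired_t_test([2, 2, 2], [3, 3, 3]) == 0.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [1, 2, 3])


class TestFoldChange:
    def test_log2_ratio(self):
        assert fold_change(5.0, 5.0) == pytest.approx(1.0)
        assert fold_change(6.0, 5.0) == pytest.approx(2.0)
        assert fold_change(4.0, 5.0) == pytest.approx(0.5)


class TestPearson:
    @pytest.mark.parametrize(
        "r, expected_p",
        [
            (0.932858, 0.002163),   # reference biomarker correlations at n = 7
            (0.897511, 0.006108),
            (0.919897, 0.00334),
            (0.914935, 0.00387),
            (0.926089, 0.00274),
        ],
    )
    def test_p_from_r_matches_reported_values(self, r, expected_p):
        """The t-transform on 5 df reproduces the reported two-sided p-values
        of the validated biomarker genes to their printed precision."""
        from sixmodel.screen import _pearson_p_from_r

        assert _pearson_p_from_r(r, 7) == pytest.approx(expected_p, rel=0.02)

    def test_zero_correlation_gives_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 0.0])
        y = np.arange(7.0)
        y = y - y.mean()
        x = x - (x @ y) / (y @ y) * y  # force exact orthogonality
        r, p = pearson_with_p(x, np.arange(7.0))
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_sign_symmetry_and_monotonicity(self):
        from sixmodel.screen import _pearson_p_from_r

        rs = np.linspace(0.05, 0.99, 30)
        p_pos = _pearson_p_from_r(rs, 7)
        p_neg = _pearson_p_from_r(-rs, 7)
        assert np.allclose(p_pos, p_neg)
        assert np.all(np.diff(p_pos) < 0)  # strictly decreasing in |r|

    def test_zero_variance_is_undefined(self):
        r, p = pearson_with_p(np.ones(7), np.arange(7.0))
        assert math.isnan(r) and math.isnan(p)


class TestScreen:
    def _zero_noise_matrix(self):
        scenario = ExpressionScenario(
            n_genes=200, planted_sd=0.0, background_sd=0.0, seed=42
        )
        return simulate_expression(IC50S, scenario)

    def test_zero_noise_recovers_exactly_the_planted_genes(self):
        matrix, truth = self._zero_noise_matrix()
        records = screen_biomarkers(matrix)
        selected = set(records.loc[records.selected, "gene"])
        assert selected == set(truth["planted_genes"])

    def test_planted_correlation_is_perfect_without_noise(self):
        matrix, truth = self._zero_noise_matrix()
        records = screen_biomarkers(matrix).set_index("gene")
        assert np.allclose(records.loc[truth["planted_genes"], "r"], 1.0)

    def test_relaxed_thresholds_select_every_gene(self):
        scenario = ExpressionScenario(n_genes=100, seed=9)
        matrix, _ = simulate_expression(IC50S, scenario)
        records = screen_biomarkers(matrix, alpha=1.0, min_fold_change=0.0, min_r=-1.0)
        assert records.selected.all()

    def test_r_threshold_boundary(self):
        """A gene whose sample correlation is 0.79 fails the default r > 0.8
        cut even when the other criteria are relaxed away."""
        z = (IC50S - IC50S.mean()) / IC50S.std(ddof=1)
        w = np.array([1.0, -1, 1, -1, 1, -1, 0])
        w = w - (w @ z) / (z @ z) * z
        w /= w.std(ddof=1)
        w -= w.mean()
        make = lambda r: 7.0 + r * z + math.sqrt(1 - r * r) * w
        X = pd.DataFrame({"just_below": make(0.79), "just_above": make(0.81)})
        screen = BiomarkerScreen(alpha=1.0, min_fold_change=0.0, min_r=0.8).fit(
            X, IC50S
        )
        rec = screen.records_.set_index("gene")
        assert rec.loc["just_below", "r"] == pytest.approx(0.79, abs=1e-9)
        assert not rec.loc["just_below", "selected"]
        assert rec.loc["just_above", "selected"]

    def test_records_sorted_by_fold_change_then_r(self):
        matrix, _ = simulate_expression(IC50S, ExpressionScenario(n_genes=50, seed=3))
        records = screen_biomarkers(matrix)
        fc = records.fc_rs.to_numpy()
        assert np.all(fc[:-1] >= fc[1:])

    def test_planted_genes_are_upregulated_in_resistant(self):
        matrix, truth = simulate_expression(
            IC50S, ExpressionScenario(n_genes=100, seed=5)
        )
        records = screen_biomarkers(matrix).set_index("gene")
        assert (records.loc[truth["planted_genes"], "fc_rs"] > 1).all()

    def test_bh_column_is_reported_but_not_used_for_selection(self):
        matrix, truth = simulate_expression(
            IC50S, ExpressionScenario(n_genes=500, seed=8)
        )
        records = screen_biomarkers(matrix)
        assert "t_p_bh" in records.columns
        sel = records.loc[records.selected]
        assert (sel.t_p < 0.01).all() and (sel.fc_rs > 1).all() and (sel.r > 0.8).all()

    def test_selector_transform_keeps_selected_columns(self):
        matrix, truth = self._zero_noise_matrix()
        X = matrix.values.T
        screen = BiomarkerScreen().fit(X, IC50S)
        kept = screen.transform(X)
        assert kept.shape == (7, len(truth["planted_genes"]))

    def test_needs_two_samples_per_group(self):
        X = np.random.default_rng(0).normal(size=(4, 10))
        with pytest.raises(ValueError):
            BiomarkerScreen().fit(X, np.array([1.0, 2.0, 3.0, 9.0]))


class TestDdct:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((20, 15, 25, 20), 1.0),   # ddCt = 0
            ((20, 16, 25, 20), 2.0),   # ddCt = -1
            ((24, 18, 26, 18), 4.0),   # ddCt = -2
        ],
    )
    def test_analytic_identities(self, cts, expected):
        rec = QpcrRecord("g", *map(float, cts))
        assert ddct_ratio(rec) == pytest.approx(expected)

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValueError):
            QpcrRecord("g", -1.0, 18.0, 26.0, 18.0)


def test_default_scenario_sample_correlations_concentrate_near_reported_range():
    """Planted sample correlations against the true IC50 vector land around
    0.9-0.95, the regime of the reported biomarker set."""
    panel, expr = default_scenario(11)
    rs = []
    for seed in range(50):
        matrix, truth = simulate_expression(
            panel.true_ic50s(), ExpressionScenario(n_genes=30, seed=seed)
        )
        rec = screen_biomarkers(matrix).set_index("gene")
        rs.append(rec.loc[truth["planted_genes"], "r"].to_numpy())
    assert 0.88 < float(np.mean(rs)) < 0.99
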