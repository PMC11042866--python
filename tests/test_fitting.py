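"""The six-model engine: constrained fits, metrics, SE, selection, labels."""

import math

import numpy as np
import pytest

from sixmodel import (
    CANONICAL_ORDER,
    VARIANTS,
    DoseResponseTable,
    LogisticCurveFit,
    LogisticParams,
    classify_sensitivity,
    fit_six_models,
    fit_variant,
    predict_growth,
    select_best_model,
)


class TestNoiseFreeRecovery:
    @pytest.mark.parametrize("variant", CANONICAL_ORDER)
    def test_recovers_truth_under_every_constraint(self, clean_table, clean_params, variant):
        """Truth (100, 1, 2, 0) satisfies all six constraint sets, so every
        variant must recover it to 1e-6 with an implied IC50 of 2."""
        fit = fit_variant(clean_table, variant)
        assert fit.converged_
        for name in "abcd":
            assert getattr(fit.params_, name) == pytest.approx(
                getattr(clean_params, name), abs=1e-6
            )
        assert fit.metrics_.ic50 == pytest.approx(2.0, abs=1e-6)

    def test_noise_free_se_is_zero(self, clean_table):
        for variant in CANONICAL_ORDER:
            fit = fit_variant(clean_table, variant)
            assert fit.metrics_.ic50_se < 1e-6

    def test_all_six_agree_and_selection_has_an_answer(self, clean_table):
        engine = fit_six_models(clean_table)
        for m in engine.metrics_.values():
            assert m.ic50 == pytest.approx(2.0, abs=1e-6)
        assert engine.selected_variant_ in CANONICAL_ORDER
        assert engine.ic50_ == pytest.approx(2.0, abs=1e-6)


class TestFitQuality:
    def test_sse_beats_dense_grid(self, noisy_table_factory):
        """The optimizer's SSE is no worse than a brute-force grid search over
        (a, b, c, d)."""
        truth = LogisticParams(a=100, b=1.3, c=2.5, d=5.0)
        table = noisy_table_factory(truth, seed=11)
        fit = fit_variant(table, "P4")
        x, y = table.concentrations, table.growth

        grid_best = np.inf
        a_g = np.linspace(85, 115, 20)
        d_g = np.linspace(-10, 20, 20)
        b_g = np.linspace(0.3, 4.0, 20)
        c_g = np.linspace(0.2, 10.0, 20)
        for a in a_g:
            for d in d_g:
                yhat = d + (a - d) / (
                    1 + (x[None, None, :] / c_g[None, :, None]) ** b_g[:, None, None]
                )
                sse = ((yhat - y[None, None, :]) ** 2).sum(axis=-1)
                grid_best = min(grid_best, float(sse.min()))
        assert fit.rss_ <= grid_best * (1 + 1e-3)

    def test_covariance_shape_and_symmetry(self, noisy_table_factory):
        table = noisy_table_factory(LogisticParams(100, 1, 2, 0), seed=3)
        for variant in CANONICAL_ORDER:
            fit = fit_variant(table, variant)
            v = VARIANTS[variant]
            assert fit.covariance_.shape == (v.n_free, v.n_free)
            assert np.allclose(fit.covariance_, fit.covariance_.T, atol=1e-8)
            assert np.all(np.linalg.eigvalsh(fit.covariance_) > -1e-8)
            assert fit.dof_ == table.n_obs - v.n_free

    def test_more_noise_means_larger_se(self, noisy_table_factory):
        """The delta-method IC50 SE grows, in expectation, with the noise SD."""
        truth = LogisticParams(a=100, b=1.2, c=3.0, d=2.0)
        lo, hi = [], []
        for seed in range(25):
            lo.append(fit_variant(noisy_table_factory(truth, seed=seed, noise_sd=3.0),
                                  "P4").metrics_.ic50_se)
            hi.append(fit_variant(noisy_table_factory(truth, seed=seed, noise_sd=6.0),
                                  "P4").metrics_.ic50_se)
        assert np.nanmean(hi) > np.nanmean(lo)


class TestSelection:
    def test_argmin_of_the_standard_errors(self):
        entries = [
            (vid, 2.0, se, True)
            for vid, se in zip(CANONICAL_ORDER, [1.0, 2.0, 3.0, 4.0, 5.0, 0.5])
        ]
        assert select_best_model(entries) == "P4_BOTTOM0"

    def test_all_equal_ties_go_to_the_first_canonical_variant(self):
        entries = [(vid, 2.0, 1.0, True) for vid in CANONICAL_ORDER]
        assert select_best_model(entries) == "P3"

    def test_undefined_ic50_is_ineligible_even_with_smallest_se(self):
        entries = [(vid, 2.0, 1.0, True) for vid in CANONICAL_ORDER]
        entries[0] = ("P3", float("nan"), 0.01, True)
        entries[3] = ("P4", 2.0, 0.5, False)  # not converged
        assert select_best_model(entries) == "P3_TOP100"

    def test_no_eligible_entry_returns_none(self):
        entries = [(vid, float("nan"), float("nan"), True) for vid in CANONICAL_ORDER]
        assert select_best_model(entries) is None

    def test_flat_data_yields_no_estimate(self):
        x = np.repeat(np.geomspace(0.02, 20, 8), 3)
        table = DoseResponseTable("flat", x, np.full_like(x, 100.0))
        engine = fit_six_models(table)
        assert engine.selected_variant_ is None
        assert math.isnan(engine.ic50_)
        assert engine.label_ == "unclassified"

    def test_selected_ic50_matches_selected_variant(self, noisy_table_factory):
        """Selection consistency: the reported IC50 is the selected variant's,
        and it is the argmin over the per-variant delta-method SEs."""
        for seed in range(10):
            table = noisy_table_factory(LogisticParams(100, 1.4, 1.5, 3.0), seed=seed)
            engine = fit_six_models(table)
            sel = engine.selected_variant_
            assert engine.ic50_ == engine.metrics_[sel].ic50
            best = min(
                (vid for vid in CANONICAL_ORDER
                 if engine.fits_[vid].converged_
                 and math.isfinite(engine.metrics_[vid].ic50)
                 and math.isfinite(engine.metrics_[vid].ic50_se)),
                key=lambda vid: (engine.metrics_[vid].ic50_se,
                                 CANONICAL_ORDER.index(vid)),
            )
            assert sel == best

    def test_amax_identity_on_fits(self, noisy_table_factory):
        table = noisy_table_factory(LogisticParams(100, 1, 2, 0), seed=5)
        engine = fit_six_models(table)
        for vid, fit in engine.fits_.items():
            if fit.converged_:
                m = engine.metrics_[vid]
                assert m.amax == fit.params_.a - fit.params_.d


class TestClassification:
    @pytest.mark.parametrize(
        "ic50, expected",
        [(3.9, "sensitive"), (5.0, "resistant"), (4.0, "resistant"),
         (float("nan"), "unclassified")],
    )
    def test_threshold_labels(self, ic50, expected):
        assert classify_sensitivity(ic50) == expected

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValueError):
            classify_sensitivity(-1.0)


class TestValidation:
    def test_single_concentration_is_degenerate(self):
        with pytest.raises(ValueError):
            LogisticCurveFit("P4").fit([1.0, 1.0, 1.0, 1.0, 1.0], [90, 80, 70, 60, 50])

    def test_table_invariants(self):
        with pytest.raises(ValueError):  # nonpositive concentration
            DoseResponseTable("x", [0.0, 1, 2, 4], [100, 80, 50, 20])
        with pytest.raises(ValueError):  # too few distinct concentrations
            DoseResponseTable("x", [1, 1, 2, 2], [100, 80, 50, 20])
        with pytest.raises(ValueError):  # non-finite growth
            DoseResponseTable("x", [1, 2, 4, 8], [100, float("inf"), 50, 20])

    def test_growth_outside_0_100_is_allowed(self):
        t = DoseResponseTable("x", [1, 2, 4, 8], [104.0, 80.0, 50.0, -3.0])
        assert t.n_obs == 4


def test_predicted_curve_matches_params(noisy_table_factory):
    table = noisy_table_factory(LogisticParams(100, 1, 2, 0), seed=7)
    fit = fit_variant(table, "P4")
    xs = np.array([0.0, 0.5, 2.0, 10.0])
    assert np.allclose(fit.predict(xs), predict_growth(fit.params_, xs))
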