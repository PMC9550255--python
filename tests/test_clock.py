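"""Aging-clock components: scaling, metrics, training, baselines, importance."""

import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from bloodclock import (
    ClockHyperparams,
    SyntheticConfig,
    apply_scaler,
    build_features,
    compute_metrics,
    exclude_invalid,
    fit_en_baseline,
    fit_scaler,
    generate_cohort,
    grid_search,
    load_model,
    mean_age_baseline,
    permutation_importance,
    predict_age,
    save_model,
    train_clock,
)


def records(truths, preds):
    truths = np.asarray(truths, dtype=float)
    preds = np.asarray(preds, dtype=float)
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(len(truths))],
            "age_true": truths,
            "age_predicted": preds,
            "error": preds - truths,
        }
    )


class TestScaler:
    def test_min_max_definition(self):
        X = pd.DataFrame({"a": [10.0, 20.0, 30.0]})
        params = fit_scaler(X)
        np.testing.assert_allclose(apply_scaler(params, X).ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero_with_warning(self, caplog):
        X = pd.DataFrame({"a": [7.0, 7.0, 7.0], "b": [1.0, 2.0, 3.0]})
        with caplog.at_level(logging.WARNING):
            params = fit_scaler(X)
        assert np.allclose(apply_scaler(params, X)[:, 0], 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_unseen_values_extrapolate_unclipped(self):
        params = fit_scaler(pd.DataFrame({"a": [10.0, 30.0]}))
        out = apply_scaler(params, pd.DataFrame({"a": [40.0, 0.0]}))
        np.testing.assert_allclose(out.ravel(), [1.5, -0.5])

    def test_training_data_lands_in_unit_interval(self, small_cohort, schema):
        cohort, _ = small_cohort
        X, _ = build_features(cohort, schema)
        scaled = apply_scaler(fit_scaler(X), X)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0


class TestComputeMetrics:
    def test_hand_worked_example(self):
        m = compute_metrics(records([50, 60, 70], [55, 60, 65]))
        assert m.mae == pytest.approx(10 / 3, abs=1e-4)
        assert m.mape == pytest.approx(40 / 7, abs=1e-4)
        assert m.r2 == pytest.approx(0.75, abs=1e-12)
        assert m.n == 3

    def test_perfect_predictions(self):
        m = compute_metrics(records([50, 60], [50, 60]))
        assert (m.mae, m.mape, m.r2) == (0.0, 0.0, 1.0)

    def test_mean_prediction_scores_r2_zero_exactly(self):
        truths = np.array([48.0, 55.0, 63.0, 77.0, 81.0])
        m = compute_metrics(records(truths, np.full(5, truths.mean())))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_truths_reports_missing_r2(self):
        m = compute_metrics(records([60, 60], [58, 61]))
        assert m.r2 is None

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        truths = rng.uniform(45, 90, n)
        preds = truths + rng.normal(0, 5, n)
        m = compute_metrics(records(truths, preds))
        mae = sum(abs(t - p) for t, p in zip(truths, preds)) / n
        mape = 100 / n * sum(abs(t - p) / t for t, p in zip(truths, preds))
        d = sum((t - truths.mean()) ** 2 for t in truths) / n
        r2 = 1 - sum((p - t) ** 2 for t, p in zip(truths, preds)) / (n * d)
        assert m.mae == pytest.approx(mae, abs=1e-10)
        assert m.mape == pytest.approx(mape, abs=1e-10)
        assert m.r2 == pytest.approx(r2, abs=1e-10)


@pytest.fixture(scope="module")
def trained_zero_noise(schema, tiny_hp):
    """A tiny clock on a zero-noise cohort (shared across tests)."""
    cfg = SyntheticConfig(n_participants=600, seed=17).with_noise_scale(0.0)
    cohort, _ = generate_cohort(cfg, schema)
    clean, _ = exclude_invalid(cohort, schema)
    model, cv = train_clock(clean, tiny_hp, seed=31, schema=schema)
    return clean, model, cv


class TestTrainClock:
    def test_learns_age_on_zero_noise_cohort(self, trained_zero_noise):
        _, _, cv = trained_zero_noise
        assert np.abs(cv["error"]).mean() < 2.0

    def test_beats_mean_age_baseline(self, trained_zero_noise):
        clean, _, cv = trained_zero_noise
        baseline = mean_age_baseline(clean)
        baseline_mae = np.abs(
            baseline.predict(clean) - clean["chronological_age"]
        ).mean()
        assert np.abs(cv["error"]).mean() < baseline_mae

    def test_monotone_recovery_rank_correlation(self, trained_zero_noise):
        _, model, _ = trained_zero_noise
        clean = trained_zero_noise[0]
        recs = predict_age(model, clean)
        rho = spearmanr(recs["age_true"], recs["age_predicted"]).statistic
        assert rho > 0.99

    def test_cv_records_cover_all_rows_once(self, trained_zero_noise):
        clean, _, cv = trained_zero_noise
        assert sorted(cv["id"]) == sorted(clean["id"])
        assert cv["fold"].nunique() == 5

    def test_mean_age_baseline_is_constant(self, small_cohort):
        cohort, _ = small_cohort
        baseline = mean_age_baseline(cohort)
        preds = baseline.predict(cohort)
        assert np.allclose(preds, cohort["chronological_age"].mean())


class TestPredictAge:
    def test_deterministic_and_duplication_consistent(self, trained_zero_noise):
        clean, model, _ = trained_zero_noise
        once = predict_age(model, clean.head(20))
        twice = predict_age(model, clean.head(20))
        pd.testing.assert_frame_equal(once, twice)
        dup = predict_age(model, pd.concat([clean.head(1)] * 3, ignore_index=True))
        assert dup["age_predicted"].nunique() == 1

    def test_error_identity(self, trained_zero_noise):
        clean, model, _ = trained_zero_noise
        recs = predict_age(model, clean.head(50))
        np.testing.assert_allclose(
            recs["error"], recs["age_predicted"] - recs["age_true"], atol=1e-12
        )

    def test_missing_predictor_row_skipped_and_logged(self, trained_zero_noise, caplog):
        clean, model, _ = trained_zero_noise
        broken = clean.head(10).copy()
        broken.loc[broken.index[4], "glucose"] = np.nan
        with caplog.at_level(logging.WARNING):
            recs = predict_age(model, broken)
        assert len(recs) == 9
        assert broken["id"].iloc[4] not in set(recs["id"])
        assert any("missing predictors" in r.message for r in caplog.records)

    def test_model_bundle_round_trip(self, trained_zero_noise, tmp_path):
        clean, model, _ = trained_zero_noise
        save_model(model, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        a = predict_age(model, clean.head(30))
        b = predict_age(loaded, clean.head(30))
        np.testing.assert_allclose(a["age_predicted"], b["age_predicted"], atol=1e-5)


class TestGridSearch:
    def test_singleton_grid_returns_that_point(self, trained_zero_noise, tiny_hp):
        clean = trained_zero_noise[0].head(200)
        best, results = grid_search(clean, [tiny_hp], seed=3)
        assert best == tiny_hp and len(results) == 1

    def test_matches_exhaustive_oracle_and_is_deterministic(self, schema, tiny_hp):
        cfg = SyntheticConfig(n_participants=400, seed=23).with_noise_scale(0.0)
        cohort, _ = generate_cohort(cfg, schema)
        clean, _ = exclude_invalid(cohort, schema)
        grid = [
            dataclasses.replace(tiny_hp, n_hidden_layers=1, units_per_layer=8),
            dataclasses.replace(tiny_hp, n_hidden_layers=2, units_per_layer=24),
        ]
        best, results = grid_search(clean, grid, seed=5, schema=schema)
        # oracle: evaluate each grid point independently and compare
        maes = []
        for hp in grid:
            _, cv = train_clock(clean, hp, seed=5, schema=schema, refit=False)
            maes.append(np.abs(cv["error"]).mean())
        assert best == grid[int(np.argmin(maes))]
        best2, _ = grid_search(clean, grid, seed=5, schema=schema)
        assert best2 == best

    def test_empty_grid_raises(self, small_cohort):
        with pytest.raises(ValueError):
            grid_search(small_cohort[0], [], seed=0)


class TestENBaseline:
    def test_fits_linear_age_signal(self, schema):
        cfg = SyntheticConfig(n_participants=500, seed=29).with_noise_scale(0.0)
        cohort, _ = generate_cohort(cfg, schema)
        clean, _ = exclude_invalid(cohort, schema)
        en = fit_en_baseline(
            clean, alphas=(0.0, 1e-3, 1.0), l1_ratios=(0.0, 0.5), seed=3, schema=schema
        )
        X, _ = build_features(clean, schema)
        mae = np.abs(en.predict(X) - clean["chronological_age"]).mean()
        assert mae < 2.0
        assert en.alpha in (0.0, 1e-3, 1.0)
        assert en.cv_mae > 0


class TestPermutationImportance:
    def test_signal_feature_ranks_first_and_noise_is_flat(self, schema, tiny_hp):
        # all age signal in glucose; everything else is flat noise
        cfg = SyntheticConfig(n_participants=600, seed=37).with_noise_scale(0.0)
        specs = {
            name: dataclasses.replace(
                spec, slope_per_decade=0.0, quadratic_per_decade2=0.0, noise_sd=1.0
            )
            for name, spec in cfg.biomarker_specs.items()
        }
        specs["glucose"] = dataclasses.replace(
            cfg.biomarker_specs["glucose"], slope_per_decade=10.0, noise_sd=0.0
        )
        cfg = dataclasses.replace(cfg, biomarker_specs=specs)
        cohort, _ = generate_cohort(cfg, schema)
        clean, _ = exclude_invalid(cohort, schema)
        model, _ = train_clock(clean, tiny_hp, seed=41, schema=schema)
        imp = permutation_importance(model, clean, n_repeats=3, seed=43, schema=schema)
        assert imp["feature"].iloc[0] == "glucose"
        fasting = imp.set_index("feature").loc["fasting", "delta_mae"]
        assert abs(fasting) < 0.1  # the generative model ignores fasting
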