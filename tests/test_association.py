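"""Matched-cohort comparison: selection, matching, Mann-Whitney U."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bloodclock import (
    InputError,
    MatchedCohortPair,
    compare_errors,
    generate_cohort,
    healthy_pool,
    match_controls,
    select_isolated_condition,
    simulate_error_comparison,
    SyntheticConfig,
)


def meta_frame(ages, sexes=None, areas=None, prefix="x"):
    n = len(ages)
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i}" for i in range(n)],
            "chronological_age": ages,
            "sex": sexes or ["female"] * n,
            "area": areas or ["rural"] * n,
        }
    )


def error_records(frame, errors):
    return pd.DataFrame(
        {
            "id": frame["id"],
            "age_true": frame["chronological_age"],
            "error": errors,
        }
    )


class TestSelectIsolatedCondition:
    @pytest.fixture()
    def discovery(self, schema):
        rows = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                **{flag: [0, 0, 0] for flag in schema.disease_flags},
            }
        )
        rows.loc[0, "stroke"] = 1
        rows.loc[1, ["stroke", "diabetes"]] = 1
        rows.loc[2, "cancer"] = 1
        return rows

    def test_isolated_only(self, discovery, schema):
        out = select_isolated_condition(discovery, "stroke", schema)
        assert out["id"].tolist() == ["a"]  # comorbid stroke+diabetes dropped

    def test_unknown_condition_raises(self, discovery, schema):
        with pytest.raises(InputError, match="gout"):
            select_isolated_condition(discovery, "gout", schema)

    def test_empty_result_returned_with_warning(self, discovery, schema, caplog):
        out = select_isolated_condition(discovery, "hypertension", schema)
        assert out.empty
        assert any("isolated" in r.message for r in caplog.records)


class TestMatchControls:
    def test_identical_meta_gives_zero_distances(self):
        afflicted = meta_frame([60, 70], prefix="a")
        pool = meta_frame([60, 70, 80], prefix="p")
        pair = match_controls(afflicted, pool, seed=1)
        assert np.allclose(pair.match_distances, 0.0)

    def test_nearest_age_neighbours_selected(self):
        afflicted = meta_frame([60, 70], prefix="a")
        pool = meta_frame([59, 61, 72], prefix="p")
        pair = match_controls(afflicted, pool, seed=2)
        ages = pool.set_index("id")["chronological_age"]
        matched = ages.loc[pair.control_ids].tolist()
        assert matched[0] in (59, 61)  # tie region around 60
        assert matched[1] == 72

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        afflicted = meta_frame(
            rng.uniform(45, 90, 15),
            sexes=list(rng.choice(["male", "female"], 15)),
            areas=list(rng.choice(["rural", "urban"], 15)),
            prefix="a",
        )
        pool = meta_frame(
            rng.uniform(45, 90, 40),
            sexes=list(rng.choice(["male", "female"], 40)),
            areas=list(rng.choice(["rural", "urban"], 40)),
            prefix="p",
        )
        pair = match_controls(afflicted, pool, seed=3)
        # brute force: normalize over the union, minimize Euclidean distance
        def coords(df):
            return np.column_stack(
                [
                    df["chronological_age"],
                    (df["sex"] == "male").astype(float),
                    (df["area"] == "rural").astype(float),
                ]
            )

        both = np.vstack([coords(afflicted), coords(pool)])
        lo, hi = both.min(0), both.max(0)
        span = np.where(hi > lo, hi - lo, 1.0)
        an = (coords(afflicted) - lo) / span
        pn = (coords(pool) - lo) / span
        chosen = pool.set_index("id")
        for i, cid in enumerate(pair.control_ids):
            dists = np.linalg.norm(pn - an[i], axis=1)
            got = np.linalg.norm(
                (coords(chosen.loc[[cid]].reset_index()) - lo) / span - an[i]
            )
            assert got == pytest.approx(dists.min(), abs=1e-12)

    def test_replacement_forced_with_pool_of_one(self):
        afflicted = meta_frame([50, 60, 70], prefix="a")
        pool = meta_frame([55], prefix="p")
        pair = match_controls(afflicted, pool, seed=4)
        assert pair.control_ids == ["p0", "p0", "p0"]

    def test_empty_pool_raises(self):
        with pytest.raises(InputError):
            match_controls(meta_frame([50], prefix="a"), meta_frame([], prefix="p"))

    def test_covariate_balance_on_synthetic_cohort(self, schema):
        cfg = SyntheticConfig(n_participants=4000, seed=51)
        cfg.disease_prevalences = dict(cfg.disease_prevalences, stroke=0.11)
        cohort, _ = generate_cohort(cfg, schema)
        afflicted = select_isolated_condition(
            cohort[cohort["stroke"] == 1], "stroke", schema
        )
        assert len(afflicted) >= 200
        pool = healthy_pool(cohort, schema)
        pair = match_controls(afflicted, pool, seed=5)
        controls = pool.set_index("id").loc[pair.control_ids]
        assert abs(
            afflicted["chronological_age"].mean()
            - controls["chronological_age"].mean()
        ) < 1.0
        assert abs(
            (afflicted["sex"] == "male").mean() - (controls["sex"] == "male").mean()
        ) < 0.05
        assert abs(
            (afflicted["area"] == "rural").mean()
            - (controls["area"] == "rural").mean()
        ) < 0.05


def make_pair(n_x, n_y=None):
    n_y = n_y or n_x
    return MatchedCohortPair(
        condition="c",
        afflicted_ids=[f"a{i}" for i in range(n_x)],
        control_ids=[f"h{i}" for i in range(n_y)],
        meta_variables=("chronological_age", "sex", "area"),
        seed=0,
    )


def make_predictions(x_errors, y_errors):
    ids = [f"a{i}" for i in range(len(x_errors))] + [
        f"h{i}" for i in range(len(y_errors))
    ]
    errs = list(x_errors) + list(y_errors)
    return pd.DataFrame(
        {"id": ids, "age_true": 60.0, "error": errs}
    )


class TestCompareErrors:
    def test_identical_multisets_give_delta_zero_p_one(self):
        res = compare_errors(make_pair(3), make_predictions([1, 2, 3], [3, 1, 2]))
        assert res.delta == 0.0 and res.p_value == 1.0

    def test_exact_p_for_separated_samples(self):
        res = compare_errors(make_pair(3), make_predictions([1, 2, 3], [4, 5, 6]))
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_exact_p_matches_enumeration_oracle(self):
        x, y = [0.3, 1.9, 2.2, 4.1], [1.1, 2.7, 3.3]
        res = compare_errors(make_pair(4, 3), make_predictions(x, y))
        # enumerate all C(7,4) arrangements of the pooled ranks
        pooled = np.array(x + y)
        ranks = pooled.argsort().argsort() + 1
        u_obs = sum(ranks[:4]) - 4 * 5 / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(7), 4):
            u = sum(sorted(ranks)[i] for i in combo) - 4 * 5 / 2
            total += 1
            if min(u, 12 - u) <= min(u_obs, 12 - u_obs):
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_asymptotic_close_to_exact_at_n25(self):
        rng = np.random.default_rng(61)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.3, 1, 25)
        res = compare_errors(make_pair(25), make_predictions(x, y))  # asymptotic
        from scipy.stats import mannwhitneyu

        exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert res.p_value == pytest.approx(exact, abs=0.01)

    def test_missing_prediction_raises_naming_id(self):
        preds = make_predictions([1, 2, 3], [4, 5]).iloc[:-1]
        with pytest.raises(InputError, match="h1"):
            compare_errors(make_pair(3, 2), preds)

    def test_delta_identity(self):
        res = compare_errors(
            make_pair(3), make_predictions([1.0, 2.0, 6.0], [0.0, 1.0, 2.0])
        )
        assert res.delta == pytest.approx(
            res.afflicted_mean_error - res.healthy_mean_error, abs=1e-12
        )
        assert res.delta == pytest.approx(2.0, abs=1e-12)


class TestSimulatedComparisons:
    def test_shift_is_detected(self):
        res = simulate_error_comparison(
            n_afflicted=150, n_pool=600, effect_years=3.0, error_sd=1.5, seed=71
        )
        assert res.p_value < 1e-6
        assert res.delta == pytest.approx(3.0, abs=0.7)

    def test_null_is_typically_not_rejected(self):
        p_values = [
            simulate_error_comparison(
                n_afflicted=50, n_pool=300, effect_years=0.0, error_sd=2.0, seed=s
            ).p_value
            for s in range(30)
        ]
        assert np.mean(np.array(p_values) < 0.05) < 0.2
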