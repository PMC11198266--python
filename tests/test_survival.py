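"""Tests for the Cox/Kaplan-Meier survival pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pvloop import (
    code_negative_percent,
    concordance_index,
    fit_cox,
    likelihood_ratio_test,
    model_staircase,
    spearman_screen,
    tertile_km,
)
from pvloop.survival import (
    STAIRCASE_COVARIATES,
    CollinearityError,
    FitError,
    add_model_codings,
    km_curve,
)

from .oracles import cox_brute_force_mle, harrell_c_pairwise, longhand_km


def _toy_table(n=8, seed=0, beta=1.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n).astype(float)
    t = rng.exponential(1.0 / (0.5 * np.exp(beta * x)))
    # jitter to guarantee distinct times (tie-free fixtures)
    t = t + rng.uniform(0, 1e-6, size=n)
    e = rng.random(n) < 0.8
    if not e.any():
        e[0] = True
    return pd.DataFrame({"x": x, "time_years": t, "event": e})


class TestSpearmanScreen:
    def test_self_and_monotone_transform_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        table = pd.DataFrame({"x": x, "x_copy": x, "x_cube": x**3, "z": rng.normal(size=200)})
        matrix, flagged = spearman_screen(table, ["x", "x_copy", "x_cube", "z"])
        assert matrix.loc["x", "x_copy"] == pytest.approx(1.0)
        assert matrix.loc["x", "x_cube"] == pytest.approx(1.0)  # rank invariance
        assert frozenset(("x", "x_copy")) in flagged
        assert frozenset(("x", "x_cube")) in flagged
        assert frozenset(("x", "z")) not in flagged

    def test_independent_draws_uncorrelated(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"a": rng.uniform(size=1000), "b": rng.uniform(size=1000)})
        matrix, flagged = spearman_screen(table, ["a", "b"])
        assert abs(matrix.loc["a", "b"]) < 0.1
        assert not flagged

    def test_constant_column_flagged_with_warning(self):
        table = pd.DataFrame({"c": np.ones(50), "z": np.arange(50.0)})
        with pytest.warns(UserWarning):
            _, flagged = spearman_screen(table, ["c", "z"])
        assert frozenset(("c", "z")) in flagged


class TestCoding:
    def test_negative_percent(self):
        assert code_negative_percent(34.0) == -34.0
        np.testing.assert_array_equal(
            code_negative_percent(np.array([10.0, 20.0])), [-10.0, -20.0]
        )

    def test_coded_fit_flips_sign_exactly(self):
        table = _toy_table(n=60, seed=3)
        table["x_neg"] = code_negative_percent(table["x"])
        raw = fit_cox(table, ["x"])
        coded = fit_cox(table, ["x_neg"])
        assert coded.coefficients["x_neg"] == pytest.approx(
            -raw.coefficients["x"], abs=1e-6
        )


class TestCoxFit:
    @pytest.mark.parametrize("seed", [1, 2, 5, 6])
    def test_matches_brute_force_partial_likelihood(self, seed):
        table = _toy_table(n=8, seed=seed)
        res = fit_cox(table, ["x"])
        oracle = cox_brute_force_mle(
            table["x"].to_numpy(),
            table["time_years"].to_numpy(),
            table["event"].to_numpy(),
        )
        assert res.coefficients["x"] == pytest.approx(oracle, abs=1e-3)

    def test_identical_groups_give_null_coefficient(self):
        rng = np.random.default_rng(7)
        half = pd.DataFrame(
            {"time_years": rng.exponential(2.0, 100), "event": rng.random(100) < 0.7}
        )
        table = pd.concat(
            [half.assign(g=0.0), half.assign(g=1.0)], ignore_index=True
        )
        res = fit_cox(table, ["g"])
        assert res.hazard_ratios["g"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_events_rejected(self):
        table = _toy_table(n=20, seed=1)
        table["event"] = False
        with pytest.raises(FitError):
            fit_cox(table, ["x"])

    def test_missing_rows_dropped_with_reported_n(self):
        table = _toy_table(n=40, seed=2)
        table.loc[:4, "x"] = np.nan
        res = fit_cox(table, ["x"])
        assert res.n_used == 35

    def test_collinear_pair_blocked(self):
        table = _toy_table(n=40, seed=4)
        table["x2"] = table["x"] * 3.0
        _, flagged = spearman_screen(table, ["x", "x2"])
        with pytest.raises(CollinearityError):
            fit_cox(table, ["x", "x2"], flagged_pairs=flagged)

    def test_hazard_ratio_is_exp_coefficient(self):
        res = fit_cox(_toy_table(n=60, seed=6), ["x"])
        assert res.hazard_ratios["x"] == pytest.approx(
            np.exp(res.coefficients["x"]), rel=1e-12
        )
        assert (res.ci_lower <= res.hazard_ratios).all()
        assert (res.hazard_ratios <= res.ci_upper).all()


@pytest.fixture(scope="module")
def cohort():
    from pvloop import CohortConfig, build_synthetic_cohort

    return build_synthetic_cohort(CohortConfig(n_patients=164, seed=21))


class TestStaircase:
    def test_covariate_sets(self):
        assert STAIRCASE_COVARIATES["M3_V"] == [
            "age", "male", "hypertension", "diabetes", "nonischemic",
            "ef_neg_pct", "edvi",
        ]
        assert STAIRCASE_COVARIATES["M3_PV"] == [
            "age", "male", "hypertension", "diabetes", "nonischemic",
            "ve_neg_pct", "stroke_work_j",
        ]

    def test_nesting_and_shared_sample(self, cohort):
        results = model_staircase(cohort)
        assert results["M2"].log_likelihood >= results["M1"].log_likelihood
        assert results["M3_V"].log_likelihood >= results["M2"].log_likelihood
        assert results["M3_PV"].log_likelihood >= results["M2"].log_likelihood
        ns = {r.n_used for r in results.values()}
        assert len(ns) == 1

    def test_lrt_between_staircase_models(self, cohort):
        results = model_staircase(cohort)
        chi2, df, p = likelihood_ratio_test(results["M2"], results["M3_PV"])
        assert df == 2
        assert chi2 >= 0
        assert 0 <= p <= 1


class TestLikelihoodRatio:
    def test_identical_models_give_null(self):
        res = fit_cox(_toy_table(n=60, seed=8), ["x"])
        chi2, df, p = likelihood_ratio_test(res, res)
        assert chi2 == 0.0
        assert df == 0
        assert p == 1.0

    def test_non_nested_rejected(self):
        table = _toy_table(n=60, seed=9)
        table["y"] = np.random.default_rng(0).normal(size=60)
        a = fit_cox(table, ["x"])
        b = fit_cox(table, ["y"])
        with pytest.raises(ValueError):
            likelihood_ratio_test(a, b)


class TestConcordance:
    def test_perfect_ordering(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        risk = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.ones(5, dtype=bool)
        assert concordance_index(risk, t, e) == 1.0

    def test_random_score_near_half(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(1.0, 2000)
        e = rng.random(2000) < 0.7
        risk = rng.normal(size=2000)
        assert concordance_index(risk, t, e) == pytest.approx(0.5, abs=0.03)

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(1.0, 100) + rng.uniform(0, 1e-9, 100)
        e = rng.random(100) < 0.8
        risk = rng.normal(size=100)
        c = concordance_index(risk, t, e)
        assert concordance_index(-risk, t, e) == pytest.approx(1.0 - c, abs=1e-12)

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(1.0, 60)
        e = rng.random(60) < 0.7
        risk = rng.normal(size=60)
        assert concordance_index(risk, t, e) == pytest.approx(
            harrell_c_pairwise(risk, t, e), abs=1e-12
        )

    def test_true_predictor_beats_noise(self):
        from pvloop import CohortConfig, build_synthetic_cohort

        table = build_synthetic_cohort(CohortConfig(n_patients=2000, seed=30))
        lp = np.log(1.04) * (-table["ve_pct"]) + np.log(0.42) * (
            table["etiology"] == "NIDCM"
        )
        rng = np.random.default_rng(0)
        t, e = table["time_years"].to_numpy(), table["event"].to_numpy()
        c_true = concordance_index(lp.to_numpy(), t, e)
        c_noise = concordance_index(rng.normal(size=len(table)), t, e)
        assert c_true - c_noise >= 0.1


class TestKaplanMeier:
    def test_longhand_six_subject_fixture(self):
        """1 censoring among 6 subjects; survival drops match the longhand
        product-limit computation exactly."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([True, True, False, True, True, False])
        frame = km_curve(t, e)
        expected = longhand_km(t, e)
        # longhand: S(1)=5/6, S(2)=2/3, S(4)=4/9, S(5)=2/9
        assert expected == {1.0: 5 / 6, 2.0: pytest.approx(2 / 3),
                            4.0: pytest.approx(4 / 9), 5.0: pytest.approx(2 / 9)}
        for time, s in expected.items():
            assert frame.loc[time, "survival"] == pytest.approx(s, abs=1e-12)
        assert frame.loc[0.0, "survival"] == 1.0
        assert (np.diff(frame["survival"]) <= 1e-12).all()

    def test_single_event_drop(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([True, False, False, False])
        frame = km_curve(t, e)
        assert frame.loc[1.0, "survival"] == pytest.approx(3 / 4)

    def test_no_events_flat_curve(self):
        t = np.linspace(1, 5, 10)
        e = np.zeros(10, dtype=bool)
        frame = km_curve(t, e)
        assert (frame["survival"] == 1.0).all()

    def test_tertile_grouping(self):
        rng = np.random.default_rng(14)
        n = 300
        table = pd.DataFrame(
            {
                "v": rng.normal(size=n),
                "time_years": rng.exponential(2.0, n),
                "event": rng.random(n) < 0.6,
            }
        )
        curves = tertile_km(table, "v")
        assert set(curves) == {"low", "middle", "high"}
        assert sum(int(f["n_at_risk_start"].iloc[0]) for f in curves.values()) == n
        for frame in curves.values():
            assert frame["survival"].iloc[0] == 1.0
            assert (np.diff(frame["survival"]) <= 1e-12).all()
            assert (frame["ci_lower"] <= frame["survival"] + 1e-12).all()
            assert (frame["survival"] <= frame["ci_upper"] + 1e-12).all()

    def test_too_few_distinct_values_rejected(self):
        table = pd.DataFrame(
            {"v": [1.0, 1.0, 2.0], "time_years": [1, 2, 3], "event": [True, True, False]}
        )
        with pytest.raises(ValueError):
            tertile_km(table, "v")


class TestCodings:
    def test_add_model_codings(self):
        table = pd.DataFrame(
            {
                "etiology": ["ICM", "NIDCM"],
                "ef_pct": [26.0, 30.0],
                "ve_pct": [34.0, 40.0],
                "male": [True, False],
                "hypertension": [False, True],
                "diabetes": [False, False],
                "event": [True, False],
            }
        )
        coded = add_model_codings(table)
        assert list(coded["nonischemic"]) == [0.0, 1.0]
        assert list(coded["ve_neg_pct"]) == [-34.0, -40.0]
        assert list(coded["ef_neg_pct"]) == [-26.0, -30.0]
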