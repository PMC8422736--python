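"""Focal-vs-reference datasets, penalized logit fits, cross-validation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import habresp as hr
from habresp.pairwise import SerializedLogOdds


def toy_telemetry(categories):
    rows = []
    for i, cat in enumerate(categories):
        rows.append(("a1", "female", 2005, 6, i % 24, 0.0, 0.0, cat))
    return pd.DataFrame(rows, columns=["id", "sex", "year", "month", "hour", "x", "y", "category"])


def toy_availability(props):
    rows = [("a1", "female", 2005, 6, cat, p) for cat, p in props.items()]
    return pd.DataFrame(rows, columns=["id", "sex", "year", "month", "category", "proportion"])


def bernoulli_rows(n, p_fn, seed=0, x_lo=0.05, x_hi=0.95):
    """Pairwise rows with present ~ Bernoulli(p_fn(x)), one animal per 50 rows."""
    r = np.random.default_rng(seed)
    x = r.uniform(x_lo, x_hi, n)
    y = r.binomial(1, p_fn(x))
    return pd.DataFrame({
        "present": y,
        "focal_category": "focal",
        "rel_availability": x,
        "hour": r.integers(0, 24, n),
        "month": r.integers(1, 13, n),
        "sex": np.where(np.arange(n) % 2 == 0, "female", "male"),
        "id": [f"a{i // 50}" for i in range(n)],
        "year": 2005,
    })


class TestBuildPairwiseDataset:
    def test_filtering_and_present_coding(self):
        tel = toy_telemetry(["f", "f", "ref", "ref", "ref", "other"])
        av = toy_availability({"f": 0.2, "ref": 0.5, "other": 0.3})
        data, dropped = hr.build_pairwise_dataset(tel, av, "f", "ref")
        assert len(data) == 5 and dropped == 0
        assert data["present"].tolist() == [1, 1, 0, 0, 0]
        assert np.allclose(data["rel_availability"], 0.2)  # focal availability everywhere

    def test_zero_focal_availability_rows_dropped_and_counted(self):
        tel = toy_telemetry(["ref", "f"])
        av = toy_availability({"f": 0.0, "ref": 1.0})
        with pytest.raises(ValueError, match="no usable rows"):
            hr.build_pairwise_dataset(tel, av, "f", "ref")
        tel2 = toy_telemetry(["ref", "f", "ref"]).reset_index(drop=True)
        tel2.loc[0, "month"] = 7  # month with zero focal availability
        av2 = pd.concat([
            toy_availability({"f": 0.4, "ref": 0.6}),
            toy_availability({"f": 0.0, "ref": 1.0}).assign(month=7),
        ])
        data, dropped = hr.build_pairwise_dataset(tel2, av2, "f", "ref")
        assert dropped == 1 and len(data) == 2

    def test_row_counting(self):
        tel = toy_telemetry(["f"] * 4 + ["ref"] * 4 + ["o1", "o2"])
        av = toy_availability({"f": 0.3, "ref": 0.4, "o1": 0.2, "o2": 0.1})
        data, dropped = hr.build_pairwise_dataset(tel, av, "f", "ref")
        assert len(data) == 8 and dropped == 0

    def test_focal_equal_reference_rejected(self):
        tel = toy_telemetry(["f", "ref"])
        av = toy_availability({"f": 0.5, "ref": 0.5})
        with pytest.raises(ValueError):
            hr.build_pairwise_dataset(tel, av, "ref", "ref")

    def test_uncovered_animal_month_raises(self):
        tel = toy_telemetry(["f", "ref"]).assign(month=8)
        av = toy_availability({"f": 0.5, "ref": 0.5})  # covers month 6 only
        with pytest.raises(ValueError, match="cover"):
            hr.build_pairwise_dataset(tel, av, "f", "ref")


class TestFit:
    def test_agrees_with_statsmodels_glm_when_unpenalized(self):
        import statsmodels.api as sm

        data = bernoulli_rows(4000, lambda x: expit(-0.5 + 0.7 * np.log(x) + np.log(x)))
        spec = hr.ModelSpec(availability_term="parametric_log", temporal_term="none",
                            sex_main=True, random_id=False, random_year=False)
        res = hr.fit_logodds_model(data, spec)
        X = np.column_stack([
            np.ones(len(data)),
            (data["sex"] == "male").astype(float),
            np.log(data["rel_availability"]),
        ])
        glm = sm.GLM(data["present"].to_numpy(), X, family=sm.families.Binomial(),
                     offset=np.log(data["rel_availability"].to_numpy())).fit()
        assert np.allclose(res.params, glm.params, atol=1e-6)

    def test_pure_proportionality_yields_flat_deviation(self):
        # true OR proportional to availability: p = x/(x + x_ref) with
        # x_ref fixed; the smooth availability deviation should be ~ 0
        data = bernoulli_rows(5000, lambda x: x / (x + 0.4), seed=1)
        spec = hr.ModelSpec(availability_term="smooth", temporal_term="none",
                            random_id=False, random_year=False)
        res = hr.fit_logodds_model(data, spec)
        grid = np.linspace(0.06, 0.94, 50)
        f = np.array([res.predict_log_or(0, 6, "female", x) for x in grid])
        dev = f - np.log(grid)  # remove the offset null
        assert np.max(np.abs(dev - dev.mean())) <= 0.15

    def test_constant_log_or_recovered_by_parametric_spec(self):
        # constant log OR of -1 regardless of availability: the log-x
        # coefficient must cancel the offset and the intercept sit at -1
        data = bernoulli_rows(5000, lambda x: np.full_like(x, expit(-1.0)), seed=2)
        spec = hr.ModelSpec(availability_term="parametric_log", temporal_term="none",
                            random_id=False, random_year=False)
        res = hr.fit_logodds_model(data, spec)
        intercept, coef = res.params[0], res.params[1]
        assert intercept == pytest.approx(-1.0, abs=0.1)
        assert 1.0 + coef == pytest.approx(0.0, abs=0.1)  # total slope ~ 0

    def test_single_response_level_rejected(self):
        data = bernoulli_rows(200, lambda x: np.zeros_like(x))
        with pytest.raises(ValueError, match="both response levels"):
            hr.fit_logodds_model(data, hr.ModelSpec())

    def test_minimum_rows_enforced(self):
        data = bernoulli_rows(30, lambda x: np.full_like(x, 0.5))
        with pytest.raises(ValueError, match="at least 50"):
            hr.fit_logodds_model(data, hr.ModelSpec())

    def test_offset_shift_sanity(self):
        data = bernoulli_rows(500, lambda x: np.full_like(x, 0.3))
        spec = hr.ModelSpec(availability_term="offset_only", temporal_term="none",
                            random_id=False, random_year=False)
        res = hr.fit_logodds_model(data, spec)
        for c in (0.5, 2.0, 3.7):
            d = res.predict_log_or(0, 6, "female", 0.2 * c, extrapolate=True) - \
                res.predict_log_or(0, 6, "female", 0.2)
            assert d == pytest.approx(np.log(c), abs=1e-12)

    def test_null_model_prediction_is_offset_arithmetic(self):
        data = bernoulli_rows(2000, lambda x: x / (x + 0.4), seed=3)
        spec = hr.ModelSpec(availability_term="offset_only", temporal_term="none",
                            random_id=False, random_year=False)
        res = hr.fit_logodds_model(data, spec)
        intercept = res.params[0]
        for x in (0.1, 0.25, 0.5, 0.75, 0.9):
            got = np.exp(res.predict_log_or(12, 6, "female", x))
            assert got == pytest.approx(x * np.exp(intercept), rel=1e-10)

    def test_out_of_range_prediction_needs_flag(self, type2_pairwise):
        res = hr.fit_logodds_model(
            type2_pairwise, hr.ModelSpec(temporal_term="none", random_year=False)
        )
        lo = res.training_range[0]
        with pytest.raises(ValueError, match="training range"):
            res.predict_log_or(0, 6, "female", lo / 2)
        val = res.predict_log_or(0, 6, "female", lo / 2, extrapolate=True)
        assert np.isfinite(val)
        # determinism
        assert res.predict_log_or(0, 6, "female", 0.3) == res.predict_log_or(
            0, 6, "female", 0.3
        )

    def test_serialization_roundtrip_preserves_predictions(self, tmp_path, type2_pairwise):
        spec = hr.ModelSpec(availability_term="smooth", temporal_term="cyclic_hour_month",
                            sex_main=True, random_year=False)
        res = hr.fit_logodds_model(type2_pairwise, spec)
        path = tmp_path / "m.json"
        res.save(path)
        back = SerializedLogOdds.load(path)
        for h, m, s, x in [(0, 6, "female", 0.3), (12, 12, "male", 0.1), (7, 3, "male", 0.8)]:
            assert back.predict_log_or(h, m, s, x) == pytest.approx(
                res.predict_log_or(h, m, s, x), abs=1e-10
            )

    def test_random_intercept_sd_recovery(self):
        # true individual prevalence SD 0.8; estimates should land near it
        ests = []
        for seed in range(10):
            sc = hr.SimScenario(
                n_individuals=15, n_months=6, fixes_per_month=50,
                categories=("meadow", "old_mixed"), reference_category="old_mixed",
                individual_prevalence_sd=0.8, year_effect_sd=0.0, seed=100 + seed,
            )
            tel, _ = hr.generate_telemetry(sc, [hr.TruthCurve("meadow", "II", 0.3, 0.05)])
            av = hr.generate_availability_vectors(sc)
            data, _ = hr.build_pairwise_dataset(tel, av, "meadow", "old_mixed")
            res = hr.fit_logodds_model(
                data, hr.ModelSpec(temporal_term="none", random_year=False)
            )
            ests.append(res.re_sigmas["re(id)"])
        assert all(0.5 <= e <= 1.1 for e in ests)


class TestCrossValidate:
    def test_true_structure_wins_on_strong_type2_response(self):
        wins = 0
        specs = [
            hr.ModelSpec(availability_term="smooth", temporal_term="none",
                         random_id=False, random_year=False),
            hr.ModelSpec(availability_term="offset_only", temporal_term="none",
                         random_id=False, random_year=False),
        ]
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 1500
            x = r.uniform(0.02, 0.9, n)
            h = hr.eval_holling("II", 0.6, 0.05, x)  # strong saturating response
            data = pd.DataFrame({
                "present": r.binomial(1, h / (h + 0.3)),
                "focal_category": "f",
                "rel_availability": x,
                "hour": 0, "month": 6,
                "sex": "female",
                "id": [f"a{i % 15}" for i in range(n)],
                "year": 2005,
            })
            cv = hr.cross_validate(data, specs, k=10, seed=seed)
            wins += cv.chosen_index == 0
        assert wins >= 9

    def test_fold_count_capped_at_animal_count(self, type2_pairwise):
        sub = type2_pairwise[type2_pairwise["id"].isin(
            sorted(type2_pairwise["id"].unique())[:7]
        )]
        specs = [hr.ModelSpec(availability_term="offset_only", temporal_term="none",
                              random_id=False, random_year=False)]
        with pytest.warns(UserWarning, match="reducing folds"):
            cv = hr.cross_validate(sub, specs, k=10)
        assert cv.k == 7

    def test_duplicate_candidates_tie_to_first(self):
        data = bernoulli_rows(600, lambda x: np.full_like(x, 0.4), seed=5)
        spec = hr.ModelSpec(availability_term="offset_only", temporal_term="none",
                            random_id=False, random_year=False)
        cv = hr.cross_validate(data, [spec, spec], k=4)
        scores = cv.ranking["score"].to_numpy()
        assert scores[0] == pytest.approx(scores[1], abs=1e-12)
        assert cv.chosen_index == 0

    def test_chosen_score_is_minimal(self, type2_pairwise):
        specs = [
            hr.ModelSpec(availability_term=a, temporal_term="none",
                         random_id=False, random_year=False)
            for a in ("offset_only", "parametric_log", "smooth")
        ]
        cv = hr.cross_validate(type2_pairwise, specs, k=5)
        chosen_score = cv.ranking.loc[
            cv.ranking["spec_index"] == cv.chosen_index, "score"
        ].iloc[0]
        assert chosen_score <= cv.ranking["score"].min() + 1e-12

    def test_validation_errors(self):
        data = bernoulli_rows(100, lambda x: np.full_like(x, 0.5))
        with pytest.raises(ValueError):
            hr.cross_validate(data, [], k=5)
        with pytest.raises(ValueError):
            hr.cross_validate(data, [hr.ModelSpec()], k=1)


class TestModelSpec:
    def test_interaction_requires_availability_term(self):
        with pytest.raises(ValueError):
            hr.ModelSpec(availability_term="offset_only", availability_by_sex=True)

    def test_default_candidate_grid_size_and_validity(self):
        specs = hr.default_candidate_specs()
        assert len(specs) == 18
        assert len({s.label() for s in specs}) == 18
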