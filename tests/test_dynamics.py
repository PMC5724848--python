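"""Rate-of-change models: responses, OLS, AICc selection, partial R2."""

import math

import numpy as np
import pandas as pd
import pytest

from funcdyn.dynamics import (
    ClimateSeries,
    ModelSpec,
    aicc,
    backward_select,
    build_predictors,
    build_response,
    fit_ols,
    partial_r2,
    stepwise_improve,
    summarize_series,
)


def make_series(records):
    """records: list of (year, season, habitat, S, total, dFDo)."""
    rows = [
        {
            "year": y, "season": se, "habitat": h, "S": s,
            "total_captures": n, "dFDo": d, "dFDn": d, "dFDw": d,
        }
        for (y, se, h, s, n, d) in records
    ]
    return pd.DataFrame(rows)


def make_climate(years, ppt=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for y in years:
        for season in ("dry", "wet"):
            base = 150.0 if season == "dry" else 650.0
            rows.append(
                {
                    "year": y, "season": season,
                    "ppt_mm": ppt[(y, season)] if ppt else base + 50 * rng.normal(),
                    "tmean_c": 25.0 + rng.normal(),
                    "tmax_c": 32.0 + rng.normal(),
                    "tmin_c": 18.0 + rng.normal(),
                    "yr92": 0,
                }
            )
    return ClimateSeries(pd.DataFrame(rows))


class TestBuildResponse:
    def test_constant_richness_zero_change(self):
        series = make_series(
            [(2000, "dry", "up", 5, 30, 0.1), (2000, "wet", "up", 5, 30, 0.1)]
        )
        out = build_response(series, "dS")
        assert len(out) == 1
        assert out.loc[0, "y"] == 0.0

    def test_doubling_gives_log_two(self):
        series = make_series(
            [(2000, "dry", "up", 4, 30, 0.0), (2000, "wet", "up", 8, 30, 0.0)]
        )
        out = build_response(series, "dS")
        assert out.loc[0, "y"] == pytest.approx(math.log(2.0))

    def test_gap_breaks_transitions(self):
        """6 seasons with one missing: exactly 4 valid transitions remain."""
        records = [
            (2000, "dry", "up", 4, 30, 0.0),
            (2000, "wet", "up", 5, 30, 0.0),
            (2001, "dry", "up", 6, 30, 0.0),
            # 2001 wet missing (gap)
            (2002, "dry", "up", 5, 30, 0.0),
            (2002, "wet", "up", 7, 30, 0.0),
            (2003, "dry", "up", 6, 30, 0.0),
        ]
        out = build_response(make_series(records), "dS")
        got = set(zip(out["year"], out["season"]))
        assert got == {(2000, "wet"), (2001, "dry"), (2002, "wet"), (2003, "dry")}

    def test_zero_richness_flagged_missing(self):
        series = make_series(
            [(2000, "dry", "up", 0, 0, np.nan), (2000, "wet", "up", 4, 9, 0.0)]
        )
        out = build_response(series, "dS")
        assert out["y"].isna().all()

    def test_telescoping_identity(self):
        """exp(sum of dS over a gap-free run) = S_end / S_start exactly."""
        s_values = [3, 5, 4, 8, 6, 7]
        records = []
        for i, s in enumerate(s_values):
            year, season = 2000 + i // 2, ("dry", "wet")[i % 2]
            records.append((year, season, "up", s, 10, 0.0))
        out = build_response(make_series(records), "dS")
        assert math.exp(out["y"].sum()) == pytest.approx(
            s_values[-1] / s_values[0], rel=1e-12
        )

    def test_deviation_response_is_difference(self):
        series = make_series(
            [(2000, "dry", "up", 5, 30, -0.10), (2000, "wet", "up", 5, 30, -0.04)]
        )
        out = build_response(series, "dFDo")
        assert out.loc[0, "y"] == pytest.approx(0.06)


class TestBuildPredictors:
    def test_previous_season_precipitation_bookkeeping(self):
        """Wet-season PPt_1 equals the same year's dry-season PPt."""
        years = range(2000, 2005)
        ppt = {}
        for y in years:
            ppt[(y, "dry")] = 100.0 + y % 7
            ppt[(y, "wet")] = 600.0 + y % 5
        climate = make_climate(years, ppt=ppt)
        records = []
        rng = np.random.default_rng(1)
        for y in years:
            for season in ("dry", "wet"):
                records.append((y, season, "up", int(rng.integers(3, 9)), 30, 0.0))
                records.append((y, season, "low", int(rng.integers(3, 9)), 30, 0.0))
        series = make_series(records)
        spec = ModelSpec("dS", "wet", ("PPt", "PPt_1"))
        data = build_predictors(climate, series, spec)
        for rec in data.itertuples(index=False):
            assert rec.PPt == ppt[(rec.year, "wet")]
            assert rec.PPt_1 == ppt[(rec.year, "dry")]
        # and for a dry-season spec, PPt_1 is the previous year's wet season
        data = build_predictors(climate, series, ModelSpec("dS", "dry", ("PPt_1",)))
        for rec in data.itertuples(index=False):
            assert rec.PPt_1 == ppt[(rec.year - 1, "wet")]

    def test_interaction_column_is_product(self):
        years = range(2000, 2006)
        climate = make_climate(years)
        records = []
        for y in years:
            for season in ("dry", "wet"):
                for h in ("arroyo", "upland"):
                    records.append((y, season, h, 5, 30, 0.0))
        series = make_series(records)
        spec = ModelSpec("dS", "wet", ("PPt", "HAB", "HAB:PPt"))
        data = build_predictors(climate, series, spec)
        np.testing.assert_allclose(data["HAB:PPt"], data["HAB"] * data["PPt"])
        assert set(data["HAB"]) == {0.0, 1.0}  # arroyo is the reference

    def test_unknown_term_error(self):
        climate = make_climate(range(2000, 2003))
        series = make_series(
            [(y, s, "up", 5, 30, 0.0) for y in range(2000, 2003) for s in ("dry", "wet")]
        )
        with pytest.raises(KeyError):
            build_predictors(climate, series, ModelSpec("dS", "wet", ("FROST",)))


class TestAicc:
    def test_formula_oracle(self):
        # n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1) at RSS=10, n=20, k=3
        expected = 20 * math.log(10 / 20) + 2 * 3 + (2 * 3 * 4) / (20 - 3 - 1)
        assert aicc(10.0, 20, 3) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_k_at_fixed_rss(self):
        values = [aicc(10.0, 30, k) for k in range(2, 10)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_correction_vanishes_at_large_n(self):
        k = 4
        diff = aicc(100.0, 10**6, k) - (10**6 * math.log(100.0 / 10**6) + 2 * k)
        assert abs(diff) < 1e-4

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(1.0, 5, 4)


def make_ols_data(n, seed, beta=None, sigma=1.0, columns=("PPt", "Y_1", "T_MEAN", "PPt_1")):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame({c: rng.normal(size=n) for c in columns})
    beta = beta or {}
    y = rng.normal(0.0, sigma, size=n)
    for c, b in beta.items():
        y = y + b * data[c]
    data["y"] = y
    return data


class TestFitOls:
    def test_exact_linear_relation(self):
        data = make_ols_data(30, 0)
        data["y"] = 2.0 + 3.0 * data["PPt"]
        fit = fit_ols(data, ModelSpec("dS", "dry", ("PPt",)))
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.params["PPt"] == pytest.approx(3.0, abs=1e-10)
        assert fit.rss < 1e-18

    def test_normal_equations_oracle(self):
        data = make_ols_data(20, 1, beta={"PPt": 1.5, "Y_1": -0.7})
        spec = ModelSpec("dS", "dry", ("PPt", "Y_1", "T_MEAN"))
        fit = fit_ols(data, spec)
        x = np.column_stack(
            [np.ones(20), data["PPt"], data["Y_1"], data["T_MEAN"]]
        )
        beta = np.linalg.solve(x.T @ x, x.T @ data["y"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        data = make_ols_data(40, 2, beta={"PPt": 0.8})
        spec = ModelSpec("dS", "dry", ("PPt", "Y_1"))
        fit = fit_ols(data, spec)
        x = sm.add_constant(data[["PPt", "Y_1"]])
        ref = sm.OLS(data["y"], x).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse.to_numpy(), atol=1e-10)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-12)

    def test_orthogonal_response_near_zero_coefficients(self):
        data = make_ols_data(2000, 3)
        fit = fit_ols(data, ModelSpec("dS", "dry", ("PPt", "Y_1")))
        assert abs(fit.params["PPt"]) < 0.1
        assert fit.r2 < 0.02

    def test_rank_deficiency_error(self):
        data = make_ols_data(20, 4)
        data["PPt_1"] = data["PPt"] * 2.0
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_ols(data, ModelSpec("dS", "dry", ("PPt", "PPt_1")))


class TestSelection:
    def test_minimal_model_unchanged(self):
        data = make_ols_data(60, 5, beta={"PPt": 2.0})
        spec = ModelSpec("dS", "dry", ("PPt",))
        out, _ = backward_select(spec, data)
        assert out.terms == ("PPt",)

    def test_backward_retains_true_predictor(self):
        data = make_ols_data(200, 6, beta={"PPt": 1.0}, sigma=1.0)
        full = ModelSpec("dS", "dry", ("PPt", "Y_1", "T_MEAN", "PPt_1"))
        out, trace = backward_select(full, data)
        assert "PPt" in out.terms
        assert len(trace.steps) > 0

    def test_interactions_removed_before_main_effects(self):
        data = make_ols_data(100, 7, beta={"PPt": 1.0})
        data["HAB"] = np.random.default_rng(7).integers(0, 2, 100).astype(float)
        data["HAB:PPt"] = data["HAB"] * data["PPt"]
        full = ModelSpec("dS", "dry", ("PPt", "HAB", "HAB:PPt"))
        out, trace = backward_select(full, data)
        # every intermediate model honours marginality
        terms = set(full.terms)
        for step in trace.steps:
            if step["accepted"] and step["action"] == "drop":
                terms.discard(step["term"])
                if "HAB:PPt" in terms:
                    assert {"HAB", "PPt"} <= terms

    def test_stepwise_adds_withheld_true_predictor(self):
        data = make_ols_data(200, 8, beta={"PPt": 1.0, "PPt_1": 1.2})
        start = ModelSpec("dS", "dry", ("PPt",))
        out, trace = stepwise_improve(start, ["PPt", "PPt_1", "T_MEAN", "Y_1"], data)
        assert "PPt_1" in out.terms

    def test_stepwise_no_improvement_returns_input(self):
        data = make_ols_data(200, 9, beta={"PPt": 2.0})
        start = ModelSpec("dS", "dry", ("PPt",))
        out, _ = stepwise_improve(start, ["PPt"], data)
        assert out.terms == ("PPt",)

    def test_accepted_moves_strictly_decrease_aicc(self):
        data = make_ols_data(150, 10, beta={"PPt": 0.9, "Y_1": -0.5})
        full = ModelSpec("dS", "dry", ("PPt", "Y_1", "T_MEAN", "PPt_1"))
        out, trace = backward_select(full, data)
        out, trace = stepwise_improve(out, list(full.terms), data, trace)
        accepted = [s["aicc"] for s in trace.steps if s["accepted"]]
        assert all(b < a for a, b in zip(accepted, accepted[1:]))

    def test_negative_feedback_recovered_with_correct_sign(self):
        """A -0.5 coefficient on the lagged level yields a negative fit."""
        hits = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            n = 100
            y_level = np.zeros(n + 1)
            ppt = rng.normal(size=n)
            for t in range(n):
                dy = 0.1 + 0.4 * ppt[t] - 0.5 * y_level[t] + rng.normal(0, 0.5)
                y_level[t + 1] = y_level[t] + dy
            data = pd.DataFrame(
                {"y": np.diff(y_level), "PPt": ppt, "Y_1": y_level[:-1]}
            )
            fit = fit_ols(data, ModelSpec("dS", "dry", ("PPt", "Y_1")))
            hits += fit.params["Y_1"] < 0
        assert hits / reps >= 0.95


class TestPartialR2:
    def test_sole_predictor_equals_model_r2(self):
        data = make_ols_data(50, 11, beta={"PPt": 1.0})
        fit = fit_ols(data, ModelSpec("dS", "dry", ("PPt",)))
        pr2 = partial_r2(fit, data)
        assert pr2["PPt"] == pytest.approx(fit.r2, abs=1e-12)

    def test_zero_effect_orthogonal_predictor_near_zero(self):
        data = make_ols_data(3000, 12, beta={"PPt": 1.0})
        fit = fit_ols(data, ModelSpec("dS", "dry", ("PPt", "T_MEAN")))
        pr2 = partial_r2(fit, data)
        assert pr2["T_MEAN"] < 0.01

    def test_two_predictor_refit_oracle(self):
        data = make_ols_data(40, 13, beta={"PPt": 1.0, "Y_1": -0.8})
        spec = ModelSpec("dS", "dry", ("PPt", "Y_1"))
        fit = fit_ols(data, spec)
        pr2 = partial_r2(fit, data)

        def r2_of(terms):
            y = data["y"].to_numpy()
            x = np.column_stack([np.ones(len(data))] + [data[t] for t in terms])
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            resid = y - x @ beta
            return 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))

        assert pr2["PPt"] == pytest.approx(fit.r2 - r2_of(["Y_1"]), abs=1e-12)
        assert pr2["Y_1"] == pytest.approx(fit.r2 - r2_of(["PPt"]), abs=1e-12)

    def test_interactions_removed_with_their_main_effect(self):
        data = make_ols_data(80, 14, beta={"PPt": 1.0})
        data["HAB"] = np.random.default_rng(14).integers(0, 2, 80).astype(float)
        data["HAB:PPt"] = data["HAB"] * data["PPt"]
        fit = fit_ols(data, ModelSpec("dS", "dry", ("PPt", "HAB", "HAB:PPt")))
        pr2 = partial_r2(fit, data)
        # removing PPt also removes HAB:PPt, so its partial R2 reflects both
        assert set(pr2.index) == {"PPt", "HAB"}
        assert pr2["PPt"] >= 0


class TestSummarizeSeries:
    def _frame(self, values, habitat="up"):
        return pd.DataFrame(
            {
                "habitat": habitat,
                "FDo": values, "FDn": values, "FDw": values,
            }
        )

    def test_constant_series_cv_zero(self):
        out = summarize_series(self._frame([0.4] * 6), "up")
        assert out["cv_pooled"] == pytest.approx(0.0, abs=1e-12)

    def test_two_value_closed_form(self):
        # pooled {1,3} repeated: CV = 100 * sd/mean = 100*sqrt(2)/2 per pair
        out = summarize_series(self._frame([1.0, 3.0]), "up")
        expected = 100.0 * np.std([1, 3, 1, 3, 1, 3], ddof=1) / 2.0
        assert out["cv_pooled"] == pytest.approx(expected, abs=1e-9)
        assert out["cv_per_index"]["FDo"] == pytest.approx(
            100.0 * np.sqrt(2.0) / 2.0, abs=1e-9
        )

    def test_injected_variance_ratio_orders_habitats(self, rng):
        lo = 0.4 + 0.02 * rng.normal(size=30)
        hi = 0.4 + 0.2 * rng.normal(size=30)
        frame = pd.concat(
            [self._frame(lo, "arroyo"), self._frame(hi, "upland")], ignore_index=True
        )
        cv_a = summarize_series(frame, "arroyo")["cv_pooled"]
        cv_u = summarize_series(frame, "upland")["cv_pooled"]
        assert cv_u > cv_a
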