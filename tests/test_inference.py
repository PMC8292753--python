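"""Tukey comparisons, the phase-timing OLS, AICc selection, predictions."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circalux.errors import CollinearityError, InsufficientDataError
from circalux.inference import (
    adjusted_r_squared, aicc_select, default_candidates, f_from_r_squared,
    fit_phase_model, participant_season_means, predict_shift, residual_df,
    seasonal_comparison,
)


def make_rows(n_per_season, beta_night=0.0056, beta_morning=-0.0042,
              base=8.0, noise_sd=0.0, season_effects=None, seed=0):
    """Participant-season rows with a known linear mechanism."""
    rng = np.random.default_rng(seed)
    season_effects = season_effects or {}
    rows = []
    for season, n in n_per_season.items():
        for i in range(n):
            night = rng.uniform(100, 800)
            morning = rng.uniform(300, 1500)
            timing = (
                base + season_effects.get(season, 0.0)
                + beta_night * night + beta_morning * morning
                + rng.normal(0, noise_sd)
            )
            rows.append(
                {
                    "source_id": f"p{i:02d}", "season": season,
                    "mean_night_auc": night, "mean_morning_auc": morning,
                    "mean_max_timing": timing,
                }
            )
    return pd.DataFrame(rows)


class TestSeasonalComparison:
    def test_identical_groups_all_nonsignificant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 30)
        groups = {s: base for s in ("winter", "spring", "summer", "autumn")}
        out = seasonal_comparison(groups)
        assert len(out) == 6  # 4*3/2 pairs
        assert (out["p_adj"] > 0.99).all()

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(1)
        out = seasonal_comparison(
            {"a": rng.normal(0, 1, 20), "b": rng.normal(10, 1, 20)}
        )
        assert out["p_adj"].iloc[0] < 1e-6

    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1.2, 17)
        p_tukey = seasonal_comparison({"a": a, "b": b})["p_adj"].iloc[0]
        p_t = stats.ttest_ind(a, b).pvalue
        assert abs(p_tukey - p_t) < 1e-9

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            seasonal_comparison({"a": [1.0], "b": [1.0, 2.0, 3.0]})


class TestParticipantSeasonMeans:
    def _tables(self):
        exposures = pd.DataFrame(
            [
                {"source_id": "p1", "season": "winter", "day_index": d,
                 "window": w, "auc_log10lux_min": v}
                for d, v in [(0, 100.0), (1, 200.0), (2, 300.0)]
                for w in ("std_night_2100_0200", "morning_0400_1159")
            ]
        )
        phases = pd.DataFrame(
            [
                {"source_id": "p1", "season": "winter", "day_index": d,
                 "max_timing_h": t}
                for d, t in [(0, 2.0), (1, 3.0), (2, 4.0)]
            ]
        )
        return exposures, phases

    def test_simple_mean(self):
        rows = participant_season_means(*self._tables())
        assert len(rows) == 1
        assert rows["mean_max_timing"].iloc[0] == pytest.approx(3.0)
        assert rows["mean_night_auc"].iloc[0] == pytest.approx(200.0)

    def test_missing_season_absent(self):
        exposures, phases = self._tables()
        rows = participant_season_means(exposures, phases)
        assert set(rows["season"]) == {"winter"}

    def test_study_sized_cohort_yields_59_rows(self):
        rows = make_rows({"summer": 17, "autumn": 15, "winter": 15, "spring": 12})
        assert len(rows) == 59


class TestFitPhaseModel:
    def test_noiseless_recovery_to_1e8(self):
        rows = make_rows({"summer": 8, "winter": 8}, noise_sd=0.0)
        fit = fit_phase_model(rows, ("night", "morning"))
        assert fit.coef["mean_night_auc"] == pytest.approx(0.0056, abs=1e-8)
        assert fit.coef["mean_morning_auc"] == pytest.approx(-0.0042, abs=1e-8)
        assert fit.coef["const"] == pytest.approx(8.0, abs=1e-6)

    def test_full_term_structure_df(self):
        rows = make_rows(
            {"summer": 17, "autumn": 15, "winter": 15, "spring": 12}, noise_sd=1.5
        )
        fit = fit_phase_model(rows, ("night", "morning", "season"))
        assert fit.n == 59
        assert fit.residual_df == 53
        assert fit.f_df == (5, 53)
        assert len(fit.terms) == 6  # intercept + 2 slopes + 3 season dummies

    def test_arithmetic_identities_hold(self):
        rows = make_rows({"summer": 10, "winter": 9, "spring": 7}, noise_sd=1.0)
        fit = fit_phase_model(rows, ("night", "morning", "season"))
        n, p = fit.n, fit.f_df[0]
        assert fit.adj_r_squared == pytest.approx(
            adjusted_r_squared(fit.r_squared, n, p), abs=1e-12
        )
        assert fit.f_statistic == pytest.approx(
            f_from_r_squared(fit.r_squared, n, p), rel=1e-12
        )
        assert fit.residual_df == residual_df(n, p + 1)
        assert fit.adj_r_squared <= fit.r_squared

    def test_published_structure_arithmetic(self):
        # from a printed R^2 of 0.2769 with n=59 and 5 predictors
        assert adjusted_r_squared(0.2769, 59, 5) == pytest.approx(0.2087, abs=5e-5)
        assert f_from_r_squared(0.2769, 59, 5) == pytest.approx(4.06, abs=5e-3)
        assert residual_df(59, 6) == 53

    def test_collinear_design_named(self):
        rows = make_rows({"summer": 10, "winter": 10})
        rows["dup"] = rows["mean_night_auc"]
        with pytest.raises(CollinearityError, match="mean_night_auc|dup"):
            fit_phase_model(rows, ("night", "morning", "dup"))


class TestAiccSelect:
    def test_hand_computed_aicc(self):
        # n=10, simple regression (k = 3 with the error variance):
        # AICc = -2*llf + 2k + 2k(k+1)/(n-k-1)
        rng = np.random.default_rng(4)
        rows = make_rows({"winter": 10}, noise_sd=1.0)
        fit = fit_phase_model(rows, ("night",))
        n, rss, k = 10, fit.rss, 3
        llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        want = -2 * llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(want, rel=1e-12)

    def test_candidate_set_is_all_subsets(self):
        assert len(default_candidates()) == 8

    def test_ranking_sorted_with_stable_ties(self):
        rows = make_rows({"summer": 12, "winter": 12}, noise_sd=1.0)
        ranking = aicc_select(rows, [("night",), ("night",), ("morning",)])
        assert ranking["aicc"].is_monotonic_increasing
        assert ranking["delta_aicc"].iloc[0] == 0.0

    def test_junk_terms_rejected_on_pure_noise(self):
        """AICc prefers the intercept model over 5 junk predictors."""
        wins = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            rows = pd.DataFrame(
                {
                    "source_id": [f"p{i}" for i in range(30)],
                    "season": ["winter"] * 30,
                    "mean_max_timing": rng.normal(8, 1, 30),
                }
            )
            for j in range(5):
                rows[f"junk{j}"] = rng.normal(size=30)
            ranking = aicc_select(
                rows, [(), tuple(f"junk{j}" for j in range(5))]
            )
            wins += ranking.iloc[0]["model"] == "intercept-only"
        assert wins / n_rep >= 0.8

    def test_aicc_undefined_when_saturated(self):
        rows = make_rows({"winter": 7}, noise_sd=1.0)
        for j in range(4):
            rows[f"x{j}"] = np.random.default_rng(j).normal(size=7)
        with pytest.raises(InsufficientDataError):
            fit_phase_model(rows, ("night", "morning", "x0", "x1", "x2"))


class TestPredictShift:
    @pytest.fixture()
    def fit(self):
        rows = make_rows({"summer": 20, "winter": 20}, noise_sd=0.0)
        return fit_phase_model(rows, ("night", "morning"))

    def test_zero_deltas(self, fit):
        assert predict_shift(fit) == 0.0

    def test_night_reduction_shifts_one_hour_earlier(self, fit):
        # removing 3 log10lux for 60 min of night light: delta = -180
        shift = predict_shift(fit, delta_night_auc=-180.0)
        assert shift == pytest.approx(-0.0056 * 180.0, abs=1e-6)
        assert shift == pytest.approx(-1.008, abs=1e-3)

    def test_linearity(self, fit):
        one = predict_shift(fit, delta_morning_auc=50.0, delta_night_auc=-30.0)
        two = predict_shift(fit, delta_morning_auc=100.0, delta_night_auc=-60.0)
        assert two == pytest.approx(2 * one, rel=1e-12)
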