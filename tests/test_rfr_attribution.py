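import numpy as np
import pandas as pd
import pytest

import firestream as fs
from firestream.rfr_attribution import CandidateModel, _aicc_from_oob
from firestream.synthetic_data import SyntheticConfig


def fixed_model(covariates, mtry=1, ntree=200):
    """A candidate with a user-chosen structure (no enumeration)."""
    return CandidateModel(
        covariates=tuple(covariates), mtry=mtry, ntree=ntree,
        max_pairwise_r=np.nan, oob_mse=np.nan, aicc=np.nan, n_train=0, seed=0,
    )


class TestCovariateConstruction:
    def test_window_grid_filter_rule(self, null_site):
        series, _ = null_site
        cov, specs = fs.build_candidate_covariates(series, (1, 7, 30))
        kinds = {}
        for s in specs:
            kinds.setdefault(s.kind, []).append(s.window_days)
        assert sorted(kinds["rolling_sum_precip"]) == [1, 7, 30]
        assert sorted(kinds["rolling_sum_pet"]) == [1, 7, 30]
        assert kinds["rolling_mean_tair"] == [30]  # 1 and 7 fall below 30-day floor
        assert "daily_tair" in kinds and "day_of_year" in kinds
        assert len(kinds["season_total_precip"]) == 2

    def test_constant_precip_rolling_sum(self):
        idx = pd.date_range("2001-01-01", periods=400, freq="D")
        df = pd.DataFrame(
            {"twater": 1.0, "tair": 1.0, "precip": 2.0, "pet": 0.5}, index=idx
        )
        series = fs.DailySeries("c", df)
        cov, _ = fs.build_candidate_covariates(series, (30,))
        after_warmup = cov["precip_sum_30d"].iloc[29:]
        np.testing.assert_allclose(after_warmup, 60.0, rtol=1e-12)
        assert cov["precip_sum_30d"].iloc[:29].isna().all()

    def test_water_year_day_counts_from_october_first(self, null_site):
        series, _ = null_site
        cov, _ = fs.build_candidate_covariates(series, (30,))
        assert cov.loc["2002-10-01", "doy_wy"] == 1
        # water year 2002-10-01..2003-09-30 contains no Feb 29
        assert cov.loc["2003-09-30", "doy_wy"] == 365

    def test_aicc_increasing_in_oob_mse(self):
        scores = [_aicc_from_oob(m, k=3, n=600) for m in (0.05, 0.1, 0.2, 0.4)]
        assert scores == sorted(scores)


class TestCandidateEnumeration:
    def test_correlated_pair_never_cooccurs(self, null_site):
        series, windows = null_site
        cov, _ = fs.build_candidate_covariates(series, (30,))
        cov = cov.copy()
        cov["tair_shadow"] = cov["tair"] + 0.01 * np.random.default_rng(0).normal(
            size=len(cov)
        )
        names = ["tair", "tair_shadow", "precip_sum_30d"]
        cands = fs.enumerate_and_fit_candidates(
            series, cov, windows, "summer", candidate_names=names,
            ntree_grid=(50,), mtry_values=(1,), seed=1,
        )
        assert all(
            not {"tair", "tair_shadow"} <= set(c.covariates) for c in cands
        )
        assert all(c.max_pairwise_r <= 0.7 for c in cands)

    def test_pure_signal_selects_thirty_day_air_covariate(self):
        # noise-free generator: water temperature is an exact function of the
        # 30-day air mean and 7-day precipitation sum
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(
                seed=seed, water_noise_sd=0.0, water_noise_ar1=0.0, n_pre_years=4
            )
            series, windows = fs.simulate_site(cfg)
            cov, _ = fs.build_candidate_covariates(series, (7, 30))
            names = ["tair", "tair_mean_30d", "precip_sum_7d", "pet_sum_30d"]
            cands = fs.enumerate_and_fit_candidates(
                series, cov, windows, "summer", candidate_names=names,
                ntree_grid=(100,), mtry_values=(1,), max_covariates=2, seed=seed,
            )
            best = fs.select_best_model(cands)
            hits += "tair_mean_30d" in best.covariates
        assert hits >= 9

    def test_tie_breaking_prefers_parsimony(self):
        a = fixed_model(["x", "y", "z"], ntree=500)
        b = fixed_model(["x"], ntree=500)
        c = fixed_model(["x"], ntree=100)
        for m in (a, b, c):
            m.aicc = 100.0
        assert fs.select_best_model([a, b, c]) is c
        b.aicc = 99.1
        assert fs.select_best_model([a, b, c]) is b

    def test_empty_candidate_list_fatal(self):
        with pytest.raises(ValueError):
            fs.select_best_model([])


class TestPerformanceMetrics:
    def test_hand_computed_triple(self):
        perf = fs.performance_metrics([10.0, 12.0, 14.0], [11.0, 12.0, 13.0])
        assert perf.nse == pytest.approx(0.75)
        assert perf.bias == pytest.approx(0.0)
        assert perf.rmse == pytest.approx(0.8165, abs=1e-4)

    def test_perfect_and_climatology_limits(self):
        obs = [1.0, 2.0, 3.0, 4.0]
        assert fs.performance_metrics(obs, obs).nse == 1.0
        clim = fs.performance_metrics(obs, [2.5] * 4)
        assert clim.nse == pytest.approx(0.0)
        assert clim.bias == pytest.approx(0.0)

    def test_bias_sign_means_underprediction(self):
        perf = fs.performance_metrics([5.0, 5.0], [4.0, 4.0])
        assert perf.bias > 0  # observations above predictions


@pytest.fixture(scope="module")
def quiet_site():
    cfg = SyntheticConfig(seed=21, water_noise_sd=0.0, water_noise_ar1=0.0)
    series, windows = fs.simulate_site(cfg)
    cov, _ = fs.build_candidate_covariates(series, (7, 30))
    return series, windows, cov


class TestLoocvAndAttribution:
    def test_loocv_skill_high_without_noise(self, quiet_site):
        series, windows, cov = quiet_site
        model = fixed_model(["tair_mean_30d", "precip_sum_7d"])
        perf = fs.loocv_evaluate(series, cov, model, windows, "summer", seed=3)
        assert perf.n_folds == 7
        assert perf.nse > 0.5
        assert abs(perf.bias) < 0.2
        daily = fs.loocv_evaluate(series, cov, model, windows, "summer", seed=3, on="daily")
        assert daily.rmse >= 0.0 and daily.nse <= 1.0

    def test_null_attribution_near_zero_and_coherent(self, quiet_site):
        series, windows, cov = quiet_site
        model = fixed_model(["tair_mean_30d", "precip_sum_7d"])
        res = fs.attribute_change(series, cov, model, windows, "summer", seed=3)
        assert abs(res.fire_contribution["MWT"]) < 0.1
        # ADD and MWT aggregate the same daily predictions
        np.testing.assert_allclose(
            res.per_year["pred_ADD"],
            res.per_year["pred_MWT"] * res.per_year["n_days_used"],
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            res.per_year["obs_ADD"],
            res.per_year["obs_MWT"] * res.per_year["n_days_used"],
            rtol=1e-12,
        )

    def test_matched_weather_limit(self, quiet_site):
        """Prediction for a post year behaves like the pre year with similar weather."""
        series, windows, cov = quiet_site
        model = fixed_model(["tair_mean_30d", "precip_sum_7d"])
        res = fs.attribute_change(series, cov, model, windows, "summer", seed=3)
        pre_mwt = [
            float(series.window_slice(w)["twater"].mean())
            for w in windows
            if w.season == "summer" and w.fire_phase == "pre"
        ]
        lo, hi = min(pre_mwt) - 0.3, max(pre_mwt) + 0.3
        assert ((res.per_year["pred_MWT"] >= lo) & (res.per_year["pred_MWT"] <= hi)).all()

    def test_injected_effect_recovered(self):
        cfg = SyntheticConfig(seed=5, delta_summer=0.5, delta_winter=-0.3)
        series, windows = fs.simulate_site(cfg)
        cov, _ = fs.build_candidate_covariates(series, (7, 30))
        model = fixed_model(["tair_mean_30d", "precip_sum_7d"])
        summer = fs.attribute_change(series, cov, model, windows, "summer", seed=5)
        winter = fs.attribute_change(series, cov, model, windows, "winter", seed=5)
        assert summer.fire_contribution["MWT"] == pytest.approx(0.5, abs=0.2)
        assert winter.fire_contribution["MWT"] == pytest.approx(-0.3, abs=0.2)

    def test_decomposition_consistency(self, quiet_site):
        """Fire + weather contributions reconstruct the raw pre/post change
        when one post year attains both medians; otherwise the gap is bounded
        by the spread of per-year differences."""
        series, windows, cov = quiet_site
        model = fixed_model(["tair_mean_30d", "precip_sum_7d"])
        res = fs.attribute_change(series, cov, model, windows, "summer", seed=3)
        pre_mwt = [
            float(series.window_slice(w)["twater"].mean())
            for w in windows
            if w.season == "summer" and w.fire_phase == "pre"
        ]
        total = float(np.median(res.per_year["obs_MWT"])) - float(np.median(pre_mwt))
        recon = res.fire_contribution["MWT"] + res.weather_contribution["MWT"]
        diffs = (res.per_year["obs_MWT"] - res.per_year["pred_MWT"]).to_numpy()
        spread = diffs.max() - diffs.min()
        assert abs(recon - total) <= spread + 1e-9

    def test_too_few_post_years_fatal(self, quiet_site):
        series, windows, cov = quiet_site
        model = fixed_model(["tair_mean_30d", "precip_sum_7d"])
        broken = series.copy()
        for w in windows:
            if w.season == "summer" and w.fire_phase == "post" and w.season_year > 2009:
                broken.data.loc[str(w.start) : str(w.end), "twater"] = np.nan
        with pytest.raises(ValueError, match="post-fire"):
            fs.attribute_change(broken, cov, model, windows, "summer", seed=3)
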