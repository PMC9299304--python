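"""Random-forest counterfactual attribution of post-fire water-temperature change.

A random-forest regression of *daily* water temperature on weather covariates
is trained on pre-fire season days only, so its post-fire predictions are a
no-fire counterfactual. Candidate models use at most three covariates drawn
from daily air temperature, day of the water year (Oct 1 = 1), trailing
rolling means of air temperature (30–200 d), trailing rolling sums of
precipitation and PET (1–200 d), and October–March / January–June
precipitation totals; any pair correlating above |r| = 0.7 on pre-fire season
days is screened out. Candidates are ranked by an AICc computed from the
forest's out-of-bag MSE with k = n_covariates + 1, and the selected model is
validated by leave-one-year-out cross-validation on seasonal aggregates
(NSE, bias, RMSE; bias > 0 means underprediction).

The fire contribution is the median over the three post-fire years of
(observed - predicted) seasonal MWT or ADD; the weather contribution is the
median predicted post-fire index minus the median observed pre-fire index.
Standard errors start from sd of the three per-year values / sqrt(3) and,
when LOOCV results are supplied, are floored by the LOOCV seasonal RMSE —
the three post-year prediction errors share one fitted model, so their
spread alone understates the uncertainty of their median.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from firestream.timeseries_io import DailySeries, SeasonWindow

__all__ = [
    "CovariateSpec",
    "CandidateModel",
    "ModelPerformance",
    "AttributionResult",
    "DEFAULT_WINDOW_GRID",
    "build_candidate_covariates",
    "enumerate_and_fit_candidates",
    "select_best_model",
    "loocv_evaluate",
    "loocv_evaluate_indices",
    "attribute_change",
    "performance_metrics",
]

DEFAULT_WINDOW_GRID = (1, 7, 15, 30, 60, 90, 120, 150, 180, 200)
TAIR_WINDOW_RANGE = (30, 200)
PRECIP_PET_WINDOW_RANGE = (1, 200)
MAX_COVARIATES = 3
MAX_PAIRWISE_R = 0.7
DEFAULT_NTREE_GRID = (100, 250, 500)


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    kind: str
    window_days: int | None = None


@dataclass
class CandidateModel:
    covariates: tuple  # 1..3 covariate names
    mtry: int
    ntree: int
    max_pairwise_r: float
    oob_mse: float
    aicc: float
    n_train: int
    seed: int
    forest: RandomForestRegressor | None = None


@dataclass
class ModelPerformance:
    nse: float
    bias: float  # positive = underprediction
    rmse: float
    n_folds: int


@dataclass
class AttributionResult:
    season: str
    model: CandidateModel
    per_year: pd.DataFrame  # observed/predicted seasonal MWT and ADD per post year
    fire_contribution: dict  # index name -> median(observed - predicted)
    fire_se: dict
    weather_contribution: dict  # index name -> median(predicted) - median(pre observed)
    weather_se: dict
    seed: int
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for index_name in self.fire_contribution:
            rows.append(
                {
                    "season": self.season,
                    "index": index_name,
                    "fire_contribution": self.fire_contribution[index_name],
                    "fire_se": self.fire_se[index_name],
                    "weather_contribution": self.weather_contribution[index_name],
                    "weather_se": self.weather_se[index_name],
                    "covariates": "+".join(self.model.covariates),
                    "mtry": self.model.mtry,
                    "ntree": self.model.ntree,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


def _water_year_day(index: pd.DatetimeIndex) -> np.ndarray:
    """Day of the water year, counted from October 1 = 1."""
    wy_start_year = np.where(index.month >= 10, index.year, index.year - 1)
    starts = pd.to_datetime({"year": wy_start_year, "month": 10, "day": 1})
    return (index.to_numpy() - starts.to_numpy()).astype("timedelta64[D]").astype(int) + 1


def build_candidate_covariates(
    series: DailySeries, window_grid=DEFAULT_WINDOW_GRID
) -> tuple[pd.DataFrame, list[CovariateSpec]]:
    """Daily covariate table aligned to the series calendar.

    Rolling windows are trailing and end on the prediction day; days without
    a full window of history are left missing (warm-up). Seasonal
    precipitation totals (Oct–Mar, Jan–Jun) are constant within a water year.
    Windows longer than the record are dropped with a note in the spec list.
    """
    df = series.data
    index = df.index
    cov = pd.DataFrame(index=index)
    specs: list[CovariateSpec] = []

    cov["tair"] = df["tair"]
    specs.append(CovariateSpec("tair", "daily_tair"))
    cov["doy_wy"] = _water_year_day(index)
    specs.append(CovariateSpec("doy_wy", "day_of_year"))

    n = len(df)
    for w in sorted(set(window_grid)):
        if w > n:
            continue
        if TAIR_WINDOW_RANGE[0] <= w <= TAIR_WINDOW_RANGE[1]:
            name = f"tair_mean_{w}d"
            cov[name] = df["tair"].rolling(w, min_periods=w).mean()
            specs.append(CovariateSpec(name, "rolling_mean_tair", w))
        if PRECIP_PET_WINDOW_RANGE[0] <= w <= PRECIP_PET_WINDOW_RANGE[1]:
            pname = f"precip_sum_{w}d"
            cov[pname] = df["precip"].rolling(w, min_periods=w).sum()
            specs.append(CovariateSpec(pname, "rolling_sum_precip", w))
            ename = f"pet_sum_{w}d"
            cov[ename] = df["pet"].rolling(w, min_periods=w).sum()
            specs.append(CovariateSpec(ename, "rolling_sum_pet", w))

    # water-year seasonal precipitation totals, broadcast to member days
    wy = pd.Series(np.where(index.month >= 10, index.year + 1, index.year), index=index)
    precip = df["precip"]
    oct_mar = precip[index.month.isin((10, 11, 12, 1, 2, 3))].groupby(wy).sum()
    jan_jun = precip[index.month.isin((1, 2, 3, 4, 5, 6))].groupby(wy).sum()
    cov["precip_oct_mar"] = wy.map(oct_mar)
    cov["precip_jan_jun"] = wy.map(jan_jun)
    specs.append(CovariateSpec("precip_oct_mar", "season_total_precip"))
    specs.append(CovariateSpec("precip_jan_jun", "season_total_precip"))
    return cov, specs


def _season_mask(index: pd.DatetimeIndex, windows, season: str, phase: str) -> np.ndarray:
    mask = np.zeros(len(index), dtype=bool)
    for win in windows:
        if win.season == season and win.fire_phase == phase:
            mask |= (index >= pd.Timestamp(win.start)) & (index <= pd.Timestamp(win.end))
    return mask


def _aicc_from_oob(oob_mse: float, k: int, n: int) -> float:
    return n * np.log(oob_mse) + 2 * k + 2 * k * (k + 1) / max(n - k - 1, 1)


def _fit_forest(X, y, mtry, ntree, seed) -> RandomForestRegressor:
    rf = RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def enumerate_and_fit_candidates(
    series: DailySeries,
    covariates: pd.DataFrame,
    windows: list[SeasonWindow],
    season: str,
    candidate_names=None,
    ntree_grid=DEFAULT_NTREE_GRID,
    mtry_values=None,
    seed: int = 0,
    max_covariates: int = MAX_COVARIATES,
    max_pairwise_r: float = MAX_PAIRWISE_R,
) -> list[CandidateModel]:
    """Fit every screened covariate subset x hyperparameter combination.

    Training rows are pre-fire season days with complete water temperature
    and covariate values; the pairwise Pearson screen is computed on those
    days. If no subset passes the screen, the single best covariate is used
    with a note. Deterministic given ``seed``.
    """
    names = list(candidate_names) if candidate_names is not None else list(covariates.columns)
    pre = _season_mask(series.data.index, windows, season, "pre")
    y_all = series.data["twater"].to_numpy()
    frame = covariates[names].copy()
    train = pre & np.isfinite(y_all) & frame.notna().all(axis=1).to_numpy()
    if train.sum() < 30:
        raise ValueError(f"only {int(train.sum())} usable pre-fire {season} days")
    Xf = frame[train]
    y = y_all[train]
    corr = Xf.corr().abs()

    def screen(subset) -> float:
        worst = 0.0
        for a, b in itertools.combinations(subset, 2):
            r = corr.loc[a, b]
            worst = max(worst, 1.0 if np.isnan(r) else float(r))
        return worst

    subsets = []
    for size in range(1, max_covariates + 1):
        for subset in itertools.combinations(names, size):
            worst = screen(subset)
            if worst <= max_pairwise_r:
                subsets.append((subset, worst))
    if not subsets:
        subsets = [((names[0],), 0.0)]

    rng_seeds = np.random.SeedSequence(seed).spawn(len(subsets))
    out = []
    n = int(train.sum())
    for (subset, worst), child in zip(subsets, rng_seeds):
        X = Xf[list(subset)].to_numpy()
        k = len(subset) + 1
        mtries = mtry_values if mtry_values is not None else range(1, len(subset) + 1)
        for mtry in mtries:
            if mtry > len(subset):
                continue
            for ntree in ntree_grid:
                sub_seed = int(child.generate_state(1)[0] % (2**31))
                rf = _fit_forest(X, y, mtry, ntree, sub_seed)
                oob_mse = float(np.mean((y - rf.oob_prediction_) ** 2))
                out.append(
                    CandidateModel(
                        covariates=tuple(subset),
                        mtry=int(mtry),
                        ntree=int(ntree),
                        max_pairwise_r=worst,
                        oob_mse=oob_mse,
                        aicc=float(_aicc_from_oob(oob_mse, k, n)),
                        n_train=n,
                        seed=sub_seed,
                        forest=rf,
                    )
                )
    return out


def select_best_model(candidates: list[CandidateModel]) -> CandidateModel:
    """Minimum-AICc candidate; ties broken by parsimony then determinism."""
    if not candidates:
        raise ValueError("no candidate models to select from")
    return min(
        candidates,
        key=lambda c: (c.aicc, len(c.covariates), c.ntree, c.covariates),
    )


def performance_metrics(obs, pred) -> ModelPerformance:
    """NSE, bias, and RMSE of predictions against observations."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    resid = obs - pred
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    nse = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return ModelPerformance(
        nse=nse,
        bias=float(resid.mean()),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_folds=len(obs),
    )


def _seasonal_obs_pred(series, covariates, model_cov, forest, window):
    """Daily predictions inside one window, aggregated with their observations.

    Returns (obs_mwt, pred_mwt, obs_add, pred_add, n_days_used) over days
    where both the observation and the covariates are available, so the two
    aggregates are directly comparable.
    """
    sl = slice(str(window.start), str(window.end))
    obs = series.data.loc[sl, "twater"]
    X = covariates.loc[sl, list(model_cov)]
    ok = obs.notna() & X.notna().all(axis=1)
    if ok.sum() == 0:
        return (np.nan,) * 4 + (0,)
    pred = forest.predict(X[ok].to_numpy())
    o = obs[ok].to_numpy()
    return (
        float(o.mean()),
        float(pred.mean()),
        float(o.sum()),
        float(pred.sum()),
        int(ok.sum()),
    )


def loocv_evaluate(
    series: DailySeries,
    covariates: pd.DataFrame,
    model: CandidateModel,
    windows: list[SeasonWindow],
    season: str,
    seed: int = 0,
    on: str = "MWT",
) -> ModelPerformance:
    """Leave-one-year-out skill of a candidate model on seasonal aggregates.

    Each pre-fire season-year is withheld in turn; the forest is refitted on
    the remaining pre-fire season days and the held-out season's daily
    predictions are aggregated to MWT (mean) or ADD (sum) and compared with
    the observed aggregate. Metrics are computed across the held-out
    seasonal values. ``on="daily"`` evaluates on pooled daily predictions.
    """
    if on not in ("MWT", "ADD", "daily"):
        raise ValueError(f"unknown evaluation target {on!r}")
    return loocv_evaluate_indices(series, covariates, model, windows, season, seed)[on]


def loocv_evaluate_indices(
    series: DailySeries,
    covariates: pd.DataFrame,
    model: CandidateModel,
    windows: list[SeasonWindow],
    season: str,
    seed: int = 0,
) -> dict:
    """LOOCV metrics for MWT, ADD, and pooled daily predictions in one pass."""
    pre_windows = sorted(
        (w for w in windows if w.season == season and w.fire_phase == "pre"),
        key=lambda w: w.start,
    )
    if len(pre_windows) < 3:
        raise ValueError("need at least 3 pre-fire seasons for LOOCV")
    index = series.data.index
    y_all = series.data["twater"].to_numpy()
    frame = covariates[list(model.covariates)]
    usable = np.isfinite(y_all) & frame.notna().all(axis=1).to_numpy()

    pools = {"MWT": ([], []), "ADD": ([], []), "daily": ([], [])}
    children = np.random.SeedSequence(seed).spawn(len(pre_windows))
    for held, child in zip(pre_windows, children):
        train = usable & _season_mask(index, windows, season, "pre")
        held_mask = (index >= pd.Timestamp(held.start)) & (index <= pd.Timestamp(held.end))
        train &= ~held_mask
        if train.sum() < 30:
            continue
        rf = _fit_forest(
            frame[train].to_numpy(),
            y_all[train],
            model.mtry,
            model.ntree,
            int(child.generate_state(1)[0] % (2**31)),
        )
        o_mwt, p_mwt, o_add, p_add, n_used = _seasonal_obs_pred(
            series, covariates, model.covariates, rf, held
        )
        if n_used == 0:
            continue
        pools["MWT"][0].append(o_mwt); pools["MWT"][1].append(p_mwt)
        pools["ADD"][0].append(o_add); pools["ADD"][1].append(p_add)
        sl = slice(str(held.start), str(held.end))
        ok = series.data.loc[sl, "twater"].notna() & covariates.loc[
            sl, list(model.covariates)
        ].notna().all(axis=1)
        pools["daily"][0].extend(series.data.loc[sl, "twater"][ok].tolist())
        pools["daily"][1].extend(
            rf.predict(covariates.loc[sl, list(model.covariates)][ok].to_numpy()).tolist()
        )
    if len(pools["MWT"][0]) < 2:
        raise ValueError("too few usable LOOCV folds")
    return {k: performance_metrics(obs, pred) for k, (obs, pred) in pools.items()}


def attribute_change(
    series: DailySeries,
    covariates: pd.DataFrame,
    model: CandidateModel,
    windows: list[SeasonWindow],
    season: str,
    seed: int = 0,
    loocv_rmse: dict | None = None,
) -> AttributionResult:
    """Decompose the post-fire seasonal change into fire and weather parts.

    The forest is refitted on all pre-fire season days and driven with
    observed post-fire weather; fire contribution = median over post years of
    (observed - predicted), weather contribution = median predicted minus the
    median observed pre-fire index. Post years with incomplete weather are
    dropped; fewer than two usable post years is an error.

    ``loocv_rmse`` (index name -> LOOCV seasonal RMSE) floors the fire-
    contribution standard error: under no fire effect a post-year
    (observed - predicted) value is the same quantity as a LOOCV fold error,
    and because the three post years share one fitted model their errors are
    correlated, so the spread of the three values alone understates the
    uncertainty of their median; the marginal per-year error (the LOOCV
    RMSE) is a conservative upper bound for it.
    """
    index = series.data.index
    y_all = series.data["twater"].to_numpy()
    frame = covariates[list(model.covariates)]
    train = (
        _season_mask(index, windows, season, "pre")
        & np.isfinite(y_all)
        & frame.notna().all(axis=1).to_numpy()
    )
    if train.sum() < 30:
        raise ValueError(f"only {int(train.sum())} usable pre-fire {season} days")
    rf = _fit_forest(
        frame[train].to_numpy(),
        y_all[train],
        model.mtry,
        model.ntree,
        int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
    )

    pre_windows = [w for w in windows if w.season == season and w.fire_phase == "pre"]
    post_windows = sorted(
        (w for w in windows if w.season == season and w.fire_phase == "post"),
        key=lambda w: w.start,
    )
    rows = []
    for win in post_windows:
        o_mwt, p_mwt, o_add, p_add, n_used = _seasonal_obs_pred(
            series, covariates, model.covariates, rf, win
        )
        if n_used == 0:
            continue
        rows.append(
            {
                "season_year": win.season_year,
                "obs_MWT": o_mwt,
                "pred_MWT": p_mwt,
                "obs_ADD": o_add,
                "pred_ADD": p_add,
                "n_days_used": n_used,
            }
        )
    per_year = pd.DataFrame(rows)
    if len(per_year) < 2:
        raise ValueError("fewer than 2 usable post-fire years")

    pre_obs = {"MWT": [], "ADD": []}
    for win in pre_windows:
        sub = series.window_slice(win)["twater"].dropna()
        if len(sub):
            pre_obs["MWT"].append(float(sub.mean()))
            pre_obs["ADD"].append(float(sub.sum()))

    fire, fire_se, weather, weather_se = {}, {}, {}, {}
    for name in ("MWT", "ADD"):
        diff = (per_year[f"obs_{name}"] - per_year[f"pred_{name}"]).to_numpy()
        fire[name] = float(np.median(diff))
        se = float(np.std(diff, ddof=1) / np.sqrt(len(diff)))
        if loocv_rmse and name in loocv_rmse:
            se = max(se, float(loocv_rmse[name]))
        fire_se[name] = se
        pred = per_year[f"pred_{name}"].to_numpy()
        weather[name] = float(np.median(pred) - np.median(pre_obs[name]))
        weather_se[name] = float(np.std(pred, ddof=1) / np.sqrt(len(pred)))
    return AttributionResult(
        season=season,
        model=model,
        per_year=per_year,
        fire_contribution=fire,
        fire_se=fire_se,
        weather_contribution=weather,
        weather_se=weather_se,
        seed=seed,
        notes={
            "weather_contribution_definition": (
                "median(predicted post-fire index) - median(observed pre-fire index); "
                "an interpretation of the weather/fire decomposition"
            )
        },
    )
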