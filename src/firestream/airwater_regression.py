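"""Weekly air-to-water regressions with seasonal-ARIMA errors and the LRT.

Two nested regressions of the weekly water index (MWT or ADD) on weekly mean
air temperature are fitted by Gaussian maximum likelihood:

    Twater = b0 + b1*(1 - X) + b2*(1 - X)*Tair + b3*X*Tair + e

where X = 1 everywhere in the *unrestricted* model (one common line) and
X = 0 on pre-fire / 1 on post-fire weeks in the *restricted* model (separate
pre and post lines). Note the naming is the study convention and is inverted
relative to the usual statistical usage — the "restricted" model here is the
richer one, with two extra parameters (b1, b2). The error term e follows a
seasonal ARIMA (p,d,q)(P,D,Q) process with seasonal period 13, the number of
weeks per season; consecutive seasons are treated as adjacent cycles. The two
fits, sharing one SARIMA order set, are compared by a 2-df likelihood-ratio
test; residual diagnostics (Shapiro–Wilk normality, Bonferroni outlier,
non-constant-variance score test) run on the richer fit's innovations.

With all orders zero the Gaussian MLE is ordinary least squares and is
computed in closed form; nonzero orders use statsmodels' SARIMAX
(regression with SARIMA errors).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionFit",
    "RegressionComparison",
    "fit_dynamic_regression",
    "select_sarima_orders",
    "likelihood_ratio_compare",
    "residual_diagnostics",
]

SEASONAL_PERIOD = 13  # weeks per winter or summer season
LRT_DF = 2  # the restricted model adds b1 and b2
ALPHA = 0.05
ZERO_ORDERS = ((0, 0, 0), (0, 0, 0))


@dataclass
class RegressionFit:
    kind: str  # "restricted" | "unrestricted"
    response: str  # "MWT" | "ADD"
    season: str
    orders: tuple  # ((p,d,q), (P,D,Q)), seasonal period 13
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    llf: float
    k_params: int
    nobs: int
    r2: float  # on the regression mean
    r2_dynamic: float  # including one-step ARIMA error predictions
    innovations: np.ndarray
    fitted_mean: np.ndarray  # X @ beta on observed rows
    observed: np.ndarray
    row_keys: tuple  # (season_year, week_index) of observed rows
    sigma2: float
    converged: bool = True

    @property
    def coefficients(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "beta3": self.beta3,
        }


@dataclass
class RegressionComparison:
    restricted: RegressionFit
    unrestricted: RegressionFit
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    decision: str  # "reject" | "retain"
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        r, u = self.restricted, self.unrestricted
        return pd.DataFrame(
            [
                {
                    "response": r.response,
                    "season": r.season,
                    "beta_pre": r.beta2,
                    "beta_post": r.beta3,
                    "beta_common": u.beta3,
                    "R2_restricted": r.r2,
                    "R2_unrestricted": u.r2,
                    "sarima": _orders_label(r.orders),
                    "lrt_statistic": self.lrt_statistic,
                    "lrt_p": self.lrt_p,
                    "decision": self.decision,
                    "shapiro_p": self.diagnostics.get("shapiro_p", np.nan),
                    "bonferroni_outlier_p": self.diagnostics.get(
                        "bonferroni_outlier_p", np.nan
                    ),
                    "ncv_score_p": self.diagnostics.get("ncv_score_p", np.nan),
                }
            ]
        )


def _orders_label(orders) -> str:
    (p, d, q), (P, D, Q) = orders
    return f"({p},{d},{q})({P},{D},{Q})[{SEASONAL_PERIOD}]"


def _prepare(weeks: pd.DataFrame, response: str, kind: str):
    """Ordered design for one season's weekly series.

    Fire-season weeks are omitted; incomplete weeks keep their calendar slot
    with a missing response so the SARIMA error process stays on its 13-week
    lattice. Returns (y, X, pre_indicator, keys).
    """
    if response not in ("MWT", "ADD"):
        raise ValueError(f"response must be 'MWT' or 'ADD', got {response!r}")
    if kind not in ("restricted", "unrestricted"):
        raise ValueError(f"kind must be 'restricted' or 'unrestricted', got {kind!r}")
    seasons = weeks["season"].unique()
    if len(seasons) != 1:
        raise ValueError(f"weekly series must cover a single season, got {list(seasons)}")
    df = weeks[weeks["fire_phase"] != "fire_year_excluded"].sort_values(
        ["season_year", "week_index"]
    )
    if df["season_year"].nunique() < 3:
        raise ValueError("need at least 3 seasons of weekly data")
    y = df[f"week_{response}"].to_numpy(dtype=float).copy()
    y[~df["complete"].to_numpy(dtype=bool)] = np.nan
    tair = df["week_MAT"].to_numpy(dtype=float)
    tair = np.where(np.isfinite(tair), tair, np.nanmean(tair))
    pre = (df["fire_phase"] == "pre").to_numpy(dtype=float)
    if kind == "unrestricted":
        pre = np.zeros_like(pre)  # X = 1 everywhere
    X = np.column_stack([np.ones_like(tair), pre, pre * tair, (1.0 - pre) * tair])
    keys = tuple(zip(df["season_year"].to_numpy(), df["week_index"].to_numpy()))
    return y, X, pre, keys, seasons[0]


def _r2(y_obs: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum((y_obs - pred) ** 2)) / ss_tot


def fit_dynamic_regression(
    weeks: pd.DataFrame,
    response: str = "MWT",
    kind: str = "restricted",
    orders=ZERO_ORDERS,
) -> RegressionFit:
    """Maximum-likelihood fit of the weekly air–water regression.

    ``weeks`` is the table from
    :func:`firestream.seasonal_indices.compute_weekly_series`, restricted to
    one season. ``orders`` is ``((p,d,q),(P,D,Q))`` with seasonal period 13.
    """
    y, X, pre, keys, season = _prepare(weeks, response, kind)
    orders = (tuple(orders[0]), tuple(orders[1]))
    obs = np.isfinite(y)
    if obs.sum() <= SEASONAL_PERIOD:
        raise ValueError("fewer usable weeks than the seasonal period")
    cols = [0, 1, 2, 3] if kind == "restricted" else [0, 3]

    if orders == ZERO_ORDERS:
        # iid Gaussian errors: the MLE is OLS, available in closed form
        res = sm.OLS(y[obs], X[obs][:, cols]).fit()
        beta = np.zeros(4)
        beta[cols] = res.params
        fitted = X[obs][:, cols] @ res.params
        innov = y[obs] - fitted
        sigma2 = float(np.mean(innov**2))
        llf = float(res.llf)
        k = len(cols) + 1
        r2 = _r2(y[obs], fitted)
        return RegressionFit(
            kind, response, season, orders,
            *beta, llf, k, int(obs.sum()), r2, r2,
            innov, fitted, y[obs], tuple(k_ for k_, o in zip(keys, obs) if o),
            sigma2,
        )

    (p, d, q), (P, D, Q) = orders
    exog = X[:, cols]
    model = sm.tsa.SARIMAX(
        y,
        exog=exog,
        order=(p, d, q),
        seasonal_order=(P, D, Q, SEASONAL_PERIOD),
        trend="n",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=200, method="lbfgs")
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            res = model.fit(disp=0, maxiter=500, method="powell")
            converged = bool(res.mle_retvals.get("converged", True))
    beta = np.zeros(4)
    beta[cols] = np.asarray(res.params[: len(cols)])
    fitted = exog[obs] @ beta[cols]
    burn = int(getattr(res, "loglikelihood_burn", 0))
    resid = np.asarray(res.resid)
    innov = resid[np.isfinite(resid)]
    innov = innov[burn:] if burn and len(innov) > burn else innov
    y_obs = y[obs]
    r2 = _r2(y_obs, fitted)
    pred_dyn = np.asarray(res.fittedvalues)[obs]
    r2_dyn = _r2(y_obs, pred_dyn)
    return RegressionFit(
        kind, response, season, orders,
        *beta, float(res.llf), int(len(res.params)), int(obs.sum()), r2, r2_dyn,
        innov, fitted, y_obs, tuple(k_ for k_, o in zip(keys, obs) if o),
        float(res.params[-1]), converged,
    )


def _aicc(llf: float, k: int, n: int) -> float:
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / max(n - k - 1, 1)


def select_sarima_orders(
    weeks: pd.DataFrame,
    response: str = "MWT",
    p_values=(0, 1, 2),
    d_values=(0, 1),
    q_values=(0, 1, 2),
    P_values=(0, 1),
    D_values=(0,),
    Q_values=(0, 1),
) -> tuple:
    """Grid-search SARIMA orders by AICc on the unrestricted model.

    The winning order set should then be imposed on both the restricted and
    unrestricted fits so the LRT compares nested models. Candidates that fail
    to fit are skipped; if all fail, falls back to (1,0,0)(0,0,0) with a
    warning.
    """
    best, best_aicc = None, np.inf
    for p, d, q, P, D, Q in itertools.product(
        p_values, d_values, q_values, P_values, D_values, Q_values
    ):
        orders = ((p, d, q), (P, D, Q))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_dynamic_regression(weeks, response, "unrestricted", orders)
        except Exception:
            continue
        if not fit.converged or not np.isfinite(fit.llf):
            continue
        score = _aicc(fit.llf, fit.k_params, fit.nobs)
        if score < best_aicc:
            best, best_aicc = orders, score
    if best is None:
        warnings.warn("all SARIMA candidates failed; falling back to (1,0,0)(0,0,0)")
        return ((1, 0, 0), (0, 0, 0))
    return best


def residual_diagnostics(fit: RegressionFit) -> dict:
    """Shapiro–Wilk, Bonferroni outlier, and non-constant-variance score tests.

    The outlier test takes the largest externally studentized innovation and
    Bonferroni-adjusts its two-sided t tail probability; the variance score
    test regresses scaled squared innovations on the fitted regression mean
    (half the explained sum of squares is chi-square with 1 df under
    homoscedasticity).
    """
    e = np.asarray(fit.innovations, dtype=float)
    n = len(e)
    n_mean_params = 4 if fit.kind == "restricted" else 2
    if n < 8:
        return {"skipped": True, "reason": f"only {n} residuals"}
    shapiro_p = float(stats.shapiro(e).pvalue)

    dfree = n - n_mean_params - 1
    s = e.std(ddof=n_mean_params)
    r = e / s if s > 0 else np.zeros_like(e)
    denom = np.clip(n - n_mean_params - r**2, 1e-9, None)
    t_ext = r * np.sqrt(dfree / denom)
    t_max = float(np.max(np.abs(t_ext)))
    outlier_p = float(min(1.0, n * 2.0 * stats.t.sf(t_max, dfree)))

    # score test for Var(e_i) depending on the fitted mean
    fitted = np.asarray(fit.fitted_mean, dtype=float)[-n:]
    u = e**2 / np.mean(e**2)
    Z = np.column_stack([np.ones(n), fitted])
    coef, *_ = np.linalg.lstsq(Z, u, rcond=None)
    u_hat = Z @ coef
    score_stat = float(np.sum((u_hat - u.mean()) ** 2) / 2.0)
    ncv_p = float(stats.chi2.sf(score_stat, 1))

    return {
        "skipped": False,
        "shapiro_p": shapiro_p,
        "bonferroni_outlier_p": outlier_p,
        "ncv_score_p": ncv_p,
    }


def likelihood_ratio_compare(
    restricted: RegressionFit, unrestricted: RegressionFit
) -> RegressionComparison:
    """2-df LRT of the separate-lines model against the common line.

    Both fits must share data, response, and SARIMA orders. Small negative
    statistics from optimizer tolerance are clamped to zero. Residual
    diagnostics run on the restricted (richer) fit.
    """
    if restricted.kind != "restricted" or unrestricted.kind != "unrestricted":
        raise ValueError("pass fits in (restricted, unrestricted) order")
    if restricted.response != unrestricted.response:
        raise ValueError("fits compare different responses")
    if restricted.orders != unrestricted.orders:
        raise ValueError("fits must share SARIMA orders for a valid LRT")
    if restricted.row_keys != unrestricted.row_keys:
        raise ValueError("fits were estimated on different weeks")
    stat = 2.0 * (restricted.llf - unrestricted.llf)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, LRT_DF))
    return RegressionComparison(
        restricted=restricted,
        unrestricted=unrestricted,
        lrt_statistic=float(stat),
        lrt_df=LRT_DF,
        lrt_p=p,
        decision="reject" if p < ALPHA else "retain",
        diagnostics=residual_diagnostics(restricted),
    )
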