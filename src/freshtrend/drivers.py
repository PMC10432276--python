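"""Environmental-driver models for site-level trends.

Site trends (with their standard errors as known measurement error) are
regressed on standardized covariates with study and country random
intercepts. The default deterministic backend treats the covariate
coefficient vector as a random effect with a common variance estimated by
REML — an empirical-Bayes ridge that adapts its shrinkage to the data,
standing in for the regularized horseshoe prior of the fully Bayesian
formulation. An unshrunk GLS fit ("flat" backend) is available for
comparison; shrinkage can be verified by contrasting the two.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .meta import INTERVAL_LEVELS, _dummy

logger = logging.getLogger(__name__)


def dam_impact_score(
    dam_distances_km: np.ndarray | list[float],
    exponent: float = 1.0,
    cutoff_km: float | None = None,
) -> float:
    """Inverse-distance dam impact: sum_k 1 / d_k^exponent.

    More dams and closer dams raise the score; ``cutoff_km`` ignores dams
    beyond that network distance. This default functional form is a
    configurable stand-in — swap in a bespoke scoring function where a
    calibrated formulation is available.
    """
    d = np.asarray(dam_distances_km, dtype=float)
    if d.size == 0:
        return 0.0
    if (d <= 0).any():
        raise ValueError("dam distances must be positive")
    if cutoff_km is not None:
        d = d[d <= cutoff_km]
    return float(np.sum(1.0 / d**exponent))


def standardize(covariates: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Centre and scale each column to mean 0, sample SD 1 (ddof=1).

    Constant columns are rejected by name. Returns (standardized frame,
    means, SDs) so new data can be projected onto the same scale.
    """
    means = covariates.mean()
    sds = covariates.std(ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be standardized: {constant}")
    return (covariates - means) / sds, means, sds


@dataclass
class DriverFit:
    coefficients: pd.DataFrame  # per covariate: mean, se, intervals, prob_positive
    intercept: float
    intercept_se: float
    tau2_study: float
    tau2_country: float
    coef_prior_var: float  # estimated ridge variance (0 => flat backend)
    covariate_order: tuple[str, ...]
    backend: str
    medians: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]
    cov_all: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def coefficient(self, name: str) -> pd.Series:
        return self.coefficients.set_index("covariate").loc[name]


def _interval_cols(mean: float, se: float) -> dict:
    out = {}
    for lv in INTERVAL_LEVELS:
        q = stats.norm.ppf(0.5 + lv / 2) * se
        out[f"q{int(lv*100)}_lo"] = mean - q
        out[f"q{int(lv*100)}_hi"] = mean + q
    return out


def fit_driver_model(
    trends: pd.DataFrame,
    covariates: pd.DataFrame,
    backend: str = "ridge",
    weighted: bool = True,
) -> DriverFit:
    """Measurement-error mixed regression of site trends on covariates.

    ``trends``: columns site_id, slope, se, study_id, country.
    ``covariates``: indexed by site_id, already (or to be) standardized —
    columns not within 1e-9 of mean 0 / SD 1 are standardized here.

    backend "ridge": covariate coefficients b ~ N(0, s_b^2 I) with s_b^2
    estimated by REML alongside the random-intercept variances; posterior
    (BLUP) means and variances are reported. backend "flat": coefficients
    as fixed effects (no shrinkage).
    """
    if backend not in ("ridge", "flat"):
        raise ValueError(f"unknown backend '{backend}'")
    df = trends.dropna(subset=["slope", "se"]).reset_index(drop=True)
    cov = covariates.loc[df["site_id"]]
    needs_std = not (
        np.allclose(cov.mean(), 0, atol=1e-9) and np.allclose(cov.std(ddof=1), 1, atol=1e-6)
    )
    if needs_std:
        cov, _, _ = standardize(cov)
    Xc = cov.to_numpy(float)
    n, p = Xc.shape
    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        corr = np.corrcoef(Xc, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient covariate design; most collinear pair: "
            f"{cov.columns[i]} / {cov.columns[j]}"
        )

    y = df["slope"].to_numpy(float)
    d_known = df["se"].to_numpy(float) ** 2 if weighted else np.zeros(n)
    zs, n_studies = _dummy(df["study_id"])
    zc, n_countries = _dummy(df["country"])
    gs = zs @ zs.T if n_studies > 1 else None
    gc = zc @ zc.T if n_countries > 1 else None
    gb = Xc @ Xc.T
    ones = np.ones((n, 1))
    scale = max(float(np.var(y)), 1e-12)

    # variance-parameter layout: [tau_s^2, tau_c^2, sigma^2?, s_b^2?] (log)
    blocks = [b for b in (gs, gc) if b is not None]
    estimate_resid = not weighted
    ridge = backend == "ridge"

    def build_v(theta: np.ndarray) -> np.ndarray:
        k = 0
        v = np.diag(d_known.copy())
        for b in blocks:
            v = v + np.exp(theta[k]) * b
            k += 1
        if estimate_resid:
            v = v + np.exp(theta[k]) * np.eye(n)
            k += 1
        if ridge:
            v = v + np.exp(theta[k]) * gb
        return v

    n_theta = len(blocks) + int(estimate_resid) + int(ridge)

    def neg_reml(theta: np.ndarray) -> float:
        v = build_v(theta)
        try:
            L = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return 1e12
        X = ones if ridge else np.hstack([ones, Xc])
        vi_x = np.linalg.solve(v, X)
        xvx = X.T @ vi_x
        beta = np.linalg.solve(xvx, vi_x.T @ y)
        r = y - X @ beta
        vi_r = np.linalg.solve(v, r)
        logdet_v = 2.0 * float(np.log(np.diag(L)).sum())
        sign, logdet_xvx = np.linalg.slogdet(xvx)
        return 0.5 * (logdet_v + logdet_xvx + float(r @ vi_r))

    x0 = np.full(n_theta, np.log(scale / max(n_theta, 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(neg_reml, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 3000})
    theta = res.x
    v = build_v(theta)

    k = 0
    tau2_study = float(np.exp(theta[k])) if gs is not None else 0.0
    k += int(gs is not None)
    tau2_country = float(np.exp(theta[k])) if gc is not None else 0.0
    k += int(gc is not None)
    k += int(estimate_resid)
    s_b2 = float(np.exp(theta[k])) if ridge else 0.0

    if ridge:
        # GLS intercept, then BLUP of b given the marginal covariance
        vi_1 = np.linalg.solve(v, ones)
        denom = float((ones.T @ vi_1).item())
        mu = float((vi_1.T @ y).item() / denom)
        mu_se = float(np.sqrt(1.0 / denom))
        r = y - mu
        vi_r = np.linalg.solve(v, r)
        b_hat = s_b2 * (Xc.T @ vi_r)
        # posterior covariance: s^2 I - s^4 X' P X with P the projected inverse
        vi_X = np.linalg.solve(v, Xc)
        P_X = vi_X - vi_1 @ (vi_1.T @ Xc) / denom
        cov_b = s_b2 * np.eye(p) - s_b2**2 * (Xc.T @ P_X)
        intercept, intercept_se = mu, mu_se
    else:
        X = np.hstack([ones, Xc])
        vi_x = np.linalg.solve(v, X)
        xvx = X.T @ vi_x
        cov_all = np.linalg.inv(xvx)
        beta = cov_all @ (vi_x.T @ y)
        intercept, intercept_se = float(beta[0]), float(np.sqrt(cov_all[0, 0]))
        b_hat = beta[1:]
        cov_b = cov_all[1:, 1:]

    rows = []
    for i, name in enumerate(cov.columns):
        se_i = float(np.sqrt(max(cov_b[i, i], 0.0)))
        mean_i = float(b_hat[i])
        pp = float(1.0 - stats.norm.cdf(0.0, mean_i, se_i)) if se_i > 0 else float(mean_i > 0)
        rows.append({"covariate": name, "mean": mean_i, "se": se_i,
                     "prob_positive": pp, **_interval_cols(mean_i, se_i)})
    coef_df = pd.DataFrame(rows)

    return DriverFit(
        coefficients=coef_df, intercept=intercept, intercept_se=intercept_se,
        tau2_study=tau2_study, tau2_country=tau2_country, coef_prior_var=s_b2,
        covariate_order=tuple(cov.columns), backend=backend,
        medians=cov.median(), cov_all=cov_b,
    )


def marginal_predictions(
    fit: DriverFit,
    covariate: str,
    grid: np.ndarray,
    observed_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Predicted trend along one covariate, others held at their medians.

    ``grid`` is on the standardized scale. Intervals propagate the
    coefficient covariance (intercept treated as independent). Warns when
    the grid leaves the observed range.
    """
    if covariate not in fit.covariate_order:
        raise KeyError(f"unknown covariate '{covariate}'")
    grid = np.asarray(grid, float)
    if observed_range is not None and (
        grid.min() < observed_range[0] or grid.max() > observed_range[1]
    ):
        warnings.warn("prediction grid extends beyond the observed covariate range")

    base = fit.medians.copy()
    j = list(fit.covariate_order).index(covariate)
    b = fit.coefficients["mean"].to_numpy()
    rows = []
    for g in grid:
        x = base.to_numpy().copy()
        x[j] = g
        pred = fit.intercept + float(x @ b)
        var = fit.intercept_se**2 + float(x @ fit.cov_all @ x)
        se = np.sqrt(max(var, 0.0))
        rows.append({"x": g, "predicted": pred, "se": se, **_interval_cols(pred, se)})
    return pd.DataFrame(rows)
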