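"""Hierarchical meta-analysis of site-level trend estimates.

Pools site trends with crossed study and country random intercepts:

    slope_i ~ Normal(mu + u[study_i] + v[country_i], s_i^2)        (weighted)
    slope_i ~ Normal(mu + u[study_i] + v[country_i], sigma^2)      (unweighted)

Variance components are estimated by REML (profile over the random-effect
variances with a direct Cholesky solve of the marginal covariance); the
pooled mean's sampling distribution supplies the Gaussian approximation
used for 80/90/95% intervals and the probability of direction. This is
the deterministic counterpart of the Bayesian mixed model the pipeline
is designed around; with the weakly informative Normal(0, 3) intercept
prior the two coincide for any realistically sized dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

INTERVAL_LEVELS = (0.80, 0.90, 0.95)


@dataclass
class MetaResult:
    metric: str
    mean: float
    se: float
    intervals: dict[float, tuple[float, float]]
    prob_positive: float
    tau2_study: float
    tau2_country: float
    sigma2_resid: float
    n_sites: int
    n_studies: int
    n_countries: int
    weighted: bool
    coefficients: pd.DataFrame | None = field(default=None, repr=False)

    def draws(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.se, size=n)


def _dummy(codes: pd.Series) -> tuple[np.ndarray, int]:
    levels, idx = np.unique(codes.to_numpy(), return_inverse=True)
    z = np.zeros((len(codes), len(levels)))
    z[np.arange(len(codes)), idx] = 1.0
    return z, len(levels)


def _reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    zs: np.ndarray | None,
    zc: np.ndarray | None,
    d_known: np.ndarray,
    estimate_resid: bool,
) -> dict:
    """REML over (tau_s^2, tau_c^2[, sigma^2]) with known variances d_known."""
    n, p = X.shape
    scale = max(float(np.var(y)), 1e-10)

    blocks: list[np.ndarray] = []
    if zs is not None:
        blocks.append(zs @ zs.T)
    if zc is not None:
        blocks.append(zc @ zc.T)
    k_rand = len(blocks)
    k = k_rand + (1 if estimate_resid else 0)

    def build_v(theta: np.ndarray) -> np.ndarray:
        v = np.diag(d_known.copy())
        for b, th in zip(blocks, theta[:k_rand]):
            v = v + np.exp(th) * b
        if estimate_resid:
            v = v + np.exp(theta[k_rand]) * np.eye(n)
        return v

    def neg_reml(theta: np.ndarray) -> float:
        v = build_v(theta)
        try:
            L = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return 1e12
        vi_y = np.linalg.solve(v, y)
        vi_x = np.linalg.solve(v, X)
        xvx = X.T @ vi_x
        try:
            beta = np.linalg.solve(xvx, X.T @ vi_y)
        except np.linalg.LinAlgError:
            return 1e12
        r = y - X @ beta
        vi_r = np.linalg.solve(v, r)
        logdet_v = 2.0 * float(np.log(np.diag(L)).sum())
        sign, logdet_xvx = np.linalg.slogdet(xvx)
        if sign <= 0:
            return 1e12
        return 0.5 * (logdet_v + logdet_xvx + float(r @ vi_r))

    if k == 0:
        theta_hat = np.empty(0)
    else:
        x0 = np.full(k, np.log(scale / max(k, 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                neg_reml, x0, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000},
            )
        theta_hat = res.x

    v = build_v(theta_hat)
    vi_x = np.linalg.solve(v, X)
    xvx = X.T @ vi_x
    cov_beta = np.linalg.inv(xvx)
    beta = cov_beta @ (vi_x.T @ y)
    out = {
        "beta": beta,
        "cov_beta": cov_beta,
        "tau2": [float(np.exp(t)) for t in theta_hat[:k_rand]],
        "sigma2": float(np.exp(theta_hat[k_rand])) if estimate_resid else 0.0,
        "V": v,
    }
    return out


def _summaries(mean: float, se: float) -> tuple[dict, float]:
    intervals = {
        lv: (mean + stats.norm.ppf(0.5 - lv / 2) * se, mean + stats.norm.ppf(0.5 + lv / 2) * se)
        for lv in INTERVAL_LEVELS
    }
    prob_pos = float(1.0 - stats.norm.cdf(0.0, loc=mean, scale=se)) if se > 0 else float(mean > 0)
    return intervals, prob_pos


def fit_meta(
    trends: pd.DataFrame,
    weighted: bool = True,
    metric: str = "",
    fixed: np.ndarray | None = None,
    coef_names: Sequence[str] | None = None,
) -> MetaResult:
    """Pool site trends into an overall mean with study/country random effects.

    ``trends`` needs columns ``slope``, ``study_id``, ``country`` and
    (when ``weighted``) ``se``. ``fixed`` optionally replaces the
    intercept-only design matrix (used by the fixed-factor sensitivity
    analysis); the first reported coefficient is then the first column.
    """
    df = trends.dropna(subset=["slope"]).reset_index(drop=True)
    y = df["slope"].to_numpy(float)
    n = len(df)
    if n < 2:
        raise ValueError("meta-analysis needs at least 2 site trends")

    if weighted:
        if "se" not in df.columns or df["se"].isna().any():
            raise ValueError("weighted meta-analysis requires a finite se per site")
        d_known = df["se"].to_numpy(float) ** 2
        estimate_resid = False
    else:
        d_known = np.zeros(n)
        estimate_resid = True

    zs, n_studies = _dummy(df["study_id"])
    zc, n_countries = _dummy(df["country"])
    if n_studies < 2:
        warnings.warn("single study: study variance dropped (fixed-effect degradation)")
        zs = None
    if n_countries < 2:
        zc = None

    X = fixed if fixed is not None else np.ones((n, 1))
    fit = _reml_fit(y, X, zs, zc, d_known, estimate_resid)

    tau2 = list(fit["tau2"])
    tau2_study = tau2.pop(0) if zs is not None else 0.0
    tau2_country = tau2.pop(0) if zc is not None else 0.0

    mean = float(fit["beta"][0])
    se = float(np.sqrt(max(fit["cov_beta"][0, 0], 0.0)))
    intervals, prob_pos = _summaries(mean, se)

    coef_df = None
    if fixed is not None:
        names = list(coef_names) if coef_names else [f"b{i}" for i in range(X.shape[1])]
        rows = []
        for i, nm in enumerate(names):
            b = float(fit["beta"][i])
            s = float(np.sqrt(max(fit["cov_beta"][i, i], 0.0)))
            iv, pp = _summaries(b, s)
            rows.append({"coef": nm, "mean": b, "se": s, "prob_positive": pp,
                         **{f"q{int(lv*100)}_lo": iv[lv][0] for lv in INTERVAL_LEVELS},
                         **{f"q{int(lv*100)}_hi": iv[lv][1] for lv in INTERVAL_LEVELS}})
        coef_df = pd.DataFrame(rows)

    return MetaResult(
        metric=metric, mean=mean, se=se, intervals=intervals, prob_positive=prob_pos,
        tau2_study=tau2_study, tau2_country=tau2_country, sigma2_resid=fit["sigma2"],
        n_sites=n, n_studies=n_studies, n_countries=n_countries, weighted=weighted,
        coefficients=coef_df,
    )


def probability_of_direction(posterior: tuple[float, float] | np.ndarray) -> float:
    """Posterior mass above zero, from a (mean, sd) pair or draw array."""
    if isinstance(posterior, tuple):
        mean, sd = posterior
        if sd <= 0:
            return float(mean > 0)
        return float(1.0 - stats.norm.cdf(0.0, loc=mean, scale=sd))
    draws = np.asarray(posterior, float)
    return float((draws > 0).mean())


def jackknife_by_country(
    trends: pd.DataFrame, weighted: bool = True, metric: str = ""
) -> dict[str, MetaResult]:
    """Refit the meta-analysis leaving out one country at a time."""
    countries = sorted(trends["country"].unique())
    if len(countries) < 3:
        raise ValueError("country jackknife needs at least 3 countries")
    out: dict[str, MetaResult] = {}
    for c in countries:
        sub = trends[trends["country"] != c]
        out[c] = fit_meta(sub, weighted=weighted, metric=metric)
    return out


def sensitivity_fixed_factor(
    trends: pd.DataFrame,
    factor: str,
    weighted: bool = True,
    metric: str = "",
    min_sites_per_level: int = 2,
) -> pd.DataFrame:
    """Meta-analysis with a categorical fixed factor (cell-means coding).

    Returns one row per retained factor level with the level's mean trend,
    se, intervals and probability of direction. Levels with fewer than
    ``min_sites_per_level`` sites are dropped (and logged).
    """
    df = trends.dropna(subset=["slope", factor]).copy()
    counts = df[factor].value_counts()
    keep = counts.index[counts >= min_sites_per_level]
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("factor '%s': dropping underpopulated level(s) %s", factor, dropped)
    df = df[df[factor].isin(keep)].reset_index(drop=True)
    levels = sorted(df[factor].unique())
    X = np.column_stack([(df[factor] == lv).to_numpy(float) for lv in levels])
    res = fit_meta(df, weighted=weighted, metric=metric, fixed=X, coef_names=levels)
    assert res.coefficients is not None
    return res.coefficients.rename(columns={"coef": factor})
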