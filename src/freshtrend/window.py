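"""Moving-window trend trajectories.

Ten-year windows slide over the study period; within each window every
site with at least 6 sampling years inside the window is refit with the
same AR(1) trend estimator on the within-window data only, and the site
trends are pooled with the hierarchical meta-analysis. Windows qualify
only when they hold at least ``min_sites`` eligible sites from at least
``min_countries`` countries. A window is labelled by its 5th year
(1990-1999 -> 1994); start-year labelling is available via ``label=``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .meta import INTERVAL_LEVELS, MetaResult, fit_meta
from .trends import DEFAULT_LEDGER, fit_site_trend

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    start_year: int
    end_year: int  # start + width - 1
    label_year: int
    eligible_sites: tuple[str, ...]
    eligible_countries: tuple[str, ...]

    @property
    def n_sites(self) -> int:
        return len(self.eligible_sites)

    @property
    def n_segments(self) -> int:
        return len(self.eligible_sites)


def build_windows(
    site_years: pd.DataFrame,
    width: int = 10,
    min_years: int = 6,
    min_sites: int = 250,
    min_countries: int = 8,
    first_start: int | None = None,
    last_start: int | None = None,
    label: str = "centre",
) -> list[WindowSpec]:
    """Enumerate qualifying windows.

    ``site_years`` has one row per sampled site-year with columns
    ``site_id, country, year``. Eligibility is recomputed per window; the
    total segment count is the sum of eligible sites over windows.
    """
    df = site_years[["site_id", "country", "year"]].drop_duplicates()
    years = df["year"]
    lo = int(years.min()) if first_start is None else first_start
    hi = int(years.max()) - width + 1 if last_start is None else last_start

    out: list[WindowSpec] = []
    for start in range(lo, hi + 1):
        end = start + width - 1
        inside = df[(years >= start) & (years <= end)]
        per_site = inside.groupby("site_id").agg(
            n=("year", "nunique"), country=("country", "first")
        )
        eligible = per_site[per_site["n"] >= min_years]
        countries = sorted(eligible["country"].unique())
        if len(eligible) >= min_sites and len(countries) >= min_countries:
            label_year = start + (width // 2 - 1) if label == "centre" else start
            out.append(WindowSpec(
                start_year=start, end_year=end, label_year=label_year,
                eligible_sites=tuple(sorted(eligible.index)),
                eligible_countries=tuple(countries),
            ))
    logger.info("%d qualifying windows, %d total segments",
                len(out), sum(w.n_segments for w in out))
    return out


def window_site_trends(
    window: WindowSpec,
    metrics_df: pd.DataFrame,
    metric: str,
    meta_lookup: pd.DataFrame,
    ledger=DEFAULT_LEDGER,
    min_years: int = 6,
    reml: bool = True,
) -> pd.DataFrame:
    """Refit site trends on within-window data for one metric.

    ``metrics_df`` is the tidy per-site metric frame; ``meta_lookup``
    maps site_id -> study_id, country. Returns the trend frame ready for
    :func:`freshtrend.meta.fit_meta`.
    """
    sub = metrics_df[
        (metrics_df["metric"] == metric)
        & metrics_df["site_id"].isin(window.eligible_sites)
        & metrics_df["year"].between(window.start_year, window.end_year)
    ]
    rows = []
    for site, g in sub.groupby("site_id"):
        est = fit_site_trend(g, metric=metric, site_id=str(site), ledger=ledger,
                             min_years=min_years, reml=reml)
        if est is None or not np.isfinite(est.se) or est.se <= 0:
            continue
        rows.append({"site_id": site, "slope": est.slope, "se": est.se,
                     "rho": est.rho, "n_years": est.n_years})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.merge(meta_lookup[["site_id", "study_id", "country"]], on="site_id")


def window_meta(
    window: WindowSpec,
    metrics_df: pd.DataFrame,
    metric: str,
    meta_lookup: pd.DataFrame,
    weighted: bool = True,
    **kwargs,
) -> tuple[MetaResult, pd.DataFrame]:
    """Within-window site trends pooled into one MetaResult."""
    trends = window_site_trends(window, metrics_df, metric, meta_lookup, **kwargs)
    if len(trends) < 2:
        raise ValueError(f"window {window.start_year}-{window.end_year}: too few site trends")
    return fit_meta(trends, weighted=weighted, metric=metric), trends


def proportion_positive(
    trends: pd.DataFrame,
    n_draws: int = 4000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Study-weighted proportion of sites with positive trends.

    Sites are weighted by the inverse of their study's site count so large
    studies do not dominate. Per posterior draw the indicator of a
    positive slope draw is averaged with these weights; intervals come
    from the draw distribution. Site posteriors are the Gaussian
    approximations N(slope, se).
    """
    rng = rng or np.random.default_rng()
    df = trends.reset_index(drop=True)
    study_sizes = df.groupby("study_id")["site_id"].transform("count")
    w = (1.0 / study_sizes).to_numpy()
    w = w / w.sum()
    draws = rng.normal(
        df["slope"].to_numpy()[:, None], df["se"].to_numpy()[:, None], size=(len(df), n_draws)
    )
    prop = (w[:, None] * (draws > 0)).sum(axis=0)
    out = {
        "proportion": float(prop.mean()),
        "intervals": {
            lv: (float(np.quantile(prop, 0.5 - lv / 2)), float(np.quantile(prop, 0.5 + lv / 2)))
            for lv in INTERVAL_LEVELS
        },
    }
    return out


def proportion_positive_exact(trends: pd.DataFrame) -> float:
    """Analytic mean of the weighted proportion (independent Gaussians)."""
    df = trends.reset_index(drop=True)
    study_sizes = df.groupby("study_id")["site_id"].transform("count")
    w = (1.0 / study_sizes).to_numpy()
    w = w / w.sum()
    p_pos = 1.0 - stats.norm.cdf(0.0, df["slope"].to_numpy(), df["se"].to_numpy())
    return float((w * p_pos).sum())


def trajectory_change(window_results: pd.DataFrame) -> dict:
    """Measurement-error regression of window mean trends on label year.

    ``window_results`` has columns ``label_year, mean, se``. The model is
    mean_w ~ Normal(a + b * year_w, se_w^2 + sigma^2) with sigma^2
    estimated by ML; returns the slope b with Gaussian 80/90/95%
    intervals. Needs at least 3 windows.
    """
    df = window_results.dropna(subset=["mean", "se"])
    if len(df) < 3:
        raise ValueError("trajectory change needs at least 3 windows")
    x = df["label_year"].to_numpy(float)
    y = df["mean"].to_numpy(float)
    s2 = df["se"].to_numpy(float) ** 2
    xc = x - x.mean()
    X = np.column_stack([np.ones_like(xc), xc])

    def nll(log_sigma2: float) -> float:
        v = s2 + np.exp(log_sigma2)
        wX = X / v[:, None]
        xvx = X.T @ wX
        beta = np.linalg.solve(xvx, wX.T @ y)
        r = y - X @ beta
        return 0.5 * float(np.sum(np.log(v)) + np.sum(r * r / v))

    res = optimize.minimize_scalar(nll, bounds=(-30, 10), method="bounded")
    v = s2 + np.exp(res.x)
    wX = X / v[:, None]
    xvx = X.T @ wX
    cov = np.linalg.inv(xvx)
    beta = cov @ (wX.T @ y)
    slope, se = float(beta[1]), float(np.sqrt(max(cov[1, 1], 0.0)))
    intervals = {
        lv: (slope + stats.norm.ppf(0.5 - lv / 2) * se, slope + stats.norm.ppf(0.5 + lv / 2) * se)
        for lv in INTERVAL_LEVELS
    }
    return {
        "slope": slope, "se": se, "intercept": float(beta[0]),
        "sigma2": float(np.exp(res.x)), "intervals": intervals,
        "prob_negative": float(stats.norm.cdf(0.0, loc=slope, scale=se)),
    }


def run_moving_window(
    metrics_df: pd.DataFrame,
    metric: str,
    meta_lookup: pd.DataFrame,
    width: int = 10,
    min_years: int = 6,
    min_sites: int = 250,
    min_countries: int = 8,
    weighted: bool = True,
    rng: np.random.Generator | None = None,
    **window_kwargs,
) -> dict:
    """Full moving-window pass for one metric.

    Returns the window table (mean, se, intervals, proportion positive),
    the trajectory-change summary and total segment count.
    """
    site_years = metrics_df[metrics_df["metric"] == metric].merge(
        meta_lookup[["site_id", "country"]], on="site_id"
    )[["site_id", "country", "year"]]
    windows = build_windows(site_years, width=width, min_years=min_years,
                            min_sites=min_sites, min_countries=min_countries,
                            **window_kwargs)
    rows = []
    for w in windows:
        try:
            res, trends = window_meta(w, metrics_df, metric, meta_lookup,
                                      weighted=weighted, min_years=min_years)
        except ValueError:
            continue
        prop = proportion_positive(trends, rng=rng)
        rows.append({
            "start_year": w.start_year, "end_year": w.end_year,
            "label_year": w.label_year, "n_sites": w.n_sites,
            "mean": res.mean, "se": res.se,
            "prob_positive": res.prob_positive,
            "prop_positive_sites": prop["proportion"],
        })
    window_df = pd.DataFrame(rows)
    traj = trajectory_change(window_df) if len(window_df) >= 3 else None
    return {
        "windows": window_df,
        "trajectory": traj,
        "n_segments": int(sum(w.n_segments for w in windows)),
    }
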