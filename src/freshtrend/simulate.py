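"""Synthetic community data with known ground truth.

Two generators are provided:

* :func:`generate_dataset` builds a full long-format community dataset —
  sites nested in studies nested in countries, log-linear site trends in
  occupancy and expected abundance with AR(1) year effects, negative
  binomial counts, fuzzy trait tables with injected missingness,
  non-native species with a trend premium, and per-site covariates —
  together with a :class:`TruthTable` recording every parameter before
  noise was added.
* :func:`simulate_trend_study` skips the community layer and draws
  per-site metric series directly from the hierarchical trend model the
  two-stage pipeline assumes. It is the workhorse for estimator-recovery
  and moving-window simulations, where the community layer would only
  add cost.

Identical (config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CommunityDataset
from .traits import TraitTable, normalize_fuzzy, table_to_long

#: default per-trait modality counts: 10 traits, 53 modalities in total
DEFAULT_MODALITY_COUNTS = (7, 5, 6, 4, 5, 6, 5, 5, 4, 6)


@dataclass
class SimConfig:
    n_countries: int = 10
    n_studies: int = 40
    n_sites: int = 500
    year_start: int = 1968
    year_end: int = 2020
    min_years: int = 8
    max_years: int = 32
    mean_years: float = 14.9
    species_pool: int = 80
    n_genera: int = 24
    n_families: int = 8
    # trend hyperparameters, percent per year
    trend_mean_pct: float = 0.5
    trend_sd_study_pct: float = 0.3
    trend_sd_country_pct: float = 0.2
    trend_sd_site_pct: float = 0.3
    nonnative_fraction: float = 0.08
    nonnative_trend_premium_pct: float = 3.0
    rho: float = 0.3
    obs_sd: float = 0.15  # stationary sd of the AR(1) year effect (log scale)
    nb_dispersion: float = 5.0
    baseline_occupancy: float = 0.35
    mean_abundance: float = 20.0
    # covariate effects on the log-scale site trend, per covariate SD
    covariate_effects: dict[str, float] = field(default_factory=dict)
    # trait missingness by level of the cascade they should be resolved at
    trait_missing_rate: float = 0.15
    # climate generator
    temp_trend: float = 0.037
    temp_noise_sd: float = 0.5
    ppt_trend: float = 0.49
    ppt_noise_sd: float = 60.0
    doy_jitter_days: float = 6.0

    def __post_init__(self) -> None:
        if not (abs(self.rho) < 1):
            raise ValueError("|rho| must be < 1")
        for name in ("trend_sd_study_pct", "trend_sd_country_pct", "trend_sd_site_pct",
                     "obs_sd", "temp_noise_sd", "ppt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_studies > self.n_sites:
            raise ValueError("more studies than sites is infeasible")
        if self.n_countries > self.n_studies:
            raise ValueError("more countries than studies is infeasible")
        if not self.min_years <= self.mean_years <= self.max_years:
            raise ValueError("mean_years must lie within [min_years, max_years]")
        span = self.year_end - self.year_start + 1
        if self.max_years > span:
            raise ValueError("max_years exceeds the year span")


@dataclass
class SimResult:
    community: CommunityDataset
    trait_table: TraitTable
    taxonomy: pd.DataFrame
    site_metadata: pd.DataFrame
    covariates: pd.DataFrame  # static per-site covariates (unstandardized)
    climate: pd.DataFrame  # site_id, year, tmax, ppt
    truth: pd.DataFrame  # per-site true parameters
    config: SimConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_community_table

        write_community_table(self.community, out / "community.csv")
        table_to_long(self.trait_table).to_csv(out / "traits.csv", index=False)
        self.taxonomy.to_csv(out / "taxonomy.csv")
        self.site_metadata.to_csv(out / "site_metadata.csv")
        self.covariates.to_csv(out / "covariates.csv")
        self.climate.to_csv(out / "climate.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _pct_to_log(pct: float) -> float:
    return float(np.log1p(pct / 100.0))


def _log_to_pct(b: float) -> float:
    return float((np.expm1(b)) * 100.0)


def sample_n_years(config: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Sampling-years counts: min + Binomial hit the configured mean exactly
    while respecting min/max bounds exactly."""
    span = config.max_years - config.min_years
    p = (config.mean_years - config.min_years) / span
    return config.min_years + rng.binomial(span, p, size=size)


def _ar1_series(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path of length n with marginal sd ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0, sd)
    innov_sd = sd * np.sqrt(1 - rho**2)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + rng.normal(0, innov_sd)
    return e


def _site_years(config: SimConfig, rng: np.random.Generator, n_years: int) -> np.ndarray:
    """Irregular sampled years: a random subset of a random duration window."""
    span = config.year_end - config.year_start + 1
    max_dur = span
    dur = min(int(np.ceil(n_years * rng.uniform(1.0, 1.6))), max_dur)
    dur = max(dur, n_years)
    start = int(rng.integers(config.year_start, config.year_end - dur + 2))
    years = rng.choice(np.arange(start, start + dur), size=n_years, replace=False)
    return np.sort(years)


# --------------------------------------------------------------------------
# traits


def generate_trait_table(
    species: list[str],
    taxonomy: pd.DataFrame,
    config: SimConfig,
    seed: int,
    modality_counts: tuple[int, ...] = DEFAULT_MODALITY_COUNTS,
) -> TraitTable:
    """Fuzzy trait table over the species pool with injected missingness.

    Species profiles are Dirichlet draws around genus-level centres so the
    genus/family medians used by gap filling are informative. A fraction
    ``config.trait_missing_rate`` of (species, trait) blocks is masked.
    """
    rng = np.random.default_rng(seed)
    traits = [f"trait{k+1:02d}" for k in range(len(modality_counts))]
    cols = pd.MultiIndex.from_tuples(
        [(tr, f"m{j+1}") for tr, m in zip(traits, modality_counts) for j in range(m)],
        names=["trait", "modality"],
    )
    genera = taxonomy.loc[species, "genus"].unique()
    centre: dict[tuple[str, str], np.ndarray] = {}
    for g in genera:
        for tr, m in zip(traits, modality_counts):
            centre[(g, tr)] = rng.dirichlet(np.ones(m) * 1.5)

    rows = []
    for sp in species:
        g = taxonomy.loc[sp, "genus"]
        profile = []
        for tr, m in zip(traits, modality_counts):
            profile.append(rng.dirichlet(centre[(g, tr)] * 25 + 0.5))
        rows.append(np.concatenate(profile))
    raw = pd.DataFrame(rows, index=pd.Index(species, name="taxon"), columns=cols)

    mask = rng.random((len(species), len(traits))) < config.trait_missing_rate
    for i, sp in enumerate(species):
        for k, tr in enumerate(traits):
            if mask[i, k]:
                raw.loc[sp, tr] = np.nan
    return normalize_fuzzy(raw)


def _build_pool(config: SimConfig) -> tuple[list[str], pd.DataFrame]:
    species = [f"sp{i:03d}" for i in range(config.species_pool)]
    genera = [f"gen{i % config.n_genera:02d}" for i in range(config.species_pool)]
    families = [f"fam{(i % config.n_genera) % config.n_families:02d}"
                for i in range(config.species_pool)]
    orders = ["Ephemeroptera", "Plecoptera", "Trichoptera", "Diptera", "Coleoptera", "Mollusca"]
    order = [orders[(i % config.n_genera) % len(orders)] for i in range(config.species_pool)]
    class_ = ["Insecta" if o != "Mollusca" else "Gastropoda" for o in order]
    taxonomy = pd.DataFrame(
        {"genus": genera, "family": families, "order": order, "class_": class_},
        index=pd.Index(species, name="taxon_id"),
    )
    return species, taxonomy


# --------------------------------------------------------------------------
# covariates


def generate_covariates(
    site_ids: list[str], config: SimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Static site covariates and annual climate series.

    Climate series follow configurable linear trends plus white noise, so
    closing the loop through the climate-trend estimator recovers the
    configured slope exactly when noise is zero.
    """
    rng = np.random.default_rng(seed)
    n = len(site_ids)
    static = pd.DataFrame(
        {
            "elevation": rng.gamma(4, 90, n),
            "slope": rng.gamma(2, 1.5, n),
            "stream_order": rng.integers(1, 8, n).astype(float),
            "flow_accumulation": rng.lognormal(4, 1.4, n),
            "pct_urban": np.clip(rng.beta(1.2, 8, n) * 100, 0, 100),
            "pct_cropland": np.clip(rng.beta(2, 4, n) * 100, 0, 100),
            "dam_score": rng.exponential(0.4, n) * rng.binomial(1, 0.6, n),
            "tmax_mean": rng.normal(18, 4, n),
            "ppt_mean": rng.normal(800, 180, n),
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    years = np.arange(config.year_start, config.year_end + 1)
    t0 = years.mean()
    frames = []
    for sid in site_ids:
        tmax = (static.loc[sid, "tmax_mean"] + config.temp_trend * (years - t0)
                + rng.normal(0, config.temp_noise_sd, len(years)))
        ppt = (static.loc[sid, "ppt_mean"] + config.ppt_trend * (years - t0)
               + rng.normal(0, config.ppt_noise_sd, len(years)))
        frames.append(pd.DataFrame({"site_id": sid, "year": years, "tmax": tmax, "ppt": ppt}))
    return static, pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# the full community generator


def generate_dataset(config: SimConfig, seed: int) -> SimResult:
    """Draw a complete synthetic dataset plus its truth table.

    Site trends act multiplicatively on both per-species occupancy and
    expected abundance, so both richness and total abundance carry the
    site's true percent trend (to first order). Non-native species get
    the configured trend premium on top.
    """
    rng = np.random.default_rng(seed)
    countries = [f"C{i:02d}" for i in range(config.n_countries)]
    studies = [f"S{i:03d}" for i in range(config.n_studies)]
    study_country = {
        s: countries[i % config.n_countries] for i, s in enumerate(studies)
    }
    site_ids = [f"site{i:04d}" for i in range(config.n_sites)]
    site_study = {s: studies[i % config.n_studies] for i, s in enumerate(site_ids)}

    species, taxonomy = _build_pool(config)
    n_nn = int(round(config.nonnative_fraction * config.species_pool))
    nonnative = set(rng.choice(species, size=n_nn, replace=False)) if n_nn else set()

    static, climate = generate_covariates(site_ids, config, int(rng.integers(2**31)))
    effects = pd.Series(config.covariate_effects, dtype=float)
    if len(effects):
        missing = set(effects.index) - set(static.columns)
        if missing:
            raise ValueError(f"covariate effect(s) refer to unknown column(s): {sorted(missing)}")
        std = (static[effects.index] - static[effects.index].mean()) / static[
            effects.index
        ].std(ddof=1)
        cov_term = (std * effects).sum(axis=1)
    else:
        cov_term = pd.Series(0.0, index=static.index)

    u_study = {s: rng.normal(0, _pct_to_log(config.trend_sd_study_pct)) for s in studies}
    v_country = {c: rng.normal(0, _pct_to_log(config.trend_sd_country_pct)) for c in countries}

    b_mean = _pct_to_log(config.trend_mean_pct)
    premium = _pct_to_log(config.nonnative_trend_premium_pct)

    n_years = sample_n_years(config, rng, config.n_sites)
    base_occ = np.clip(
        config.baseline_occupancy * rng.lognormal(0, 0.4, config.species_pool), 0.01, 0.9
    )
    base_ab = rng.lognormal(np.log(config.mean_abundance), 0.8, config.species_pool)

    truth_rows = []
    community_rows = []
    for i, sid in enumerate(site_ids):
        study = site_study[sid]
        country = study_country[study]
        b_site = (
            b_mean + u_study[study] + v_country[country]
            + float(cov_term[sid])
            + rng.normal(0, _pct_to_log(config.trend_sd_site_pct))
        )
        years = _site_years(config, rng, int(n_years[i]))
        t_mid = years.mean()
        eta = _ar1_series(rng, len(years), config.rho, config.obs_sd)
        month = int(rng.integers(3, 10))
        modal_day = int(rng.integers(5, 20))

        truth_rows.append({
            "site_id": sid, "study_id": study, "country": country,
            "trend_log": b_site, "trend_pct": _log_to_pct(b_site),
            "study_effect_log": u_study[study], "country_effect_log": v_country[country],
            "covariate_effect_log": float(cov_term[sid]),
            "rho": config.rho, "n_years": int(n_years[i]),
            "nonnative_premium_log": premium,
        })

        for k, yr in enumerate(years):
            growth = b_site * (yr - t_mid) + eta[k]
            day = modal_day + int(np.round(rng.normal(0, config.doy_jitter_days)))
            day = int(np.clip(day, 1, 28))
            date = f"{yr}-{month:02d}-{day:02d}"
            for j, sp in enumerate(species):
                g = growth + premium * (yr - t_mid) if sp in nonnative else growth
                # the site trend acts on occupancy only: both expected richness
                # (sum of p) and expected total abundance (sum of p * mu) then
                # carry the same log trend b_site
                p = min(base_occ[j] * float(np.exp(g)), 0.995)
                if rng.random() >= p:
                    continue
                mu = base_ab[j]
                k_disp = config.nb_dispersion
                count = rng.negative_binomial(k_disp, k_disp / (k_disp + mu))
                count = max(int(count), 1)
                community_rows.append(
                    (sid, study, country, date, sp, "species", float(count))
                )

    table = pd.DataFrame(
        community_rows,
        columns=["site_id", "study_id", "country", "date", "taxon_id", "taxon_level", "abundance"],
    )
    table["date"] = pd.to_datetime(table["date"])
    community = CommunityDataset(table)

    trait_table = generate_trait_table(species, taxonomy, config, int(rng.integers(2**31)))

    meta = pd.DataFrame({
        "site_id": site_ids,
        "study_id": [site_study[s] for s in site_ids],
        "country": [study_country[site_study[s]] for s in site_ids],
        "taxonomic_resolution": "species",
        "effort_consistent": True,
    }).set_index("site_id")
    meta = meta.join(static)

    truth = pd.DataFrame(truth_rows)
    truth["nonnative_species"] = ",".join(sorted(nonnative))
    return SimResult(community, trait_table, taxonomy, meta, static, climate, truth, config)


# --------------------------------------------------------------------------
# direct metric-level simulator


def simulate_trend_study(
    n_sites: int = 500,
    n_studies: int = 40,
    n_countries: int = 10,
    mean_trend_pct: float = 0.5,
    sd_study_pct: float = 0.3,
    sd_country_pct: float = 0.2,
    sd_site_pct: float = 0.3,
    rho: float = 0.5,
    noise_sd: float = 0.08,
    year_start: int = 1968,
    year_end: int = 2020,
    min_years: int = 8,
    max_years: int = 32,
    mean_years: float = 14.9,
    metric: str = "abundance",
    trend_change_per_year_log10: float = 0.0,
    trend_ref_year: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Metric series drawn directly from the hierarchical trend model.

    The site slope on the log10 scale is
    ``log10(1 + pct/100)`` plus study, country and site deviations (also
    specified in percent and converted). With
    ``trend_change_per_year_log10`` nonzero the instantaneous slope drifts
    linearly over calendar years (deceleration scenarios); series then
    follow the integrated quadratic path.

    Returns (metrics tidy frame, site lookup with study/country, truth).
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_countries=n_countries, n_studies=n_studies, n_sites=n_sites,
        year_start=year_start, year_end=year_end,
        min_years=min_years, max_years=max_years, mean_years=mean_years,
        rho=rho,
    )
    countries = [f"C{i:02d}" for i in range(n_countries)]
    studies = [f"S{i:03d}" for i in range(n_studies)]
    study_country = {s: countries[i % n_countries] for i, s in enumerate(studies)}
    site_ids = [f"site{i:04d}" for i in range(n_sites)]
    site_study = {s: studies[i % n_studies] for i, s in enumerate(site_ids)}

    def pct_to_log10(p: float) -> float:
        return float(np.log10(1 + p / 100.0))

    b_mean = pct_to_log10(mean_trend_pct)
    u = {s: rng.normal(0, pct_to_log10(sd_study_pct)) for s in studies}
    v = {c: rng.normal(0, pct_to_log10(sd_country_pct)) for c in countries}
    tref = trend_ref_year if trend_ref_year is not None else (year_start + year_end) / 2

    n_years = sample_n_years(cfg, rng, n_sites)
    rows, truth_rows = [], []
    for i, sid in enumerate(site_ids):
        study = site_study[sid]
        country = study_country[study]
        b_i = b_mean + u[study] + v[country] + rng.normal(0, pct_to_log10(sd_site_pct))
        years = _site_years(cfg, rng, int(n_years[i]))
        eta = _ar1_series(rng, len(years), rho, noise_sd)
        a_i = rng.normal(1.2, 0.3)  # log10 level
        tc = years - tref
        path = a_i + b_i * tc + 0.5 * trend_change_per_year_log10 * tc**2 + eta
        vals = 10.0**path
        for yr, val in zip(years, vals):
            rows.append((sid, metric, int(yr), float(val)))
        truth_rows.append({
            "site_id": sid, "study_id": study, "country": country,
            "trend_log10": b_i, "trend_pct": float((10.0**b_i - 1) * 100),
            "n_years": int(n_years[i]),
        })

    metrics_df = pd.DataFrame(rows, columns=["site_id", "metric", "year", "value"])
    lookup = pd.DataFrame({
        "site_id": site_ids,
        "study_id": [site_study[s] for s in site_ids],
        "country": [study_country[site_study[s]] for s in site_ids],
    })
    return metrics_df, lookup, pd.DataFrame(truth_rows)


def config_from_yaml(path: str | Path) -> SimConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimConfig(**raw)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
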