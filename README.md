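# freshtrend

Trend analysis for multidecadal freshwater invertebrate community time
series: taxonomic and functional diversity metrics, site-level AR(1)
trend estimation, hierarchical (study/country) meta-analysis with
measurement-error weighting, 10-year moving-window trajectories, and
environmental-driver models with adaptive shrinkage — plus a synthetic
data generator with recorded ground truth so the whole pipeline is
testable end to end without external downloads.

## Pipeline

1. **IO & inclusion rules** (`freshtrend.io`) — long-format community
   tables (site, study, country, date, taxon, level, abundance); ≥8
   sampling years, one sampling event per year within a single 3-month
   season (longest season preferred), configurable taxon exclusions,
   community subsets (EPT, insects, native / non-native).
2. **Taxonomic metrics** (`freshtrend.taxonomic`) — abundance, richness,
   Shannon diversity/evenness, individual-based rarefied richness
   (hypergeometric expectation, reference = series minimum), temporal
   turnover between consecutive sampled years.
3. **Traits & functional metrics** (`freshtrend.traits`,
   `freshtrend.functional`) — fuzzy-coded trait normalization, four-step
   taxonomic gap filling (direct → genus data → genus median → family
   median) with provenance and coverage reports, >85% coverage filter,
   community-weighted means; Gower-style fuzzy and scaled-Euclidean
   trait distances, PCoA (6 axes, sqrt/Cailliez corrections),
   convex-hull functional richness, MST-based evenness, divergence,
   Rao's Q, Simpson diversity and functional redundancy (1 − Q/D),
   CWM-based functional turnover.
4. **Site trends** (`freshtrend.trends`) — exact Gaussian AR(1)
   likelihood over irregular years (correlation ρ^|Δt|), REML profile
   over ρ with posterior averaging across the ρ grid for calibrated
   intervals, automatic day-of-year covariate (>30-day spread),
   metric-specific transforms (log10 / square / beta-logit) and
   back-transformation to percent change per year.
5. **Meta-analysis** (`freshtrend.meta`) — crossed study and country
   random intercepts, known per-site sampling variances (or estimated
   residual variance when unweighted), REML; probability of direction,
   80/90/95% intervals, country jackknife, fixed-factor sensitivity
   reruns.
6. **Moving windows** (`freshtrend.window`) — 10-year windows with ≥6
   sampling years per site, ≥250 sites and ≥8 countries per window
   (all configurable), per-window re-estimation and meta-analysis,
   study-weighted proportion of positive site trends with posterior
   draw propagation, measurement-error change-in-trajectory regression.
7. **Drivers** (`freshtrend.drivers`) — standardized covariates (unit
   sample SD), inverse-distance dam impact score, measurement-error
   mixed regression with empirical-Bayes ridge shrinkage on covariate
   coefficients (an unshrunk "flat" backend for comparison), marginal
   predictions holding other covariates at their medians.
8. **Synthetic data** (`freshtrend.simulate`) — full community generator
   (negative-binomial counts, AR(1) year effects, trends nested in
   study/country, fuzzy traits with missingness, non-native premium,
   climate/land-use covariates) and a fast direct metric-series
   simulator; both record a truth table and are seed-deterministic.

## CLI

```sh
freshtrend simulate --config sim.yaml --seed 1 --out sim/
freshtrend validate sim/community.csv
freshtrend subset sim/community.csv --subset EPT --taxonomy sim/taxonomy.csv --out ept.csv
freshtrend metrics sim/community.csv --set taxonomic --out metrics.csv
freshtrend trends metrics.csv --out trends.csv
freshtrend meta trends.csv --lookup sim/truth.csv --metric abundance
freshtrend window metrics.csv --lookup sim/truth.csv --metric abundance --out windows.csv
freshtrend drivers --trends trends.csv --covariates cov.csv --lookup sim/truth.csv \
    --metric abundance --out coefs.csv
```

## Notes

- All estimators are deterministic (GLS / REML / empirical-Bayes ridge);
  no MCMC sampler is required. Probability-of-direction values are
  Gaussian approximations of the corresponding posterior quantities.
- Deliverables are plain-text formats throughout (CSV/JSON/YAML).
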