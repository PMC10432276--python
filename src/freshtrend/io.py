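"""Reading, validation and subsetting of community time-series data.

The community table is long-format delimited text with one row per taxon
per sampling event: ``site_id, study_id, country, date, taxon_id,
taxon_level, abundance``. Unknown columns are preserved as annotations.

Inclusion rules enforced here:

* at least 8 distinct sampling years per site (not necessarily consecutive);
* a single sampling season per site, a season being any block of three
  consecutive calendar months (12 rolling blocks); when several seasons
  were sampled the season with the most sampling years is retained,
  ties broken by the earlier median sampling date;
* one sampling event (one calendar day) per year;
* constant sampling effort and taxonomic resolution, asserted via
  metadata flags because they cannot be recomputed from counts alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "site_id",
    "study_id",
    "country",
    "date",
    "taxon_id",
    "taxon_level",
    "abundance",
)

TAXON_LEVELS = ("species", "genus", "family", "coarser")

#: Orders forming the EPT indicator group.
EPT_ORDERS = frozenset({"Ephemeroptera", "Plecoptera", "Trichoptera"})


class DataError(ValueError):
    """Raised when an input table violates the format contract."""


class MissingColumnError(DataError):
    def __init__(self, columns: Iterable[str]):
        self.columns = sorted(columns)
        super().__init__(f"missing required column(s): {', '.join(self.columns)}")


@dataclass
class CommunityDataset:
    """A parsed long-format community table.

    ``table`` always carries the required columns plus a derived integer
    ``year`` column; extra input columns are kept and listed in
    ``annotations``.
    """

    table: pd.DataFrame
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "year" not in self.table.columns:
            self.table = self.table.assign(year=self.table["date"].dt.year)

    @property
    def n_rows(self) -> int:
        return len(self.table)

    @property
    def sites(self) -> list[str]:
        return sorted(self.table["site_id"].unique())

    def site(self, site_id: str) -> pd.DataFrame:
        return self.table[self.table["site_id"] == site_id]

    def total_abundance(self) -> float:
        return float(self.table["abundance"].sum())

    def copy(self) -> "CommunityDataset":
        return CommunityDataset(self.table.copy(), self.annotations)


@dataclass
class TimeSeries:
    """One site's selected annual series within a single season."""

    site_id: str
    events: pd.DataFrame  # rows of the community table, one event per year
    season_start_month: int  # 1..12, season = this month plus the next two
    n_sampling_years: int

    @property
    def season_label(self) -> str:
        months = "JFMAMJJASOND"
        m = self.season_start_month - 1
        return "".join(months[(m + k) % 12] for k in range(3))

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.events["year"].unique())


@dataclass
class ValidationReport:
    """Per-site pass/fail record for every inclusion rule."""

    site_id: str
    checks: dict[str, bool] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    def failures(self) -> list[str]:
        return [k for k, ok in self.checks.items() if not ok]


def _sniff_sep(path: Path) -> str:
    head = Path(path).open("r", encoding="utf-8").readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def load_community_table(path: str | Path, sep: str | None = None) -> CommunityDataset:
    """Load a delimited community table.

    Raises :class:`MissingColumnError` if a required column is absent and
    :class:`DataError` listing offending row numbers for unparseable dates
    or negative abundances.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype={"site_id": str, "study_id": str})
    missing = set(REQUIRED_COLUMNS) - set(raw.columns)
    if missing:
        raise MissingColumnError(missing)

    dates = pd.to_datetime(raw["date"], format="ISO8601", errors="coerce")
    bad_dates = raw.index[dates.isna()].tolist()
    if bad_dates:
        raise DataError(f"unparseable date in rows {bad_dates[:20]}")
    raw = raw.assign(date=dates)

    abund = pd.to_numeric(raw["abundance"], errors="coerce")
    bad_ab = raw.index[abund.isna() | (abund < 0)].tolist()
    if bad_ab:
        raise DataError(f"negative or non-numeric abundance in rows {bad_ab[:20]}")
    raw = raw.assign(abundance=abund.astype(float))

    bad_level = set(raw["taxon_level"].unique()) - set(TAXON_LEVELS)
    if bad_level:
        raise DataError(f"unknown taxon_level value(s): {sorted(bad_level)}")

    annotations = tuple(c for c in raw.columns if c not in REQUIRED_COLUMNS)
    ds = CommunityDataset(raw, annotations)
    logger.info("loaded %d rows, %d sites from %s", ds.n_rows, len(ds.sites), path)
    return ds


def write_community_table(ds: CommunityDataset, path: str | Path, sep: str = ",") -> None:
    out = ds.table.drop(columns=["year"], errors="ignore").copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=sep, index=False)


def load_site_metadata(path: str | Path) -> pd.DataFrame:
    """Site metadata CSV keyed by ``site_id``; percentages validated to [0, 100]."""
    meta = pd.read_csv(path, dtype={"site_id": str}).set_index("site_id")
    for col in ("pct_urban", "pct_cropland"):
        if col in meta.columns:
            vals = meta[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise DataError(f"{col} outside [0, 100]")
    return meta


def load_nonnative_lookup(path: str | Path) -> dict[tuple[str, str], str]:
    """CSV with columns species, country, status -> {(species, country): status}."""
    df = pd.read_csv(path)
    need = {"species", "country", "status"}
    if not need <= set(df.columns):
        raise MissingColumnError(need - set(df.columns))
    bad = set(df["status"].unique()) - {"native", "non_native"}
    if bad:
        raise DataError(f"unknown status value(s): {sorted(bad)}")
    return {(r.species, r.country): r.status for r in df.itertuples()}


def load_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxonomy map CSV: taxon_id, genus, family, order, class_ (any subset)."""
    return pd.read_csv(path, dtype=str).set_index("taxon_id")


# --------------------------------------------------------------------------
# season selection


def _season_months(start: int) -> tuple[int, int, int]:
    return (start, start % 12 + 1, (start + 1) % 12 + 1)


def _ensure_year(df: pd.DataFrame) -> pd.DataFrame:
    if "year" not in df.columns:
        df = df.assign(year=df["date"].dt.year)
    return df


def assign_season(months: Iterable[int]) -> int:
    """Season (start month of a rolling 3-month block) holding the modal month."""
    months = pd.Series(list(months))
    modal = int(months.mode().iloc[0])
    # prefer the block centred on the modal month, i.e. starting the month before
    return (modal - 2) % 12 + 1


def select_annual_series(site_df: pd.DataFrame) -> TimeSeries | None:
    """Reduce a site's raw events to one event per year in one season.

    The season retained is the 3-consecutive-month block covering the most
    sampling years; ties go to the block whose events have the earlier
    median date, then to the smaller start month. Within each retained
    year the earliest sampling day is kept. Returns ``None`` when no
    season reaches 8 sampling years.
    """
    df = _ensure_year(site_df.copy())
    months = df["date"].dt.month

    best: tuple[int, pd.Timestamp, int] | None = None  # (-n_years, median_date, start)
    for start in range(1, 13):
        in_block = months.isin(_season_months(start))
        if not in_block.any():
            continue
        n_years = df.loc[in_block, "year"].nunique()
        med = df.loc[in_block, "date"].astype("int64").median()
        key = (-n_years, med, start)
        if best is None or key < best:
            best = key
    assert best is not None
    n_years, start = -best[0], best[2]
    if n_years < 8:
        logger.info(
            "site %s excluded: best season has %d < 8 sampling years",
            df["site_id"].iloc[0], n_years,
        )
        return None

    sel = df[months.isin(_season_months(start))]
    # one event (= one day) per year: keep the earliest day
    first_day = sel.groupby("year")["date"].transform("min")
    sel = sel[sel["date"] == first_day]
    return TimeSeries(
        site_id=str(df["site_id"].iloc[0]),
        events=sel.reset_index(drop=True),
        season_start_month=start,
        n_sampling_years=n_years,
    )


def site_taxonomic_resolution(
    site_df: pd.DataFrame, species_threshold: float = 0.8, family_threshold: float = 0.2
) -> str:
    """Classify a site as species / mixed / family resolution.

    Based on the fraction of rows identified to species level; thresholds
    are configurable because the source classification rule is not
    recomputable from the data alone.
    """
    frac_sp = (site_df["taxon_level"] == "species").mean()
    if frac_sp >= species_threshold:
        return "species"
    if frac_sp <= family_threshold:
        return "family"
    return "mixed"


def validate_time_series(
    site_df: pd.DataFrame,
    min_years: int = 8,
    effort_consistent: bool = True,
    resolution_consistent: bool = True,
) -> ValidationReport:
    """Check one site's (already season-selected or raw) events against the rules."""
    site_df = _ensure_year(site_df)
    site_id = str(site_df["site_id"].iloc[0])
    rep = ValidationReport(site_id)
    years = site_df["year"]
    rep.checks["min_years"] = years.nunique() >= min_years

    months = sorted(site_df["date"].dt.month.unique())
    single = any(set(months) <= set(_season_months(s)) for s in range(1, 13))
    rep.checks["single_season"] = single
    if not single:
        rep.notes["single_season"] = "season selection required (multiple 3-month blocks sampled)"

    days_per_year = site_df.groupby("year")["date"].nunique()
    rep.checks["one_event_per_year"] = bool((days_per_year == 1).all())

    rep.checks["consistent_effort"] = bool(effort_consistent)
    rep.checks["consistent_resolution"] = bool(resolution_consistent)
    return rep


# --------------------------------------------------------------------------
# taxon exclusions and subsetting


def default_exclusion_list() -> list[str]:
    """Ship-with defaults for small/terrestrial taxa removed before analysis.

    The complete operational list is data-provider specific; this default
    names the commonly excluded groups (mites, copepods, cladocerans,
    ostracods and semi-aquatic/terrestrial groups).
    """
    text = resources.files("freshtrend").joinpath("data/default_exclusions.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def apply_taxon_exclusions(
    ds: CommunityDataset,
    exclusions: Iterable[str] | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> CommunityDataset:
    """Drop excluded taxa, matching taxon ids and (if taxonomy given) any rank name."""
    excl = set(exclusions if exclusions is not None else default_exclusion_list())
    drop = ds.table["taxon_id"].isin(excl)
    if taxonomy is not None:
        ranks = taxonomy.reindex(ds.table["taxon_id"])
        for col in ranks.columns:
            drop |= ranks[col].isin(excl).to_numpy()
    n = int(drop.sum())
    if n:
        logger.info("excluded %d rows matching the taxon exclusion list", n)
    return CommunityDataset(ds.table[~drop].reset_index(drop=True), ds.annotations)


def subset_community(
    ds: CommunityDataset,
    subset: str,
    taxonomy: pd.DataFrame | None = None,
    lookup: Mapping[tuple[str, str], str] | None = None,
    site_resolution: Mapping[str, str] | None = None,
) -> CommunityDataset:
    """Filter the dataset to one community subset.

    ``subset`` is one of ``all``, ``EPT``, ``insects``, ``native``,
    ``non_native``. EPT and insect subsets need a taxonomy map with
    ``order`` / ``class_`` columns; native status needs the
    (species, country) lookup. Family-resolution sites are skipped for
    native/non-native subsets because species cannot be resolved there.
    """
    if subset == "all":
        return ds.copy()
    tbl = ds.table

    if subset in ("EPT", "insects"):
        if taxonomy is None:
            raise ValueError(f"subset '{subset}' requires a taxonomy map")
        ranks = taxonomy.reindex(tbl["taxon_id"])
        if subset == "EPT":
            keep = ranks["order"].isin(EPT_ORDERS).to_numpy()
        else:
            keep = (ranks["class_"] == "Insecta").to_numpy()
    elif subset in ("native", "non_native"):
        if lookup is None:
            raise ValueError(f"subset '{subset}' requires a non-native lookup")
        if site_resolution is not None:
            skipped = {s for s in ds.sites if site_resolution.get(s) == "family"}
            if skipped:
                logger.info(
                    "skipping %d family-resolution site(s) for subset '%s'",
                    len(skipped), subset,
                )
            tbl = tbl[~tbl["site_id"].isin(skipped)]
        is_species = (tbl["taxon_level"] == "species").to_numpy()
        status = np.array(
            [lookup.get((t, c), "native") for t, c in zip(tbl["taxon_id"], tbl["country"])]
        )
        if subset == "non_native":
            keep = is_species & (status == "non_native")
            if not keep.any():
                logger.info("no non-natives detected in subset request")
        else:
            # native = everything not flagged non-native (incl. coarser taxa)
            keep = ~(is_species & (status == "non_native"))
    else:
        raise ValueError(f"unknown subset '{subset}'")

    return CommunityDataset(tbl[keep].reset_index(drop=True), ds.annotations)
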