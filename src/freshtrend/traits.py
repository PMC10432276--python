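"""Fuzzy-coded trait handling: normalization, gap filling, coverage, CWMs.

A trait table holds per-taxon affinity scores across the modalities of
each trait; within a trait the affinities of one taxon sum to 1. Missing
trait information is filled through a four-step taxonomic cascade and the
provenance of every value is recorded:

1. ``direct`` — data at the original identification level;
2. ``genus_data`` — a genus-level database entry;
3. ``genus_median`` — per-modality median over congeneric species,
   renormalized;
4. ``family_median`` — per-modality median over confamilial taxa,
   renormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROVENANCE_STEPS = ("direct", "genus_data", "genus_median", "family_median", "missing")


@dataclass
class TraitTable:
    """Fuzzy trait affinities plus per-(taxon, trait) provenance.

    ``affinities``: DataFrame indexed by taxon with MultiIndex columns
    (trait, modality). NaN across a whole trait block means missing.
    ``provenance``: DataFrame indexed by taxon, one column per trait.
    """

    affinities: pd.DataFrame
    provenance: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.affinities.columns, pd.MultiIndex):
            raise ValueError("affinity columns must be a (trait, modality) MultiIndex")
        if self.provenance is None:
            prov = pd.DataFrame(
                "direct", index=self.affinities.index, columns=self.traits, dtype=object
            )
            for tr in self.traits:
                prov.loc[self.affinities[tr].isna().all(axis=1), tr] = "missing"
            self.provenance = prov

    @property
    def traits(self) -> list[str]:
        return list(self.affinities.columns.get_level_values(0).unique())

    @property
    def taxa(self) -> pd.Index:
        return self.affinities.index

    def trait_block(self, trait: str) -> pd.DataFrame:
        return self.affinities[trait]

    def coverage(self) -> pd.Series:
        """Fraction of taxa with data, per trait."""
        return pd.Series(
            {tr: 1.0 - self.affinities[tr].isna().all(axis=1).mean() for tr in self.traits}
        )

    def complete_taxa(self) -> pd.Index:
        """Taxa with no missing trait block."""
        ok = ~self.affinities.isna().any(axis=1)
        return self.affinities.index[ok]

    def copy(self) -> "TraitTable":
        return TraitTable(self.affinities.copy(), self.provenance.copy())


def _renormalize_block(block: pd.DataFrame) -> pd.DataFrame:
    sums = block.sum(axis=1)
    out = block.div(sums, axis=0)
    out[sums <= 0] = np.nan
    return out


def normalize_fuzzy(raw: pd.DataFrame) -> TraitTable:
    """Scale raw non-negative modality scores to sum to 1 within each trait.

    An all-zero trait block becomes missing. Negative scores are an error.
    Idempotent on already-normalized tables.
    """
    if not isinstance(raw.columns, pd.MultiIndex):
        raise ValueError("raw scores need (trait, modality) MultiIndex columns")
    if (raw.fillna(0) < 0).any().any():
        raise ValueError("negative trait score")
    blocks = {tr: _renormalize_block(raw[tr]) for tr in raw.columns.get_level_values(0).unique()}
    aff = pd.concat(blocks, axis=1)
    aff.columns.names = raw.columns.names
    return TraitTable(aff)


def traits_long_to_table(df: pd.DataFrame) -> TraitTable:
    """Build a table from a long frame with columns taxon, trait, modality, affinity."""
    wide = df.pivot_table(
        index="taxon", columns=["trait", "modality"], values="affinity", aggfunc="first"
    )
    return normalize_fuzzy(wide)


def table_to_long(table: TraitTable) -> pd.DataFrame:
    long = table.affinities.stack(["trait", "modality"], future_stack=True).dropna()
    long = long.rename("affinity").reset_index()
    long.columns = ["taxon", "trait", "modality", "affinity"]
    return long


@dataclass
class CoverageReport:
    """Coverage bookkeeping of the gap-filling cascade.

    ``per_step``: overall fraction of (taxon, trait) cells resolved after
    each cascade step; ``resolved_counts``: cells resolved *at* each step.
    """

    per_step: dict[str, float]
    resolved_counts: dict[str, int]
    per_trait: pd.Series


def _median_profile(block: pd.DataFrame) -> pd.Series | None:
    """Per-modality median over rows with data, renormalized to sum 1."""
    have = block.dropna(how="any")
    if have.empty:
        return None
    med = have.median(axis=0)
    tot = med.sum()
    if tot <= 0:
        return None
    return med / tot


def fill_gaps(
    taxa: list[str],
    trait_db: TraitTable,
    taxonomy: pd.DataFrame,
) -> tuple[TraitTable, CoverageReport]:
    """Resolve trait profiles for ``taxa`` through the four-step cascade.

    ``taxonomy`` is indexed by taxon id with ``genus`` and ``family``
    columns (NaN where unknown). The database may contain species-,
    genus- or family-level rows keyed by their name. Directly observed
    values are never modified; coverage is monotone over steps.
    """
    cols = trait_db.affinities.columns
    traits = trait_db.traits
    aff = pd.DataFrame(np.nan, index=pd.Index(taxa, name="taxon"), columns=cols)
    prov = pd.DataFrame("missing", index=aff.index, columns=traits, dtype=object)

    tax = taxonomy.reindex(taxa)
    genus = tax["genus"] if "genus" in tax.columns else pd.Series(index=tax.index, dtype=object)
    family = tax["family"] if "family" in tax.columns else pd.Series(index=tax.index, dtype=object)

    counts = dict.fromkeys(PROVENANCE_STEPS[:4], 0)
    n_cells = len(taxa) * len(traits)

    def has_data(key: str, trait: str) -> bool:
        return key in trait_db.affinities.index and not trait_db.affinities.loc[key, trait].isna().all()

    # step 1: direct match at the identification level
    for t in taxa:
        for tr in traits:
            if has_data(t, tr):
                aff.loc[t, tr] = trait_db.affinities.loc[t, tr].to_numpy()
                prov.loc[t, tr] = "direct"
                counts["direct"] += 1
    cov = {"direct": 1 - aff.isna().all(axis=1).to_numpy().reshape(len(taxa), -1).mean()}

    def _step_coverage() -> float:
        resolved = sum((prov[tr] != "missing").sum() for tr in traits)
        return resolved / n_cells

    cov = {"direct": _step_coverage()}

    # step 2: genus-level database entry
    for t in taxa:
        g = genus.get(t)
        if not isinstance(g, str):
            continue
        for tr in traits:
            if prov.loc[t, tr] == "missing" and has_data(g, tr):
                aff.loc[t, tr] = trait_db.affinities.loc[g, tr].to_numpy()
                prov.loc[t, tr] = "genus_data"
                counts["genus_data"] += 1
    cov["genus_data"] = _step_coverage()

    # step 3: median over congeneric species in the database
    db_tax = taxonomy.reindex(trait_db.affinities.index)
    db_genus = db_tax["genus"] if "genus" in db_tax.columns else None
    for t in taxa:
        g = genus.get(t)
        if not isinstance(g, str) or db_genus is None:
            continue
        congeners = trait_db.affinities.index[(db_genus == g).to_numpy()]
        congeners = congeners.difference([t])
        if len(congeners) == 0:
            continue
        for tr in traits:
            if prov.loc[t, tr] != "missing":
                continue
            med = _median_profile(trait_db.affinities.loc[congeners, tr])
            if med is not None:
                aff.loc[t, tr] = med.to_numpy()
                prov.loc[t, tr] = "genus_median"
                counts["genus_median"] += 1
    cov["genus_median"] = _step_coverage()

    # step 4: median over confamilial taxa in the database
    db_family = db_tax["family"] if "family" in db_tax.columns else None
    for t in taxa:
        f = family.get(t)
        if not isinstance(f, str) or db_family is None:
            continue
        kin = trait_db.affinities.index[(db_family == f).to_numpy()]
        kin = kin.difference([t])
        if len(kin) == 0:
            continue
        for tr in traits:
            if prov.loc[t, tr] != "missing":
                continue
            med = _median_profile(trait_db.affinities.loc[kin, tr])
            if med is not None:
                aff.loc[t, tr] = med.to_numpy()
                prov.loc[t, tr] = "family_median"
                counts["family_median"] += 1
    cov["family_median"] = _step_coverage()

    unresolved = aff.index[prov.eq("missing").any(axis=1)]
    for t in unresolved:
        logger.info("taxon %s left with missing trait(s) after gap filling", t)

    table = TraitTable(aff, prov)
    report = CoverageReport(per_step=cov, resolved_counts=counts, per_trait=table.coverage())
    return table, report


def filter_traits_by_coverage(table: TraitTable, threshold: float = 0.85) -> TraitTable:
    """Keep only traits with coverage strictly above ``threshold``."""
    cov = table.coverage()
    keep = [tr for tr in table.traits if cov[tr] > threshold]
    if not keep:
        raise ValueError(f"no trait exceeds coverage threshold {threshold}")
    dropped = sorted(set(table.traits) - set(keep))
    if dropped:
        logger.info("dropping trait(s) below coverage threshold: %s", dropped)
    aff = pd.concat({tr: table.affinities[tr] for tr in keep}, axis=1)
    aff.columns.names = table.affinities.columns.names
    return TraitTable(aff, table.provenance[keep].copy())


def community_weighted_means(
    sample: pd.Series | dict[str, float], table: TraitTable
) -> pd.Series:
    """Abundance-weighted mean affinity per modality.

    Taxa absent from the table (or with missing traits) are excluded and
    their abundance mass logged; relative abundances are renormalized over
    the covered taxa. Returns NaN-filled series if nothing is covered.
    """
    s = pd.Series(sample, dtype=float)
    s = s[s > 0]
    covered = s.index.intersection(table.complete_taxa())
    lost = float(s.sum() - s[covered].sum())
    if lost > 0:
        logger.info("CWM: %.3g abundance mass from taxa without trait coverage excluded", lost)
    if len(covered) == 0:
        return pd.Series(np.nan, index=table.affinities.columns)
    w = s[covered] / s[covered].sum()
    aff = table.affinities.loc[covered]
    return aff.mul(w, axis=0).sum(axis=0)
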