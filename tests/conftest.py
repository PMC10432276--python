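import numpy as np
import pandas as pd
import pytest

from freshtrend.traits import TraitTable, normalize_fuzzy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_community_frame(rows):
    """rows: (site, study, country, date, taxon, level, abundance) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["site_id", "study_id", "country", "date", "taxon_id", "taxon_level", "abundance"],
    )
    df["date"] = pd.to_datetime(df["date"])
    df["abundance"] = df["abundance"].astype(float)
    return df


@pytest.fixture
def toy_table(tmp_path):
    """3-row toy community CSV on disk."""
    p = tmp_path / "toy.csv"
    p.write_text(
        "site_id,study_id,country,date,taxon_id,taxon_level,abundance\n"
        "s1,st1,DE,2001-05-02,Baetis rhodani,species,12\n"
        "s1,st1,DE,2001-05-02,Gammarus pulex,species,5\n"
        "s1,st1,DE,2002-05-11,Baetis rhodani,species,9\n"
    )
    return p


def random_fuzzy_table(rng, n_taxa=8, modality_counts=(3, 4, 2)) -> TraitTable:
    cols = pd.MultiIndex.from_tuples(
        [(f"tr{k}", f"m{j}") for k, m in enumerate(modality_counts) for j in range(m)],
        names=["trait", "modality"],
    )
    raw = pd.DataFrame(
        rng.random((n_taxa, sum(modality_counts))),
        index=pd.Index([f"sp{i}" for i in range(n_taxa)], name="taxon"),
        columns=cols,
    )
    return normalize_fuzzy(raw)
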