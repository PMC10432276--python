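"""Per-site, per-year taxonomic diversity metrics.

All functions take a "sample": a mapping (or pandas Series) of taxon id to
abundance for one site-year. Shannon quantities use natural logarithms;
evenness is base-invariant. Rarefied richness is the individual-based
hypergeometric expectation. Temporal turnover compares consecutive
*sampled* years (gaps allowed) and is attributed to the later year.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "richness_abundance",
    "shannon",
    "rarefied_richness",
    "temporal_turnover",
    "compute_metric_series",
]


def _counts(sample: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(sample, dtype=float)
    if (s < 0).any():
        raise ValueError("negative abundance")
    return s[s > 0]


def richness_abundance(sample: Mapping[str, float]) -> tuple[int, float]:
    """Taxon count (abundance > 0) and total individual count."""
    s = _counts(sample)
    return int(len(s)), float(s.sum())


def shannon(sample: Mapping[str, float]) -> tuple[float, float]:
    """Shannon diversity H (nats) and evenness J = H / ln S.

    J is undefined (NaN) for single-taxon samples.
    """
    s = _counts(sample)
    if len(s) == 0:
        return 0.0, float("nan")
    p = s.to_numpy() / s.sum()
    h = float(-(p * np.log(p)).sum())
    j = h / math.log(len(s)) if len(s) > 1 else float("nan")
    return h, j


def _lncomb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(sample: Mapping[str, float], n_ref: int) -> float:
    """Expected taxon count in a random subsample of ``n_ref`` individuals.

    E[S] = sum_i [1 - C(N - N_i, n_ref) / C(N, n_ref)] (hypergeometric).
    """
    s = _counts(sample)
    counts = np.round(s.to_numpy()).astype(int)
    n = int(counts.sum())
    if n_ref > n:
        raise ValueError(f"n_ref={n_ref} exceeds total individuals N={n}")
    if n_ref < 0:
        raise ValueError("n_ref must be non-negative")
    rest = n - counts
    with np.errstate(invalid="ignore"):
        ln_ratio = np.where(rest >= n_ref, _lncomb(rest, n_ref) - _lncomb(n, n_ref), -np.inf)
    return float(np.sum(1.0 - np.exp(ln_ratio)))


def temporal_turnover(
    communities: Mapping[int, Iterable[str]],
) -> pd.Series:
    """Turnover between consecutive sampled years.

    ``communities`` maps year to the taxa present that year. For each
    consecutive pair of sampled years the value is
    (gained + lost) / pooled richness, in [0, 1], indexed by the later year.
    """
    years = sorted(communities)
    out: dict[int, float] = {}
    for y0, y1 in zip(years, years[1:]):
        a, b = set(communities[y0]), set(communities[y1])
        pooled = len(a | b)
        if pooled == 0:
            out[y1] = float("nan")
        else:
            out[y1] = (len(b - a) + len(a - b)) / pooled
    return pd.Series(out, dtype=float)


def compute_metric_series(site_year_counts: pd.DataFrame) -> pd.DataFrame:
    """All taxonomic metrics for one site.

    Input: long frame with columns ``year, taxon_id, abundance`` (one site).
    Output: tidy frame ``metric, year, value``. The rarefaction reference
    is the minimum annual individual total across the series' years.
    """
    grouped = {
        int(y): g.groupby("taxon_id")["abundance"].sum()
        for y, g in site_year_counts.groupby("year")
    }
    totals = {y: s.sum() for y, s in grouped.items()}
    n_ref = int(round(min(totals.values()))) if totals else 0

    rows: list[tuple[str, int, float]] = []
    for y, s in grouped.items():
        rich, ab = richness_abundance(s)
        h, j = shannon(s)
        rows.append(("abundance", y, ab))
        rows.append(("richness", y, float(rich)))
        rows.append(("shannon", y, h))
        rows.append(("evenness", y, j))
        rows.append(("rarefied_richness", y, rarefied_richness(s, n_ref)))

    tos = temporal_turnover({y: s.index[s > 0] for y, s in grouped.items()})
    for y, v in tos.items():
        rows.append(("turnover", int(y), float(v)))

    out = pd.DataFrame(rows, columns=["metric", "year", "value"])
    return out.sort_values(["metric", "year"]).reset_index(drop=True)
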