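"""Distance-based functional diversity metrics.

Trait distances come in two flavours: ``gower_fuzzy`` (mean over traits of
half the L1 distance between fuzzy profiles, in [0, 1]) and
``euclidean_scaled`` (Euclidean over all modalities, rescaled by the
maximum to [0, 1]; used for redundancy). A principal-coordinates
ordination of the distance matrix (first six positive axes by default)
underlies convex-hull richness, evenness and divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .traits import TraitTable

logger = logging.getLogger(__name__)

RAO_TOLERANCE = 1e-8  # Simpson diversity below this -> uniqueness undefined
NEG_EIG_TOL = 1e-8


@dataclass
class TraitSpace:
    """PCoA embedding of the taxon trait-distance matrix."""

    taxa: pd.Index
    coordinates: np.ndarray  # (n_taxa, n_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    correction: str  # none | sqrt | cailliez; "" if not needed
    degenerate: bool = False

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def coords_for(self, taxa: list[str]) -> np.ndarray:
        idx = self.taxa.get_indexer(taxa)
        if (idx < 0).any():
            missing = [t for t, i in zip(taxa, idx) if i < 0]
            raise KeyError(f"taxa not in trait space: {missing}")
        return self.coordinates[idx]


@dataclass
class FunctionalSummary:
    fric: float
    feve: float
    fdiv: float
    rao_q: float
    simpson: float
    uniqueness: float
    redundancy: float
    flags: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# distances


def trait_distance(table: TraitTable, metric: str = "gower_fuzzy") -> tuple[pd.Index, np.ndarray]:
    """Pairwise trait distances among taxa with complete trait data.

    Taxa with any missing trait block are excluded (and logged).
    """
    taxa = table.complete_taxa()
    dropped = table.taxa.difference(taxa)
    if len(dropped):
        logger.info("trait_distance: excluding %d taxa with missing traits", len(dropped))
    aff = table.affinities.loc[taxa]
    if metric == "gower_fuzzy":
        parts = []
        for tr in table.traits:
            block = aff[tr].to_numpy()
            parts.append(0.5 * squareform(pdist(block, metric="cityblock")))
        dist = np.mean(parts, axis=0)
    elif metric == "euclidean_scaled":
        dist = squareform(pdist(aff.to_numpy(), metric="euclidean"))
        mx = dist.max()
        if mx > 0:
            dist = dist / mx
    else:
        raise ValueError(f"unknown distance metric '{metric}'")
    np.fill_diagonal(dist, 0.0)
    return taxa, dist


# --------------------------------------------------------------------------
# ordination


def _double_centre(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest c such that d + c (off-diagonal) is Euclidean-embeddable."""
    n = d.shape[0]
    b1 = _double_centre(d**2)
    b2 = _double_centre(d)
    zero = np.zeros((n, n))
    eye = np.eye(n)
    top = np.hstack([zero, 2.0 * b1])
    bot = np.hstack([-eye, -4.0 * b2])
    eig = np.linalg.eigvals(np.vstack([top, bot]))
    return float(np.max(eig.real))


def pcoa(
    dist: np.ndarray,
    taxa: pd.Index | None = None,
    n_axes: int = 6,
    correction: str = "sqrt",
) -> TraitSpace:
    """Principal coordinates of a distance matrix.

    Negative eigenvalues beyond tolerance trigger the configured
    correction (``sqrt`` transforms distances, ``cailliez`` adds the
    minimal additive constant, ``none`` keeps positive axes only). The
    first ``n_axes`` positive axes (or as many as exist) are retained.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if taxa is None:
        taxa = pd.Index([f"t{i}" for i in range(n)])
    if n < 2:
        return TraitSpace(taxa, np.zeros((n, 1)), np.zeros(1), "", degenerate=True)

    applied = ""
    for _ in range(2):
        b = _double_centre(d**2)
        eigval, eigvec = np.linalg.eigh(b)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        if applied or correction == "none" or eigval[-1] >= -NEG_EIG_TOL * max(1.0, eigval[0]):
            break
        if correction == "sqrt":
            d = np.sqrt(d)
        elif correction == "cailliez":
            c = _cailliez_constant(d)
            d = d + c
            np.fill_diagonal(d, 0.0)
        else:
            raise ValueError(f"unknown correction '{correction}'")
        applied = correction

    pos = eigval > NEG_EIG_TOL * max(1.0, abs(eigval[0]))
    k = min(n_axes, int(pos.sum()))
    if k == 0:
        return TraitSpace(taxa, np.zeros((n, 1)), eigval, applied, degenerate=True)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    return TraitSpace(taxa, coords, eigval, applied)


# --------------------------------------------------------------------------
# hull-based metrics


def _present(sample: pd.Series | dict) -> pd.Series:
    s = pd.Series(sample, dtype=float)
    return s[s > 0]


def _hull(points: np.ndarray) -> ConvexHull | None:
    """Convex hull with dimensionality fallback for degenerate point sets."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    d = min(pts.shape[1], n - 1)
    while d >= 1:
        sub = pts[:, :d] if pts.shape[1] > d else pts
        # project onto principal axes when points are affinely degenerate
        try:
            return ConvexHull(sub)
        except (QhullError, ValueError):
            centred = sub - sub.mean(axis=0)
            u, s, vt = np.linalg.svd(centred, full_matrices=False)
            rank = int((s > 1e-10 * max(1.0, s[0] if len(s) else 1.0)).sum())
            if rank < 1:
                return None
            if rank < sub.shape[1]:
                pts = centred @ vt[:rank].T
                d = rank
                continue
            d -= 1
    return None


def functional_richness(space: TraitSpace, sample: pd.Series | dict) -> tuple[float, tuple[str, ...]]:
    """Convex-hull volume of the present taxa in ordination space.

    With fewer than ``n_axes + 1`` taxa the hull dimensionality is reduced
    to S - 1 axes (flagged); fully collinear communities return 0.
    """
    s = _present(sample)
    flags: list[str] = []
    pts = space.coords_for(list(s.index))
    if len(s) < 2:
        return 0.0, ("degenerate",)
    d = min(space.n_axes, len(s) - 1)
    if d < space.n_axes:
        flags.append(f"axes_reduced_to_{d}")
    hull = _hull(pts[:, :d])
    if hull is None:
        return 0.0, tuple(flags + ["degenerate"])
    return float(hull.volume), tuple(flags)


def functional_evenness(space: TraitSpace, sample: pd.Series | dict) -> float:
    """Minimum-spanning-tree regularity of taxa in trait space.

    FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1)), where
    PEW_l is the partial weighted evenness of MST branch l:
    EW_l = length_l / (p_i + p_j), normalized to sum 1. NaN for S < 3.
    """
    s = _present(sample)
    S = len(s)
    if S < 3:
        return float("nan")
    p = (s / s.sum()).to_numpy()
    pts = space.coords_for(list(s.index))
    dmat = squareform(pdist(pts))
    mst = minimum_spanning_tree(dmat).tocoo()
    ew = np.array([d / (p[i] + p[j]) for i, j, d in zip(mst.row, mst.col, mst.data)])
    if ew.sum() == 0:
        return float("nan")
    pew = ew / ew.sum()
    thr = 1.0 / (S - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def functional_divergence(space: TraitSpace, sample: pd.Series | dict) -> float:
    """Abundance-weighted divergence from the hull-vertex centroid, in [0, 1].

    FDiv = (Delta_d + mean_dG) / (Delta_|d| + mean_dG) with dG the distance
    of each taxon to the centroid of the convex-hull vertices.
    """
    s = _present(sample)
    if len(s) < 3:
        return float("nan")
    p = (s / s.sum()).to_numpy()
    d_axes = min(space.n_axes, len(s) - 1)
    pts = space.coords_for(list(s.index))[:, :d_axes]
    hull = _hull(pts)
    if hull is None:
        return float("nan")
    centroid = pts[np.unique(hull.vertices)].mean(axis=0) if pts.shape[1] > 1 else pts.mean(axis=0)
    dg = np.linalg.norm(pts - centroid, axis=1)
    mean_dg = dg.mean()
    dev = dg - mean_dg
    delta_d = float((p * dev).sum())
    delta_abs = float((p * np.abs(dev)).sum())
    denom = delta_abs + mean_dg
    if denom <= 0:
        return float("nan")
    return (delta_d + mean_dg) / denom


# --------------------------------------------------------------------------
# Rao / redundancy


def rao_simpson_redundancy(
    dist: np.ndarray,
    taxa: pd.Index,
    sample: pd.Series | dict,
    tolerance: float = RAO_TOLERANCE,
) -> tuple[float, float, float, float]:
    """Rao's Q, Gini–Simpson D, uniqueness U = Q/D and redundancy 1 - U.

    Distances are expected in [0, 1], which bounds U and redundancy in
    [0, 1]. Monocultures (D <= tolerance) yield NaN uniqueness/redundancy.
    """
    s = _present(sample)
    idx = taxa.get_indexer(s.index)
    if (idx < 0).any():
        missing = [t for t, i in zip(s.index, idx) if i < 0]
        raise KeyError(f"taxa without distances: {missing}")
    p = (s / s.sum()).to_numpy()
    d = dist[np.ix_(idx, idx)]
    q = float(p @ d @ p)
    simpson = float(1.0 - (p**2).sum())
    if simpson <= tolerance:
        return q, simpson, float("nan"), float("nan")
    u = q / simpson
    return q, simpson, u, 1.0 - u


# --------------------------------------------------------------------------
# CWM turnover


def functional_turnover(
    cwm_by_year: Mapping[int, pd.Series], presence_threshold: float = 0.0
) -> pd.Series:
    """Turnover of CWM modality presence between consecutive sampled years.

    A modality counts as present when its CWM affinity exceeds
    ``presence_threshold`` (default: strictly positive). The value for a
    year pair is (gained + lost) / pooled present modalities, attributed
    to the later year, bounded in [0, 1].
    """
    years = sorted(cwm_by_year)
    out: dict[int, float] = {}
    for y0, y1 in zip(years, years[1:]):
        a = set(cwm_by_year[y0].index[cwm_by_year[y0] > presence_threshold])
        b = set(cwm_by_year[y1].index[cwm_by_year[y1] > presence_threshold])
        pooled = len(a | b)
        out[y1] = float("nan") if pooled == 0 else (len(a - b) + len(b - a)) / pooled
    return pd.Series(out, dtype=float)


# --------------------------------------------------------------------------
# orchestration


class FunctionalCalculator:
    """Precomputed trait space shared across all site-year communities.

    Redundancy uses scaled Euclidean distances; the hull/MST metrics use
    the configurable default distance (Gower-style fuzzy distance).
    """

    def __init__(
        self,
        trait_table: TraitTable,
        hull_metric: str = "gower_fuzzy",
        n_axes: int = 6,
        correction: str = "sqrt",
    ):
        self.table = trait_table
        self.taxa, self.dist_hull = trait_distance(trait_table, hull_metric)
        _, self.dist_redundancy = trait_distance(trait_table, "euclidean_scaled")
        self.space = pcoa(self.dist_hull, self.taxa, n_axes=n_axes, correction=correction)

    def _covered(self, sample: pd.Series | dict) -> pd.Series:
        s = _present(sample)
        return s[s.index.isin(self.taxa)]

    def summary(self, sample: pd.Series | dict) -> FunctionalSummary:
        s = self._covered(sample)
        flags: list[str] = []
        if len(s) == 0:
            nan = float("nan")
            return FunctionalSummary(nan, nan, nan, nan, nan, nan, nan, ("no_covered_taxa",))
        fric, fric_flags = functional_richness(self.space, s)
        flags.extend(fric_flags)
        feve = functional_evenness(self.space, s)
        fdiv = functional_divergence(self.space, s)
        q, simpson, u, red = rao_simpson_redundancy(self.dist_redundancy, self.taxa, s)
        return FunctionalSummary(fric, feve, fdiv, q, simpson, u, red, tuple(flags))

    def metric_series(self, site_year_counts: pd.DataFrame) -> pd.DataFrame:
        """Tidy (metric, year, value) frame of functional metrics for one site."""
        from .traits import community_weighted_means

        rows: list[tuple[str, int, float]] = []
        cwms: dict[int, pd.Series] = {}
        for y, g in site_year_counts.groupby("year"):
            counts = g.groupby("taxon_id")["abundance"].sum()
            fs = self.summary(counts)
            y = int(y)
            rows += [
                ("FRic", y, fs.fric),
                ("FEve", y, fs.feve),
                ("FDiv", y, fs.fdiv),
                ("RaoQ", y, fs.rao_q),
                ("redundancy", y, fs.redundancy),
            ]
            cwms[y] = community_weighted_means(counts, self.table).dropna()
        for y, v in functional_turnover(cwms).items():
            rows.append(("functional_turnover", int(y), float(v)))
        out = pd.DataFrame(rows, columns=["metric", "year", "value"])
        return out.sort_values(["metric", "year"]).reset_index(drop=True)
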