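import itertools

import numpy as np
import pandas as pd
import pytest

from freshtrend.functional import (
    FunctionalCalculator,
    TraitSpace,
    functional_divergence,
    functional_evenness,
    functional_richness,
    functional_turnover,
    pcoa,
    rao_simpson_redundancy,
    trait_distance,
)
from freshtrend.traits import normalize_fuzzy
from conftest import random_fuzzy_table
from test_traits import make_raw


def space_from_points(points):
    pts = np.asarray(points, float)
    return TraitSpace(
        taxa=pd.Index([f"t{i}" for i in range(len(pts))]),
        coordinates=pts,
        eigenvalues=np.ones(pts.shape[1]),
        correction="",
    )


class TestTraitDistance:
    def test_identical_profiles_zero(self):
        t = normalize_fuzzy(make_raw([[1, 1], [1, 1]], ["a", "b"], (2,)))
        _, d = trait_distance(t)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_profiles_one(self):
        t = normalize_fuzzy(make_raw([[1, 0], [0, 1]], ["a", "b"], (2,)))
        _, d = trait_distance(t, "gower_fuzzy")
        assert d[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_gower_against_double_loop(self, rng):
        t = random_fuzzy_table(rng, n_taxa=7, modality_counts=(3, 4, 2))
        taxa, d = trait_distance(t, "gower_fuzzy")
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                acc = 0.0
                for tr in t.traits:
                    pa = t.affinities.loc[a, tr].to_numpy()
                    pb = t.affinities.loc[b, tr].to_numpy()
                    acc += 0.5 * np.abs(pa - pb).sum()
                assert d[i, j] == pytest.approx(acc / len(t.traits), abs=1e-9)

    def test_euclidean_scaled_bounds(self, rng):
        t = random_fuzzy_table(rng, n_taxa=9)
        _, d = trait_distance(t, "euclidean_scaled")
        assert d.max() <= 1.0 + 1e-12 and d.min() >= 0.0
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_missing_taxa_excluded(self, rng):
        t = random_fuzzy_table(rng, n_taxa=4)
        t.affinities.loc["sp0", "tr0"] = np.nan
        taxa, d = trait_distance(t)
        assert "sp0" not in taxa


class TestPcoa:
    def test_euclidean_embedding_recovered(self, rng):
        pts = rng.normal(size=(5, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        space = pcoa(d, n_axes=4, correction="none")
        d2 = squareform(pdist(space.coordinates))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    @pytest.mark.parametrize("correction", ["sqrt", "cailliez"])
    def test_non_euclidean_corrected(self, correction):
        # triangle-inequality violation: d(0,2) > d(0,1)+d(1,2)
        d = np.array([
            [0.0, 0.1, 1.0, 0.4],
            [0.1, 0.0, 0.1, 0.4],
            [1.0, 0.1, 0.0, 0.4],
            [0.4, 0.4, 0.4, 0.0],
        ])
        space = pcoa(d, n_axes=3, correction=correction)
        assert space.correction == correction
        kept = space.eigenvalues[: space.n_axes]
        assert (kept >= 0).all()

    def test_permutation_invariant_eigenvalues(self, rng):
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        perm = rng.permutation(6)
        e1 = pcoa(d, correction="none").eigenvalues
        e2 = pcoa(d[np.ix_(perm, perm)], correction="none").eigenvalues
        np.testing.assert_allclose(np.sort(e1), np.sort(e2), atol=1e-8)

    def test_degenerate_single_taxon(self):
        space = pcoa(np.zeros((1, 1)))
        assert space.degenerate


class TestFunctionalRichness:
    def test_triangle_area(self):
        space = space_from_points([[0, 0], [1, 0], [0, 1]])
        vol, flags = functional_richness(space, {"t0": 1, "t1": 1, "t2": 1})
        assert vol == pytest.approx(0.5, abs=1e-12)

    def test_interior_point_no_change(self):
        space = space_from_points([[0, 0], [1, 0], [0, 1], [0.2, 0.2]])
        v1, _ = functional_richness(space, {"t0": 1, "t1": 1, "t2": 1})
        v2, _ = functional_richness(space, {"t0": 1, "t1": 1, "t2": 1, "t3": 1})
        assert v2 == pytest.approx(v1, abs=1e-12)

    def test_collinear_returns_zero_flagged(self):
        space = space_from_points([[0, 0], [1, 1], [2, 2]])
        vol, flags = functional_richness(space, {"t0": 1, "t1": 1, "t2": 1})
        assert vol == 0.0 or vol == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_oracle(self, rng):
        pts = rng.random((8, 2))
        space = space_from_points(pts)
        vol, _ = functional_richness(space, {f"t{i}": 1 for i in range(8)})
        # rejection sampling in the bounding box
        from scipy.spatial import Delaunay

        tri = Delaunay(pts)
        box_lo, box_hi = pts.min(axis=0), pts.max(axis=0)
        draws = rng.random((200_000, 2)) * (box_hi - box_lo) + box_lo
        frac = (tri.find_simplex(draws) >= 0).mean()
        mc_vol = frac * np.prod(box_hi - box_lo)
        assert vol == pytest.approx(mc_vol, rel=0.02)

    def test_monotone_under_union(self, rng):
        pts = rng.normal(size=(10, 2))
        space = space_from_points(pts)
        a = {f"t{i}": 1 for i in range(5)}
        b = {f"t{i}": 1 for i in range(4, 10)}
        va, _ = functional_richness(space, a)
        vb, _ = functional_richness(space, b)
        vu, _ = functional_richness(space, {**a, **b})
        assert vu >= max(va, vb) - 1e-12


def brute_force_feve(points, abundances):
    """Independent FEve: exhaustive minimum spanning tree for n <= 6."""
    n = len(points)
    p = np.asarray(abundances, float)
    p = p / p.sum()
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    edges = list(itertools.combinations(range(n), 2))
    best = None
    for subset in itertools.combinations(edges, n - 1):
        # check spanning tree via union-find
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if not ok:
            continue
        w = sum(d[i, j] for i, j in subset)
        if best is None or w < best[0]:
            best = (w, subset)
    _, tree = best
    ew = np.array([d[i, j] / (p[i] + p[j]) for i, j in tree])
    pew = ew / ew.sum()
    thr = 1.0 / (n - 1)
    return (np.minimum(pew, thr).sum() - thr) / (1 - thr)


class TestFunctionalEvenness:
    def test_equidistant_line_equal_abundance(self):
        space = space_from_points([[0, 0], [1, 0], [2, 0], [3, 0]])
        feve = functional_evenness(space, {f"t{i}": 2 for i in range(4)})
        assert feve == pytest.approx(1.0, abs=1e-12)

    def test_clumped_abundance_below_one(self):
        space = space_from_points([[0, 0], [1, 0], [2, 0], [3, 0]])
        feve = functional_evenness(space, {"t0": 100, "t1": 1, "t2": 1, "t3": 1})
        assert feve < 1.0

    def test_fewer_than_three_taxa_missing(self):
        space = space_from_points([[0, 0], [1, 0]])
        assert np.isnan(functional_evenness(space, {"t0": 1, "t1": 1}))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_brute_force_mst(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        pts = rng.random((n, 2))
        ab = rng.integers(1, 10, n).astype(float)
        space = space_from_points(pts)
        feve = functional_evenness(space, {f"t{i}": ab[i] for i in range(n)})
        assert feve == pytest.approx(brute_force_feve(pts, ab), abs=1e-9)


class TestRaoRedundancy:
    def test_two_maximally_distinct_species(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        q, simpson, u, red = rao_simpson_redundancy(d, pd.Index(["a", "b"]), {"a": 1, "b": 1})
        assert q == pytest.approx(0.5)
        assert simpson == pytest.approx(0.5)
        assert red == pytest.approx(0.0, abs=1e-12)

    def test_identical_species_full_redundancy(self):
        d = np.zeros((3, 3))
        q, simpson, u, red = rao_simpson_redundancy(
            d, pd.Index(["a", "b", "c"]), {"a": 1, "b": 2, "c": 3}
        )
        assert q == 0.0
        assert red == pytest.approx(1.0)

    def test_monoculture_undefined(self):
        d = np.zeros((2, 2))
        q, simpson, u, red = rao_simpson_redundancy(d, pd.Index(["a", "b"]), {"a": 5})
        assert np.isnan(u) and np.isnan(red)

    def test_against_brute_force_double_sum(self, rng):
        n = 5
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        d = d / d.max()
        ab = rng.integers(1, 20, n).astype(float)
        p = ab / ab.sum()
        q_bf = sum(d[i, j] * p[i] * p[j] for i in range(n) for j in range(n))
        taxa = pd.Index([f"t{i}" for i in range(n)])
        q, simpson, u, red = rao_simpson_redundancy(d, taxa, dict(zip(taxa, ab)))
        assert q == pytest.approx(q_bf, abs=1e-9)
        assert simpson == pytest.approx(1 - (p**2).sum(), abs=1e-12)

    def test_q_bounded_by_simpson_random(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            d = np.clip(d, 0, 1)
            ab = rng.integers(1, 30, n).astype(float)
            taxa = pd.Index([f"t{i}" for i in range(n)])
            q, simpson, u, red = rao_simpson_redundancy(d, taxa, dict(zip(taxa, ab)))
            assert q <= simpson + 1e-12
            assert -1e-12 <= red <= 1 + 1e-12

    def test_equal_abundance_constant_distance_closed_form(self):
        # Q = (1 - 1/S) * d when all pairwise distances equal d
        S, dval = 5, 0.6
        d = np.full((S, S), dval)
        np.fill_diagonal(d, 0)
        taxa = pd.Index([f"t{i}" for i in range(S)])
        q, *_ = rao_simpson_redundancy(d, taxa, {t: 1 for t in taxa})
        assert q == pytest.approx((1 - 1 / S) * dval, abs=1e-12)

    def test_rescaling_invariance(self, rng):
        n = 6
        d = rng.random((n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        taxa = pd.Index([f"t{i}" for i in range(n)])
        ab = rng.integers(1, 9, n).astype(float)
        r1 = rao_simpson_redundancy(d, taxa, dict(zip(taxa, ab)))
        r2 = rao_simpson_redundancy(d, taxa, dict(zip(taxa, ab * 7.5)))
        np.testing.assert_allclose(r1, r2, atol=1e-12)


class TestFunctionalDivergence:
    def test_fixed_four_point_fixture(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        ab = np.array([1.0, 2.0, 3.0, 4.0])
        space = space_from_points(pts)
        # independent computation of the standard formula
        centroid = pts.mean(axis=0)  # all four points are hull vertices
        dg = np.linalg.norm(pts - centroid, axis=1)
        p = ab / ab.sum()
        dev = dg - dg.mean()
        expected = ((p * dev).sum() + dg.mean()) / ((p * np.abs(dev)).sum() + dg.mean())
        fdiv = functional_divergence(space, {f"t{i}": ab[i] for i in range(4)})
        assert fdiv == pytest.approx(expected, abs=1e-9)

    def test_extreme_vertex_concentration_raises_fdiv(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [0.34, 0.33]])
        space = space_from_points(pts)
        conc_vertices = functional_divergence(space, {"t0": 50, "t1": 50, "t2": 50, "t3": 1})
        conc_centre = functional_divergence(space, {"t0": 1, "t1": 1, "t2": 1, "t3": 50})
        assert conc_vertices > conc_centre
        assert 0 <= conc_vertices <= 1

    def test_label_permutation_invariance(self, rng):
        pts = rng.random((5, 2))
        ab = rng.integers(1, 9, 5).astype(float)
        space = space_from_points(pts)
        f1 = functional_divergence(space, {f"t{i}": ab[i] for i in range(5)})
        perm = rng.permutation(5)
        space2 = TraitSpace(
            taxa=pd.Index([f"t{i}" for i in perm]), coordinates=pts[perm],
            eigenvalues=np.ones(2), correction="",
        )
        f2 = functional_divergence(space2, {f"t{i}": ab[i] for i in range(5)})
        assert f1 == pytest.approx(f2, abs=1e-12)


class TestFunctionalTurnover:
    def test_identical_cwms_zero(self):
        cwm = pd.Series([0.5, 0.5], index=["m1", "m2"])
        out = functional_turnover({2000: cwm, 2001: cwm.copy()})
        assert out[2001] == 0.0

    def test_disjoint_dominant_modalities_one(self):
        a = pd.Series([1.0, 0.0], index=["m1", "m2"])
        b = pd.Series([0.0, 1.0], index=["m1", "m2"])
        out = functional_turnover({2000: a, 2001: b})
        assert out[2001] == 1.0

    def test_three_year_toy_hand_computed(self):
        y1 = pd.Series([0.5, 0.5, 0.0], index=["m1", "m2", "m3"])
        y2 = pd.Series([0.5, 0.0, 0.5], index=["m1", "m2", "m3"])
        y3 = pd.Series([0.0, 0.0, 1.0], index=["m1", "m2", "m3"])
        out = functional_turnover({2000: y1, 2002: y2, 2005: y3})
        # 2000->2002: lose m2, gain m3, pooled {m1,m2,m3} -> 2/3
        assert out[2002] == pytest.approx(2 / 3)
        # 2002->2005: lose m1, pooled {m1,m3} -> 1/2
        assert out[2005] == pytest.approx(0.5)


class TestCalculator:
    def test_end_to_end_summary(self, rng):
        t = random_fuzzy_table(rng, n_taxa=10, modality_counts=(3, 4, 2))
        calc = FunctionalCalculator(t)
        sample = {f"sp{i}": float(rng.integers(1, 20)) for i in range(10)}
        fs = calc.summary(sample)
        assert fs.fric >= 0
        assert 0 <= fs.feve <= 1
        assert 0 <= fs.redundancy <= 1
        assert fs.rao_q <= fs.simpson + 1e-12

    def test_metric_series_tidy(self, rng):
        t = random_fuzzy_table(rng, n_taxa=8)
        calc = FunctionalCalculator(t)
        df = pd.DataFrame({
            "year": [2000] * 4 + [2001] * 4,
            "taxon_id": [f"sp{i}" for i in [0, 1, 2, 3, 2, 3, 4, 5]],
            "abundance": rng.integers(1, 9, 8).astype(float),
        })
        out = calc.metric_series(df)
        assert set(out["metric"]) == {
            "FRic", "FEve", "FDiv", "RaoQ", "redundancy", "functional_turnover",
        }
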