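import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from freshtrend.meta import (
    fit_meta,
    jackknife_by_country,
    probability_of_direction,
    sensitivity_fixed_factor,
)


def make_trends(slopes, ses, studies=None, countries=None):
    n = len(slopes)
    return pd.DataFrame({
        "site_id": [f"s{i}" for i in range(n)],
        "slope": slopes,
        "se": ses,
        "study_id": studies if studies is not None else [f"st{i % 4}" for i in range(n)],
        "country": countries if countries is not None else [f"c{i % 2}" for i in range(n)],
    })


class TestFitMeta:
    def test_unanimous_trends(self):
        tr = make_trends([0.5] * 12, [1e-4] * 12)
        res = fit_meta(tr, weighted=True)
        assert res.mean == pytest.approx(0.5, abs=1e-3)
        assert res.prob_positive > 0.999

    def test_symmetric_trends_centre_zero(self):
        slopes = [0.5, -0.5] * 6
        tr = make_trends(slopes, [0.1] * 12,
                         studies=[f"st{i % 3}" for i in range(12)])
        res = fit_meta(tr, weighted=True)
        assert res.mean == pytest.approx(0.0, abs=0.05)
        assert 0.3 < res.prob_positive < 0.7

    def test_intervals_nested(self, rng):
        tr = make_trends(rng.normal(0.2, 0.1, 30), np.full(30, 0.05))
        res = fit_meta(tr, weighted=True)
        i80, i90, i95 = (res.intervals[lv] for lv in (0.80, 0.90, 0.95))
        assert i95[0] <= i90[0] <= i80[0] <= i80[1] <= i90[1] <= i95[1]

    def test_single_study_degrades_with_warning(self, rng):
        tr = make_trends(rng.normal(0.1, 0.05, 8), np.full(8, 0.05),
                         studies=["only"] * 8, countries=["c0"] * 8)
        with pytest.warns(UserWarning, match="single study"):
            res = fit_meta(tr, weighted=True)
        assert np.isfinite(res.mean)

    def test_huge_se_site_has_no_influence(self, rng):
        tr = make_trends(rng.normal(0.2, 0.1, 20), np.full(20, 0.05))
        extra = pd.DataFrame({
            "site_id": ["ghost"], "slope": [50.0], "se": [1e6],
            "study_id": ["st0"], "country": ["c0"],
        })
        res1 = fit_meta(tr, weighted=True)
        res2 = fit_meta(pd.concat([tr, extra], ignore_index=True), weighted=True)
        assert res2.mean == pytest.approx(res1.mean, abs=1e-6)

    def test_weighted_equal_se_reduces_to_classical_re(self, rng):
        """Single grouping + equal se must match a 1-D REML oracle."""
        n = 40
        slopes = rng.normal(0.3, 0.2, n)
        se = 0.1
        tr = make_trends(slopes, np.full(n, se),
                         studies=[f"st{i}" for i in range(n)], countries=["c0"] * n)

        def neg_reml_1d(log_tau2):
            v = np.exp(log_tau2) + se**2
            w = np.full(n, 1.0 / v)
            mu = np.sum(w * slopes) / np.sum(w)
            return 0.5 * (n * np.log(v) + np.log(np.sum(w))
                          + np.sum((slopes - mu) ** 2) / v)

        res = optimize.minimize_scalar(neg_reml_1d, bounds=(-20, 5), method="bounded")
        v = np.exp(res.x) + se**2
        w = np.full(n, 1.0 / v)
        mu_oracle = np.sum(w * slopes) / np.sum(w)
        se_oracle = np.sqrt(1.0 / np.sum(w))

        out = fit_meta(tr, weighted=True)
        assert out.mean == pytest.approx(mu_oracle, abs=1e-4)
        assert out.se == pytest.approx(se_oracle, rel=1e-2)

    def test_unweighted_estimates_residual_variance(self, rng):
        tr = make_trends(rng.normal(0.0, 0.3, 40), np.full(40, np.nan),
                         studies=[f"st{i % 5}" for i in range(40)])
        res = fit_meta(tr.drop(columns="se"), weighted=False)
        assert res.sigma2_resid > 0

    def test_weighted_requires_se(self):
        tr = make_trends([0.1, 0.2, 0.3], [np.nan, 0.1, 0.1])
        with pytest.raises(ValueError, match="se"):
            fit_meta(tr, weighted=True)


class TestProbabilityOfDirection:
    def test_gaussian_quantile(self):
        sigma = 0.3
        assert probability_of_direction((1.645 * sigma, sigma)) == pytest.approx(0.95, abs=1e-3)

    def test_mean_zero(self):
        assert probability_of_direction((0.0, 1.0)) == pytest.approx(0.5)

    def test_draws_match_analytic(self, rng):
        mean, sd = 0.4, 0.6
        draws = rng.normal(mean, sd, 200_000)
        analytic = probability_of_direction((mean, sd))
        assert probability_of_direction(draws) == pytest.approx(analytic, abs=0.01)


class TestJackknife:
    def _trends(self, rng, n_countries=5, outlier=None):
        rows = []
        for c in range(n_countries):
            for s in range(4):
                slope = rng.normal(0.2, 0.05)
                if outlier is not None and c == outlier:
                    slope += 5.0
                rows.append({"site_id": f"s{c}_{s}", "slope": slope, "se": 0.05,
                             "study_id": f"st{c}_{s % 2}", "country": f"c{c}"})
        return pd.DataFrame(rows)

    def test_one_refit_per_country(self, rng):
        tr = self._trends(rng)
        out = jackknife_by_country(tr)
        assert len(out) == 5
        assert set(out) == set(tr["country"].unique())

    def test_outlier_removal_shifts_mean_down(self, rng):
        tr = self._trends(rng, outlier=2)
        full = fit_meta(tr, weighted=True)
        out = jackknife_by_country(tr)
        assert out["c2"].mean < full.mean

    def test_homogeneous_leave_one_out_stable(self, rng):
        tr = self._trends(rng)
        full = fit_meta(tr, weighted=True)
        for res in jackknife_by_country(tr).values():
            assert abs(res.mean - full.mean) < 4 * full.se

    def test_needs_three_countries(self, rng):
        tr = self._trends(rng, n_countries=2)
        with pytest.raises(ValueError):
            jackknife_by_country(tr)


class TestFixedFactor:
    def test_single_level_reduces_to_fit_meta(self, rng):
        tr = make_trends(rng.normal(0.3, 0.1, 20), np.full(20, 0.05))
        tr["season"] = "spring"
        out = sensitivity_fixed_factor(tr, "season")
        base = fit_meta(tr, weighted=True)
        assert len(out) == 1
        assert out["mean"].iloc[0] == pytest.approx(base.mean, abs=1e-3)

    def test_levels_with_identical_truth_overlap(self, rng):
        n = 60
        tr = make_trends(rng.normal(0.2, 0.05, n), np.full(n, 0.05),
                         studies=[f"st{i % 6}" for i in range(n)])
        tr["resolution"] = [["species", "mixed", "family"][i % 3] for i in range(n)]
        out = sensitivity_fixed_factor(tr, "resolution")
        base = fit_meta(tr, weighted=True)
        assert len(out) == 3
        for _, row in out.iterrows():
            gap_se = np.hypot(row["se"], base.se)
            assert abs(row["mean"] - base.mean) < 4 * gap_se

    def test_label_permutation_destroys_differences(self, rng):
        n = 40
        slopes = np.where(np.arange(n) % 2 == 0, 0.5, -0.5) + rng.normal(0, 0.02, n)
        tr = make_trends(slopes, np.full(n, 0.05),
                         studies=[f"st{i % 4}" for i in range(n)])
        tr["grp"] = np.where(np.arange(n) % 2 == 0, "hi", "lo")
        out = sensitivity_fixed_factor(tr, "grp")
        gap = abs(out["mean"].iloc[0] - out["mean"].iloc[1])
        tr2 = tr.copy()
        tr2["grp"] = rng.permutation(tr["grp"].to_numpy())
        out2 = sensitivity_fixed_factor(tr2, "grp")
        gap_perm = abs(out2["mean"].iloc[0] - out2["mean"].iloc[1])
        assert gap > 0.5
        assert gap_perm < gap / 3

    def test_underpopulated_level_dropped(self, rng):
        tr = make_trends(rng.normal(0, 0.1, 10), np.full(10, 0.05))
        tr["season"] = ["spring"] * 9 + ["winter"]
        out = sensitivity_fixed_factor(tr, "season")
        assert list(out["season"]) == ["spring"]


def test_simulated_hierarchy_recovery(rng):
    """Small-n spot check; the full recovery study runs in acceptance."""
    hits = 0
    n_rep = 10
    for rep in range(n_rep):
        r = np.random.default_rng(rep)
        rows = []
        for st in range(20):
            u = r.normal(0, 0.1)
            c = f"c{st % 5}"
            for k in range(5):
                rows.append({"site_id": f"s{st}_{k}",
                             "slope": 0.2 + u + r.normal(0, 0.05),
                             "se": 0.05, "study_id": f"st{st}", "country": c})
        res = fit_meta(pd.DataFrame(rows), weighted=True)
        lo, hi = res.intervals[0.95]
        hits += lo <= 0.2 <= hi
    assert hits >= 8
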