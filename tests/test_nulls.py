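import numpy as np
import pytest

from popspectrum.datasets import PopulationTimeSeries
from popspectrum.nulls import (
    dip_pvalue, dip_statistic, dip_test, duration_model, randomize_dataset,
    significance_rates, truncate_series,
)
from popspectrum.simulate import SimulationConfig, simulate_dataset


def _lp_branch_dip(left, right, n):
    """Minimal sup-distance for one modal split, by linear programming.

    ``left``/``right`` are lists of (x, reach, cap) triples: a nondecreasing
    piecewise-linear CDF branch (convex on the left of the mode, concave on
    the right, jump allowed at the junction) must pass within
    [reach/n - d, cap/n + d] at each x.  Returns the minimised d.
    """
    from scipy.optimize import linprog

    nL, nR = len(left), len(right)
    nv = nL + nR + 1
    c = np.zeros(nv)
    c[-1] = 1.0
    A, b = [], []

    def add(row, rhs):
        A.append(row)
        b.append(rhs)

    for pos, (_, reach, cap) in enumerate(left + right):
        r = np.zeros(nv); r[pos] = -1; r[-1] = -1; add(r, -reach / n)
        r = np.zeros(nv); r[pos] = 1; r[-1] = -1; add(r, cap / n)
    for i in range(nL - 1):
        r = np.zeros(nv); r[i] = 1; r[i + 1] = -1; add(r, 0)
    for j in range(nR - 1):
        r = np.zeros(nv); r[nL + j] = 1; r[nL + j + 1] = -1; add(r, 0)
    if nL and nR:
        r = np.zeros(nv); r[nL - 1] = 1; r[nL] = -1; add(r, 0)
    for i in range(nL - 2):  # convex: slopes nondecreasing
        dx1 = left[i + 1][0] - left[i][0]
        dx2 = left[i + 2][0] - left[i + 1][0]
        r = np.zeros(nv)
        r[i] = -1 / dx1; r[i + 1] = 1 / dx1 + 1 / dx2; r[i + 2] = -1 / dx2
        add(r, 0)
    for j in range(nR - 2):  # concave: slopes nonincreasing
        dx1 = right[j + 1][0] - right[j][0]
        dx2 = right[j + 2][0] - right[j + 1][0]
        r = np.zeros(nv)
        r[nL + j] = 1 / dx1
        r[nL + j + 1] = -1 / dx1 - 1 / dx2
        r[nL + j + 2] = 1 / dx2
        add(r, 0)
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                  bounds=[(0, 1)] * (nv - 1) + [(0, None)], method="highs")
    return res.fun if res.success else np.inf


def lp_dip_oracle(x):
    """Brute-force dip: minimise the sup-distance to a piecewise-linear
    unimodal CDF over every modal cut, including modes carrying an atom at
    a data value."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    vals, counts = np.unique(x, return_counts=True)
    hi = np.cumsum(counts)
    lo = hi - counts
    m = vals.size
    if m == 1:
        return 1 / (2 * n)
    pts = [(vals[i], hi[i], lo[i]) for i in range(m)]
    best = np.inf
    for k in range(m + 1):  # mode (and jump) between values k-1 and k
        best = min(best, _lp_branch_dip(pts[:k], pts[k:], n))
    for k in range(m):      # mode with an atom at value k
        left = pts[:k] + [(vals[k], lo[k], lo[k])]
        right = [(vals[k], hi[k], hi[k])] + pts[k + 1:]
        best = min(best, _lp_branch_dip(left, right, n))
    return max(best, 1 / (2 * n))


class TestRandomize:
    def test_multiset_preserved_per_series(self, small_dataset):
        data, _ = small_dataset
        permuted = randomize_dataset(data, seed=3)
        for s, p in zip(data, permuted):
            assert np.array_equal(np.sort(s.abundances), np.sort(p.abundances))
            assert np.array_equal(s.years, p.years)
            assert s.species == p.species

    def test_length_one_series_unchanged(self):
        s = PopulationTimeSeries("x", years=[2000], abundances=[5.0])
        (p,) = randomize_dataset([s], seed=0)
        assert p.abundances[0] == 5.0

    def test_seed_reproducible(self, small_dataset):
        data, _ = small_dataset
        p1 = randomize_dataset(data, seed=9)
        p2 = randomize_dataset(data, seed=9)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.abundances, b.abundances)


class TestSignificanceRates:
    def test_trending_data_all_positive(self):
        mk = lambda i: PopulationTimeSeries(
            f"s{i}", years=2000 + np.arange(10),
            abundances=np.arange(10) * 2.0 + i)
        res = significance_rates([mk(i) for i in range(20)])
        assert res.pct_sig_positive == 100.0
        assert res.pct_sig_negative == 0.0

    def test_alpha_one_catches_everything_untied(self, rng):
        mk = lambda i: PopulationTimeSeries(
            f"s{i}", years=2000 + np.arange(8), abundances=rng.random(8))
        res = significance_rates([mk(i) for i in range(40)], alpha=1.0)
        assert res.pct_sig_negative + res.pct_sig_positive == 100.0

    def test_permuted_null_rates_near_alpha(self):
        data, _ = simulate_dataset(SimulationConfig(n_series=800,
                                                    n_species=200), seed=21)
        permuted = randomize_dataset(data, seed=22)
        res = significance_rates(permuted, alpha=0.05)
        total = res.pct_sig_negative + res.pct_sig_positive
        assert total == pytest.approx(5.0, abs=2.0)
        assert abs(res.pct_sig_negative - res.pct_sig_positive) < 2.5


class TestTruncation:
    def _series(self, n):
        return PopulationTimeSeries("x", years=2000 + np.arange(n),
                                    abundances=np.linspace(1, 2, n))

    def test_left_truncation_counts(self):
        out = truncate_series(self._series(12), drop_first=5)
        assert out.n_obs == 7
        assert out.years[0] == 2005

    def test_truncation_below_filter_threshold(self):
        from popspectrum.datasets import filter_min_points

        out = truncate_series(self._series(9), drop_first=5)
        assert out.n_obs == 4
        assert filter_min_points([out], k=5) == []

    def test_identity(self):
        s = self._series(7)
        out = truncate_series(s, drop_first=0, drop_last=0)
        assert np.array_equal(out.years, s.years)

    def test_linear_series_slope_invariant(self):
        from popspectrum.datasets import ScaledSeries
        from popspectrum.trends import fit_linear_trend

        s = self._series(20)
        for df, dl in ((5, 0), (0, 5)):
            t = truncate_series(s, drop_first=df, drop_last=dl)
            sc = ScaledSeries("x", t.years, t.abundances, "raw")
            slope, _, _ = fit_linear_trend(sc)
            assert slope == pytest.approx(np.diff(s.abundances)[0], rel=1e-9)


class TestDip:
    def test_matches_lp_oracle_on_grid_samples(self):
        from itertools import combinations_with_replacement

        for size in (4, 5, 6):
            for comb in combinations_with_replacement([0.0, 1.0, 2.0, 3.0],
                                                      size):
                x = np.array(comb)
                mine = dip_statistic(x).D
                assert mine == pytest.approx(lp_dip_oracle(x), abs=1e-7), comb

    def test_matches_lp_oracle_on_random_samples(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 9))
            x = np.round(rng.normal(size=n), 2)
            assert dip_statistic(x).D == pytest.approx(lp_dip_oracle(x),
                                                       abs=1e-7)

    def test_lower_bound_holds(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 120))
            x = rng.normal(size=n)
            assert dip_statistic(x).D >= 1 / (2 * n) - 1e-12

    def test_two_point_masses_reach_quarter(self):
        x = np.r_[np.zeros(100), np.ones(100)]
        assert dip_statistic(x).D == pytest.approx(0.25, abs=1e-9)

    def test_uniform_sample_small_dip(self, rng):
        x = rng.random(1000)
        assert dip_statistic(x).D < 0.02

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            dip_statistic([1.0, 2.0, 3.0])

    def test_pvalue_large_d_small_p(self):
        assert dip_pvalue(0.24, 50, n_boot=200, seed=1) < 0.02

    def test_pvalue_median_d_half(self, rng):
        # D at the null median must sit near p = 0.5 by construction
        null = [dip_statistic(rng.random(30)).D for _ in range(200)]
        med = float(np.median(null))
        p = dip_pvalue(med, 30, n_boot=400, seed=2)
        assert p == pytest.approx(0.5, abs=0.12)

    def test_pvalue_seeded(self):
        p1 = dip_pvalue(0.06, 40, n_boot=100, seed=7)
        p2 = dip_pvalue(0.06, 40, n_boot=100, seed=7)
        assert p1 == p2

    def test_bimodal_trend_distribution_detected(self, rng):
        x = np.r_[rng.normal(-0.025, 0.006, 400), rng.normal(0.025, 0.006, 400)]
        res = dip_test(x, n_boot=300, seed=3)
        assert res.p < 0.01


class TestDurationModel:
    def test_through_origin_formula(self):
        res = duration_model([0.1, 0.2], [10.0, 20.0],
                             iterations=6000, burnin=1000, thin=1, seed=1)
        d = np.ravel(res.draws["duration"])
        assert np.mean(d) == pytest.approx(0.01, abs=0.002)

    def test_zero_trends_zero_slope(self, rng):
        res = duration_model(np.zeros(50), rng.uniform(5, 30, 50),
                             iterations=4000, burnin=1000, thin=1, seed=2)
        assert np.mean(np.ravel(res.draws["duration"])) == pytest.approx(
            0.0, abs=1e-3)

    def test_matches_through_origin_ols(self, rng):
        dur = rng.uniform(5, 40, 300)
        mu = 0.004 * dur + rng.normal(0, 0.05, 300)
        res = duration_model(mu, dur, iterations=8000, burnin=2000, thin=1,
                             seed=3)
        ols = float(mu @ dur / (dur @ dur))
        d = np.ravel(res.draws["duration"])
        assert np.mean(d) == pytest.approx(ols, abs=3 * np.std(d))

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            duration_model([0.1], [0.0])
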