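"""Randomization nulls, truncation sensitivity, duration model, and
Hartigan's dip test for bimodality.

The randomization null asks how many significant trends pure noise with the
database's structure would produce: abundance values are permuted within
each series (preserving each series' value distribution, length and survey
years), an OLS slope of abundance on year is tested per series, and the
percentage of significant negative and positive slopes is reported.

The dip statistic D is the maximal distance between the empirical CDF and
the closest unimodal CDF; its p-value is Monte-Carlo calibrated against
uniform samples of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import PopulationTimeSeries, ScaledSeries
from .trends import fit_linear_trend

__all__ = [
    "NullResult",
    "DipResult",
    "randomize_dataset",
    "significance_rates",
    "truncate_series",
    "dip_statistic",
    "dip_pvalue",
    "dip_test",
    "duration_model",
]


@dataclass
class NullResult:
    """Share of series with significant negative/positive OLS slopes."""

    pct_sig_negative: float
    pct_sig_positive: float
    n_series: int
    alpha: float
    seed: int | None = None

    def summary(self) -> str:
        return (f"Significance rates over {self.n_series} series "
                f"(alpha={self.alpha}):\n"
                f"  declining: {self.pct_sig_negative:.2f}%\n"
                f"  increasing: {self.pct_sig_positive:.2f}%")


@dataclass
class DipResult:
    """Hartigan's dip statistic with its Monte-Carlo p-value."""

    D: float
    p: float | None
    n: int
    n_boot: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n >= 1 and not (1.0 / (2 * self.n) - 1e-12 <= self.D <= 0.25 + 1e-12):
            raise ValueError(f"dip {self.D} outside [1/(2n), 1/4] for n={self.n}")


def randomize_dataset(data: list[PopulationTimeSeries],
                      seed: int | None = None,
                      mode: str = "permute") -> list[PopulationTimeSeries]:
    """Null data with structure identical to the input.

    ``permute`` (default) shuffles abundance values within each series over
    its own survey years; ``resample`` draws them iid with replacement from
    the series' own values.  Metadata, years and lengths are unchanged;
    reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in data:
        if mode == "permute":
            vals = rng.permutation(s.abundances)
        elif mode == "resample":
            vals = rng.choice(s.abundances, size=s.n_obs, replace=True)
        else:
            raise ValueError(f"unknown randomization mode: {mode!r}")
        out.append(replace(s, abundances=vals))
    return out


def significance_rates(data: list[PopulationTimeSeries],
                       alpha: float = 0.05,
                       seed: int | None = None) -> NullResult:
    """Per-series OLS abundance-vs-year slope test; percentage of series
    with a significant negative and positive slope at ``alpha``."""
    neg = pos = 0
    n = 0
    for s in data:
        if s.n_obs < 3:
            raise ValueError(f"{s.series_id}: need >= 3 points for a p-value")
        sc = ScaledSeries(s.series_id, s.years, s.abundances, "raw",
                          constant_flag=bool(np.ptp(s.abundances) == 0))
        if sc.constant_flag:
            n += 1
            continue
        slope, _, p = fit_linear_trend(sc)
        if p < alpha:
            if slope < 0:
                neg += 1
            elif slope > 0:
                pos += 1
        n += 1
    return NullResult(100.0 * neg / n, 100.0 * pos / n, n, alpha, seed)


def truncate_series(series: PopulationTimeSeries, drop_first: int = 5,
                    drop_last: int = 0) -> PopulationTimeSeries | None:
    """Remove the first ``drop_first`` and last ``drop_last`` observations
    (site-selection-bias sensitivity).  Returns None when nothing remains;
    the caller re-applies the minimum-points filter downstream."""
    n = series.n_obs
    stop = n - drop_last
    if stop - drop_first <= 0:
        return None
    sl = slice(drop_first, stop)
    return replace(series, years=series.years[sl], abundances=series.abundances[sl])


# ---------------------------------------------------------------------------
# Hartigan's dip
# ---------------------------------------------------------------------------

def _collapse_ties(x):
    """Distinct sorted values with the empirical CDF just below / at each."""
    vals, counts = np.unique(x, return_counts=True)
    hi = np.cumsum(counts)  # F_n at the value
    lo = hi - counts        # F_n just below the value
    return vals, lo, hi


def _lower_hull_dev(xs, upper, lower):
    """Max of (lower_i - hull(x_i)) over the greatest convex minorant of the
    points (x_i, upper_i): how far a convex CDF branch must stretch."""
    stack = []  # indices of hull vertices
    for i in range(len(xs)):
        while len(stack) >= 2:
            a, b = stack[-2], stack[-1]
            # pop b if it lies above chord a->i
            if (upper[b] - upper[a]) * (xs[i] - xs[a]) >= \
               (upper[i] - upper[a]) * (xs[b] - xs[a]):
                stack.pop()
            else:
                break
        stack.append(i)
    hull = np.interp(xs, xs[stack], upper[stack])
    return float(np.max(lower - hull))


def _dip_one_side(xs, req, cap, n):
    """Half-deviation demanded of a convex CDF branch over these points.

    At each distinct value the branch must reach at least req/n - d (the
    empirical CDF at the value) while staying at most cap/n + d (the CDF
    just below it); the greatest convex minorant of the caps says how much
    stretching (d) that takes.
    """
    if len(xs) == 0:
        return 0.0
    return max(0.0, _lower_hull_dev(xs, cap / n, req / n) / 2.0)


def dip_statistic(sample, n_boot: int | None = None,
                  seed: int | None = None) -> DipResult:
    """Hartigan & Hartigan's dip: the maximal deviation between the
    empirical CDF and the nearest unimodal CDF.

    For each candidate modal cut the convex branch (left) and concave
    branch (right) each demand a minimal half-deviation, obtained from the
    greatest convex minorant / least concave majorant of the empirical CDF
    band; both demands are monotone in the cut, so the dip is the minimax
    over cuts.  When ``n_boot`` is given the Monte-Carlo p-value is attached.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 observations for the dip, have {n}")
    D = _dip_value(x)
    p = None
    if n_boot:
        p = dip_pvalue(D, n, n_boot=n_boot, seed=seed)
    return DipResult(D, p, n, n_boot, seed)


def _dip_value(x_sorted) -> float:
    n = x_sorted.size
    vals, lo, hi = _collapse_ties(x_sorted)
    m = vals.size
    if m == 1:
        return 1.0 / (2 * n)

    def d_left(k):  # values[0..k-1] on the convex side
        if k == 0:
            return 0.0
        return _dip_one_side(vals[:k], req=hi[:k], cap=lo[:k], n=n)

    def d_right(k):  # values[k..m-1] on the concave side, mirrored
        if k == m:
            return 0.0
        xs = -vals[k:][::-1]
        req = (n - lo[k:])[::-1]   # mirrored CDF must reach 1 - F(just below)
        cap = (n - hi[k:])[::-1]   # ... staying under 1 - F(at value)
        return _dip_one_side(xs, req=req, cap=cap, n=n)

    # mode carrying an atom AT value k: the convex branch only has to meet
    # F just below the value, the concave branch starts from F at the value
    def d_left_atom(k):
        return _dip_one_side(vals[:k + 1], req=np.r_[hi[:k], lo[k]],
                             cap=np.r_[lo[:k], lo[k]], n=n)

    def d_right_atom(k):
        xs = -vals[k:][::-1]
        req = (n - np.r_[hi[k], lo[k + 1:]])[::-1]
        cap = (n - np.r_[hi[k], hi[k + 1:]])[::-1]
        return _dip_one_side(xs, req=req, cap=cap, n=n)

    best = np.inf
    # d_left is nondecreasing and d_right nonincreasing in the cut (the atom
    # variants are sandwiched between consecutive plain cuts); scan all cuts
    # when small, else search around the crossing
    if m <= 64:
        cuts = range(m + 1)
    else:
        lo_k, hi_k = 0, m
        while hi_k - lo_k > 1:
            mid = (lo_k + hi_k) // 2
            if d_left(mid) < d_right(mid):
                lo_k = mid
            else:
                hi_k = mid
        cuts = range(max(0, lo_k - 4), min(m, hi_k + 4) + 1)
    for k in cuts:
        d = max(d_left(k), d_right(k))
        if k < m:
            d = min(d, max(d_left_atom(k), d_right_atom(k)))
        if d < best:
            best = d
    return float(max(best, 1.0 / (2 * n)))


def dip_pvalue(D: float, n: int, n_boot: int = 2000,
               seed: int | None = None) -> float:
    """Monte-Carlo p-value: share of uniform(0,1) samples of size n whose
    dip is at least ``D``."""
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        xb = np.sort(rng.random(n))
        if _dip_value(xb) >= D:
            count += 1
    return count / n_boot


def dip_test(sample, n_boot: int = 2000, seed: int | None = None) -> DipResult:
    """Dip statistic plus its Monte-Carlo p-value."""
    return dip_statistic(sample, n_boot=n_boot, seed=seed)


def duration_model(trends, durations, species=None,
                   iterations: int = 20_000, burnin: int = 4_000,
                   thin: int = 5, seed: int | None = None):
    """Bayesian through-origin regression of trend on monitoring duration.

    The intercept is suppressed: at zero duration no population change can
    have occurred.  Returns the HierarchicalResults of the fit (the 'duration'
    parameter carries the slope posterior).
    """
    import pandas as pd

    durations = np.asarray(durations, dtype=float)
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    df = pd.DataFrame(dict(mu=np.asarray(trends, dtype=float), duration=durations))
    if species is not None:
        df["species"] = np.asarray(species)
    from .hierarchical import HierarchicalGaussianModel

    model = HierarchicalGaussianModel.from_dataframe(
        df, "mu", fixed="duration", fixed_type="continuous", intercept=False,
        species="species" if species is not None else None,
    )
    return model.fit(iterations=iterations, burnin=burnin, thin=thin, seed=seed)
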