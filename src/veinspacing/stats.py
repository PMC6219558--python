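"""Inferential machinery for vein-spacing distributions.

Three independent pieces:

* Hartigan & Hartigan's dip statistic of unimodality, with Monte-Carlo
  p-values against a uniform(0, 1) null.
* The Brunner-Munzel two-sample rank test (relative effect
  ``P(X < Y) + 0.5 P(X = Y)``, studentized with Satterthwaite degrees of
  freedom).
* Gaussian-kernel density summaries (the "violin" curves) with mode
  locations.

All operations are deterministic given their inputs and, where relevant, a
seed.  The dip p-value is the add-one Monte-Carlo estimate
``(1 + #{null >= observed}) / (reps + 1)``, which is never exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "DipResult",
    "BMResult",
    "DensitySummary",
    "dip_statistic",
    "dip_test",
    "dip_pvalue",
    "brunner_munzel",
    "density_summary",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DipResult:
    """Dip statistic plus its Monte-Carlo p-value.

    The dip lies in [1/(2n), 0.25]; small p-values indicate departure from
    unimodality.
    """

    n: int
    dip: float
    p_value: float
    reps: int
    seed: int


@dataclass(frozen=True)
class BMResult:
    """Brunner-Munzel test result.

    ``p_hat`` is the relative effect P(X < Y) + 0.5 P(X = Y); values above
    0.5 mean the second sample tends to be larger.  ``degenerate`` is set
    when the rank-variance estimate vanishes (complete separation or
    all-tied data), in which case statistic/df/p_value are NaN.
    """

    statistic: float
    df: float
    p_value: float
    p_hat: float
    n_x: int
    n_y: int
    degenerate: bool = False


@dataclass(frozen=True)
class DensitySummary:
    """Gaussian-KDE summary of a pooled ratio sample."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    modes: tuple[float, ...]
    degenerate: bool = False

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


# ---------------------------------------------------------------------------
# dip statistic
# ---------------------------------------------------------------------------
#
# The dip of an empirical cdf F_n is the smallest sup-norm distance from
# F_n to any unimodal cdf (convex on (-inf, m], concave on [m, inf), with
# a jump permitted at the mode m itself).  It is computed exactly by a
# modal-knot decomposition.  Work in count units on the distinct values
# z_0 < ... < z_{m-1} with cumulative counts c_k = n F(z_k) and lower
# steps cl_k = n F(z_k^-):
#
# * A unimodal cdf within sup-distance d of F_n and with mode at z_k
#   exists iff a nondecreasing convex function fits the vertical windows
#   [c_j - nd, cl_j + nd] at z_0..z_k (window relaxed at the mode knot)
#   and a concave one fits them on z_k..z_{m-1}.
# * Convex feasibility on a prefix has a closed form: the greatest convex
#   minorant of the upper window corners is the pointwise-largest convex
#   candidate, so the prefix is feasible iff
#   nd >= leftNeed(k) = 1/2 * max_{j<k} (c_j - A_k(z_j)), with A_k the
#   lower convex hull of the points (z_i, cl_i), i <= k.  Mirrored,
#   rightNeed(k) = 1/2 * max_{j>k} (B_k(z_j) - cl_j) with B_k the upper
#   concave hull of (z_i, c_i), i >= k.
#
# A third condition couples the two sides at the mode: the convex piece
# ends at the left limit v, the concave one starts at w, and the (possibly
# jumping) cdf needs v <= w.  Window pairs propagate through convexity -
# a window floor at z_j2 above a window ceiling at z_j1 < z_j2 forces a
# positive entry slope that convexity cannot relax afterwards - so the
# smallest achievable v at mode k is
#   alpha_k(d) = max(c_{k-1} - nd, max_{j2<k} [c_j2 - nd + s_j2 (z_k - z_j2)]),
#   s_j2 = max(0, max_{j1<j2} (c_j2 - cl_j1 - 2nd) / (z_j2 - z_j1)),
# and beta_k(d), the largest achievable w, is its mirror image.  The dip
# is the smallest d for which some mode k satisfies all three conditions;
# min_k max(leftNeed(k), rightNeed(k)) is a lower bound (exact whenever
# the junction is slack there), refined by bisection on the monotone
# feasibility predicate otherwise.  The result is floored at 1/2 count
# (the classic 1/(2n) bound, attained automatically whenever the sample
# has at least two distinct values).
#
# The need-profiles are accumulated in single hull sweeps: pushing a new
# point rebuilds only the final hull segment, below which the gaps can
# only have grown, so a running maximum over the rebuilt span is exact.

def _convex_needs_py(z: np.ndarray, cl: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-prefix convex-fit requirement, in count units.

    ``needs[k]`` is the smallest ``n*d`` such that a nondecreasing convex
    function passes through the windows [c_j - nd, cl_j + nd] at z_0..z_k
    (the lower window relaxed at the endpoint k, which plays the mode).
    Equals ``1/2 * max_{j<k} (c_j - A_k(z_j))`` with A_k the lower convex
    hull of the points (z_i, cl_i), i <= k.
    """
    m = z.shape[0]
    needs = np.zeros(m)
    hull = np.empty(m, dtype=np.int64)
    hull[0] = 0
    n_h = 1
    M = 0.0
    for k in range(1, m):
        while n_h >= 2:
            a = hull[n_h - 2]
            b = hull[n_h - 1]
            if (cl[b] - cl[a]) * (z[k] - z[b]) < (cl[k] - cl[b]) * (z[b] - z[a]):
                break
            n_h -= 1
        p = hull[n_h - 1]
        if p == k - 1:
            gap = c[k - 1] - cl[k - 1]
            if gap > M:
                M = gap
        else:
            slope = (cl[k] - cl[p]) / (z[k] - z[p])
            for j in range(p + 1, k):
                gap = c[j] - (cl[p] + (z[j] - z[p]) * slope)
                if gap > M:
                    M = gap
        hull[n_h] = k
        n_h += 1
        needs[k] = 0.5 * M
    return needs


def _alpha_profile_py(z: np.ndarray, cl: np.ndarray, c: np.ndarray,
                      d: float) -> np.ndarray:
    """Smallest achievable left limit of the convex piece at each mode knot.

    All in count units at tolerance ``d``; clamped below at 0.
    """
    m = z.shape[0]
    sigma = np.zeros(m)
    for j2 in range(m):
        s = 0.0
        top = c[j2] - 2.0 * d  # cl >= 0, so (top - cl[j1])/dz <= top/dz
        if top > 0.0:
            for j1 in range(j2 - 1, -1, -1):
                dz = z[j2] - z[j1]
                if top / dz <= s:
                    break  # dz only grows leftwards; no farther pair can win
                t = (top - cl[j1]) / dz
                if t > s:
                    s = t
        sigma[j2] = s
    alpha = np.empty(m)
    for k in range(m):
        a = c[k - 1] - d if k > 0 else -d
        for j2 in range(k):
            if sigma[j2] > 0.0:
                v = (c[j2] - d) + sigma[j2] * (z[k] - z[j2])
                if v > a:
                    a = v
        if a < 0.0:
            a = 0.0
        alpha[k] = a
    return alpha


def _dip_feasible_py(z, cl, c, zr, clr, cr, left, right_rev, n, d) -> bool:
    m = z.shape[0]
    alpha = _alpha_profile(z, cl, c, d)
    alpha_r = _alpha_profile(zr, clr, cr, d)
    for k in range(m):
        if left[k] <= d and right_rev[m - 1 - k] <= d:
            beta = n - alpha_r[m - 1 - k]
            if alpha[k] <= beta:
                return True
    return False


def _dip_sorted_py(x: np.ndarray) -> float:
    n = x.shape[0]
    if n < 2 or x[0] == x[n - 1]:
        return 0.5 / n

    # collapse ties: distinct values z, upper/lower cumulative counts c, cl
    z = np.empty(n)
    c = np.empty(n)
    m = 0
    for i in range(n):
        if m > 0 and x[i] == z[m - 1]:
            c[m - 1] += 1.0
        else:
            z[m] = x[i]
            c[m] = c[m - 1] + 1.0 if m > 0 else 1.0
            m += 1
    z = z[:m]
    c = c[:m]
    cl = np.empty(m)
    cl[0] = 0.0
    for i in range(1, m):
        cl[i] = c[i - 1]

    left = _convex_needs(z, cl, c)
    # the concave side is the convex side of the mirrored sample
    zr = np.empty(m)
    clr = np.empty(m)
    cr = np.empty(m)
    for i in range(m):
        zr[i] = -z[m - 1 - i]
        cr[i] = n - cl[m - 1 - i]
        clr[i] = n - c[m - 1 - i]
    right_rev = _convex_needs(zr, clr, cr)

    d_lo = np.inf
    for k in range(m):
        need = max(left[k], right_rev[m - 1 - k])
        if need < d_lo:
            d_lo = need

    if not _dip_feasible(z, cl, c, zr, clr, cr, left, right_rev, n, d_lo):
        # the mode junction binds: bisect the monotone feasibility predicate
        d_hi = 0.26 * n
        tol = 1e-11 * n
        while d_hi - d_lo > tol:
            mid = 0.5 * (d_lo + d_hi)
            if _dip_feasible(z, cl, c, zr, clr, cr, left, right_rev, n, mid):
                d_hi = mid
            else:
                d_lo = mid
        d_lo = d_hi

    if d_lo < 0.5:
        d_lo = 0.5
    return d_lo / n


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _convex_needs = njit(cache=True)(_convex_needs_py)
    _alpha_profile = njit(cache=True)(_alpha_profile_py)
    _dip_feasible = njit(cache=True)(_dip_feasible_py)
    _dip_sorted = njit(cache=True)(_dip_sorted_py)
except ImportError:  # pragma: no cover
    _convex_needs = _convex_needs_py
    _alpha_profile = _alpha_profile_py
    _dip_feasible = _dip_feasible_py
    _dip_sorted = _dip_sorted_py


def dip_statistic(sample) -> float:
    """Hartigan-Hartigan dip statistic of a univariate sample.

    Parameters
    ----------
    sample : array-like
        At least two finite values.

    Returns
    -------
    float
        The dip, bounded by ``1/(2n) <= dip <= 0.25``.  Invariant under
        increasing affine transforms of the sample.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("dip_statistic requires at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic requires finite values")
    return float(_dip_sorted(np.sort(x)))


# Monte-Carlo null tables, keyed by (n, reps, seed).  Regenerating a table
# is the expensive part of a dip p-value; p-values for many samples of the
# same size share one table.
_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}
_NULL_CACHE_MAX = 32


def _null_dips(n: int, reps: int, seed: int) -> np.ndarray:
    key = (n, reps, seed)
    table = _NULL_CACHE.get(key)
    if table is None:
        rng = np.random.default_rng(seed)
        u = np.sort(rng.random((reps, n)), axis=1)
        table = np.sort(np.array([_dip_sorted(u[i]) for i in range(reps)]))
        if len(_NULL_CACHE) >= _NULL_CACHE_MAX:
            _NULL_CACHE.pop(next(iter(_NULL_CACHE)))
        _NULL_CACHE[key] = table
    return table


def dip_pvalue(dip: float, n: int, reps: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo p-value of an observed dip.

    Null dips are drawn from uniform(0, 1) samples of the observed size
    (the convention of the classic tables).  ``p = (1 + #{null >= dip}) /
    (reps + 1)``; reproducible given the seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    table = _null_dips(int(n), int(reps), int(seed))
    n_ge = table.size - np.searchsorted(table, dip, side="left")
    return float((1 + n_ge) / (reps + 1))


def dip_test(sample, reps: int = 10_000, seed: int = 0) -> DipResult:
    """Dip statistic and Monte-Carlo p-value in one call."""
    x = np.asarray(sample, dtype=float).ravel()
    d = dip_statistic(x)
    p = dip_pvalue(d, x.size, reps=reps, seed=seed)
    return DipResult(n=int(x.size), dip=d, p_value=p, reps=int(reps), seed=int(seed))


# ---------------------------------------------------------------------------
# Brunner-Munzel
# ---------------------------------------------------------------------------

def brunner_munzel(x, y) -> BMResult:
    """Two-sided Brunner-Munzel test.

    Tests the relative effect ``p_hat = P(X < Y) + 0.5 P(X = Y)`` against
    0.5 using pooled midranks, rank-based variance estimates and a t
    reference distribution with Satterthwaite degrees of freedom.  Ties are
    handled through average ranks.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("brunner_munzel requires at least 2 values per sample")
    N = n1 + n2
    r = sps.rankdata(np.concatenate([x, y]))
    r1, r2 = r[:n1], r[n1:]
    m1, m2 = float(r1.mean()), float(r2.mean())
    p_hat = (m2 - (n2 + 1) / 2.0) / n1

    v1 = float(np.sum((r1 - sps.rankdata(x) - m1 + (n1 + 1) / 2.0) ** 2)) / (n1 - 1)
    v2 = float(np.sum((r2 - sps.rankdata(y) - m2 + (n2 + 1) / 2.0) ** 2)) / (n2 - 1)
    var = n1 * v1 + n2 * v2
    if var <= 0.0:
        return BMResult(
            statistic=math.nan, df=math.nan, p_value=math.nan,
            p_hat=p_hat, n_x=n1, n_y=n2, degenerate=True,
        )
    statistic = n1 * n2 * (m2 - m1) / (N * math.sqrt(var))
    df = var**2 / ((n1 * v1) ** 2 / (n1 - 1) + (n2 * v2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(statistic), df)
    return BMResult(
        statistic=float(statistic), df=float(df), p_value=float(min(p, 1.0)),
        p_hat=float(p_hat), n_x=n1, n_y=n2,
    )


# ---------------------------------------------------------------------------
# density summaries
# ---------------------------------------------------------------------------

def density_summary(
    sample,
    bandwidth_rule: str = "silverman",
    bandwidth: float | None = None,
    gridsize: int = 512,
) -> DensitySummary:
    """Gaussian-KDE density on a regular grid with mode locations.

    The grid spans [min - 2h, max + 2h].  Modes are grid locations of
    strict local maxima of the estimated density, sorted by location.  A
    zero-variance sample is flagged degenerate and reported as a single
    mode at the common value.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("density_summary requires a non-empty sample")
    if bandwidth_rule not in ("silverman", "fixed"):
        raise ValueError(f"unknown bandwidth_rule {bandwidth_rule!r}")
    if bandwidth_rule == "fixed" and (bandwidth is None or bandwidth <= 0):
        raise ValueError("fixed bandwidth_rule requires a positive bandwidth")

    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if std <= 1e-12 * max(1.0, float(np.abs(x).max())):
        # effectively a point mass; report its location as the single mode
        v = float(np.median(x))
        h = bandwidth if bandwidth_rule == "fixed" else 0.0
        grid = np.array([v])
        dens = np.array([np.inf])
        return DensitySummary(grid=grid, density=dens, bandwidth=float(h or 0.0),
                              modes=(v,), degenerate=True)

    if bandwidth_rule == "fixed":
        kde = sps.gaussian_kde(x, bw_method=bandwidth / std)
    else:
        kde = sps.gaussian_kde(x, bw_method="silverman")
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 2 * h, x.max() + 2 * h, int(gridsize))
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    modes = tuple(float(g) for g in grid[1:-1][interior])
    return DensitySummary(grid=grid, density=dens, bandwidth=h, modes=modes)
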