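"""Statistical layer: robust summaries, rank/variance tests, seeded
permutation correlation with Gaussian-tail extrapolation, polynomial curve
and sheet fits, and displacement autocorrelation."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: switch from exact Mann-Whitney enumeration to the normal approximation
EXACT_MW_MAX_N = 8


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    side: str = "two-sided"
    extrapolated: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class FitResult:
    coefficients: np.ndarray
    degrees: tuple[int, ...]
    r_squared: float
    n: int
    column_names: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# robust summary


def summarize_median(values, n_boot: int = 10_000, seed: int = 0
                     ) -> tuple[float, float]:
    """Median with a seeded bootstrap standard error (B resamples).

    Returns ``(median, se)``.  The SE of a sample median has no closed form
    for general distributions; the nonparametric bootstrap is the standard
    estimator for "median +/- SE" summaries.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite values")
    med = float(np.median(x))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    chunk = max(1, int(5e6 // max(x.size, 1)))
    for start in range(0, n_boot, chunk):
        m = min(chunk, n_boot - start)
        idx = rng.integers(0, x.size, size=(m, x.size))
        boots[start:start + m] = np.median(x[idx], axis=1)
    return med, float(np.std(boots, ddof=1))


# ---------------------------------------------------------------------------
# two-sample tests


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray, side: str) -> TestResult:
    # enumerate assignments of the smaller sample's ranks; flip sidedness
    # when the samples are swapped
    flipped = a.size > b.size
    if flipped:
        a, b = b, a
        side_enum = {"less": "greater", "greater": "less"}.get(side, side)
    else:
        side_enum = side
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks handle ties
    na = a.size
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    mu = na * b.size / 2.0
    stats_null = np.array([
        sum(comb) - na * (na + 1) / 2.0
        for comb in itertools.combinations(ranks, na)
    ])
    if side_enum == "two-sided":
        p = np.mean(np.abs(stats_null - mu) >= np.abs(u_obs - mu) - 1e-12)
    elif side_enum == "less":
        p = np.mean(stats_null <= u_obs + 1e-12)
    elif side_enum == "greater":
        p = np.mean(stats_null >= u_obs - 1e-12)
    else:
        raise ValueError(f"unknown side {side!r}")
    if flipped:
        u_obs = a.size * b.size - u_obs  # report U of the original first sample
    return TestResult(statistic=float(u_obs), p_value=float(p),
                      method="mann-whitney-exact",
                      n=(b.size, a.size) if flipped else (na, b.size), side=side)


def mann_whitney(a, b, side: str = "two-sided") -> TestResult:
    """Mann-Whitney U test for two independent samples.

    When the smaller sample has at most 8 observations (and the enumeration
    is affordable) the null is enumerated exactly over all rank assignments,
    with midranks handling ties; otherwise the tie-corrected normal
    approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_small = min(a.size, b.size)
    from math import comb
    if n_small <= EXACT_MW_MAX_N and comb(a.size + b.size, n_small) <= 200_000:
        return _mann_whitney_exact(a, b, side)
    with np.errstate(invalid="ignore"):
        res = sps.mannwhitneyu(a, b, alternative=side, method="asymptotic",
                               use_continuity=False)
    p = float(res.pvalue)
    if np.isnan(p):  # zero rank variance (complete ties): no evidence
        p = 1.0
    return TestResult(statistic=float(res.statistic), p_value=p,
                      method="mann-whitney-asymptotic", n=(a.size, b.size),
                      side=side)


def variance_f_test(a, b) -> TestResult:
    """Two-sided F test comparing sample variances; statistic = var(a)/var(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    f = va / vb if vb > 0 else np.inf
    dist = sps.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return TestResult(statistic=float(f), p_value=float(min(p, 1.0)),
                      method="variance-F", n=(a.size, b.size))


# ---------------------------------------------------------------------------
# permutation correlation with Gaussian-tail extrapolation


def gaussian_tail_p(z) -> float:
    """One-sided upper-tail standard-normal probability, accurate far into
    the tail (erfc-based; exponentiated from log space for large z)."""
    z = float(z)
    if z > 6:
        return float(np.exp(sps.norm.logsf(z)))
    return float(sps.norm.sf(z))


def permutation_correlation(x, y, n_perm: int = 1_000_000, seed: int = 0,
                            absolute: bool = False) -> TestResult:
    """Monte-Carlo permutation test of the Pearson correlation of (x, y).

    The null is built by permuting ``y``.  The empirical p-value uses the
    add-one estimator  (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).  The
    permuted correlations are also summarised by their sample mean and sd
    (a Gaussian fit to the null); when no permutation is as extreme as the
    observation the Gaussian one-sided tail probability at
    z = (r_obs - mu) / sigma is reported as the extrapolated p.

    ``absolute`` first maps both variables to their absolute values —
    appropriate for angle pairs compared on [0, 90] degrees.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if absolute:
        x, y = np.abs(x), np.abs(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    nv = x.size
    r_obs = float(np.mean(xs * ys))
    rng = np.random.default_rng(seed)
    count = 0
    s1 = 0.0
    s2 = 0.0
    chunk = max(1, int(2e6 // nv))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(ys, (m, nv)), axis=1)
        r = perm @ xs / nv
        count += int(np.sum(np.abs(r) >= abs(r_obs) - 1e-15))
        s1 += float(r.sum())
        s2 += float(np.square(r).sum())
        done += m
    mu = s1 / n_perm
    sigma = np.sqrt(max(s2 / n_perm - mu ** 2, 0.0))
    p_emp = (1 + count) / (1 + n_perm)
    z = (abs(r_obs) - mu) / sigma if sigma > 0 else np.inf
    p_tail = gaussian_tail_p(z)
    extrapolated = count == 0
    # with no permutation as extreme, p_value is the add-one upper bound
    # 1/(n_perm+1); the Gaussian-tail extrapolation refines it in `extra`
    return TestResult(
        statistic=r_obs,
        p_value=float(p_emp),
        method="permutation-pearson",
        n=(nv,),
        side="two-sided",
        extrapolated=extrapolated,
        extra={"p_empirical": float(p_emp), "p_gaussian_tail": float(p_tail),
               "null_mu": float(mu), "null_sigma": float(sigma),
               "z": float(z), "n_perm": int(n_perm)},
    )


# ---------------------------------------------------------------------------
# polynomial curve / sheet fits


def _power_design(y: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(y, degree + 1, increasing=True)


def fit_swivel_surface(y_positions, swivels, thicknesses=None,
                       degree_y: int = 3, degree_thickness: int = 1) -> FitResult:
    """Least-squares polynomial fit of y-swivel against plate position.

    Without ``thicknesses``: a degree-3 polynomial in the y position.  With
    ``thicknesses``: a separable sheet, the tensor product of a degree-3
    polynomial in y and a degree-1 polynomial in plate thickness.
    Returns coefficients and the coefficient of determination R^2.
    """
    y = np.asarray(y_positions, dtype=float)
    s = np.asarray(swivels, dtype=float)
    design = _power_design(y, degree_y)
    names = [f"y^{i}" for i in range(degree_y + 1)]
    degrees = (degree_y,)
    if thicknesses is not None:
        t = np.asarray(thicknesses, dtype=float)
        dt = _power_design(t, degree_thickness)
        design = np.einsum("ni,nj->nij", design, dt).reshape(y.size, -1)
        names = [f"y^{i}*t^{j}" for i in range(degree_y + 1)
                 for j in range(degree_thickness + 1)]
        degrees = (degree_y, degree_thickness)
    if y.size <= design.shape[1]:
        raise ValueError("need more observations than coefficients")
    coef, _, rank, _ = np.linalg.lstsq(design, s, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    resid = s - design @ coef
    ss_tot = np.sum((s - s.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return FitResult(coefficients=coef, degrees=degrees, r_squared=float(r2),
                     n=y.size, column_names=names)


# ---------------------------------------------------------------------------
# trajectories


def displacement_autocorrelation(series, max_lag: int = 10) -> np.ndarray:
    """Autocorrelation of frame-to-frame displacements of a position series.

    Returns the correlation at lags 1..max_lag of ``diff(series)``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 frames")
    d = np.diff(x)
    if np.ptp(d) == 0:
        raise ValueError("constant displacement series")
    # per-lag Pearson correlation of the displacement series with its
    # lagged copy (not the biased single-variance ACF estimator)
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        if lag >= d.size:
            out[lag - 1] = np.nan
            continue
        out[lag - 1] = np.corrcoef(d[:-lag], d[lag:])[0, 1]
    return out


def angular_histogram(angles_deg, bin_width: float = 20.0) -> pd.DataFrame:
    """Binned angular histogram over (-180, 180] (rose-plot data as a table)."""
    a = np.asarray(angles_deg, dtype=float)
    a = np.mod(a + 180.0, 360.0) - 180.0
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(a, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
    })
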