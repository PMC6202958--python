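"""Statistical layer: paired one-sided tests on evenness, Spearman
correlations with Benjamini-Hochberg FDR control, and the low-chlorophyll
spectral-tuning trend.

The paired tests are implemented from their textbook definitions (scipy
supplies only the t and normal distribution functions); the full scipy tests
serve as independent cross-checks in the test suite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DIRECTIONS = ("greater", "less")


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    direction: str
    n_pairs: int
    degenerate: bool = False  # zero-variance / all-zero differences


def _check_pairs(x, y, direction):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing pairs are not allowed")
    return x, y


def paired_t_one_sided(x, y, direction: str = "greater") -> PairedTestResult:
    """One-sided paired t-test on differences d = x - y (mu = 0).

    ``direction='greater'`` tests whether x tends to exceed y.  Zero-variance
    differences are flagged degenerate: p is 0.5 for all-zero d, otherwise 0
    or 1 by the sign of the (constant) difference.
    """
    x, y = _check_pairs(x, y, direction)
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 0.5, direction, n, degenerate=True)
        aligned = (mean > 0) == (direction == "greater")
        stat = math.inf if mean > 0 else -math.inf
        return PairedTestResult(stat, 0.0 if aligned else 1.0, direction, n, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = sps.t.sf(t, n - 1) if direction == "greater" else sps.t.cdf(t, n - 1)
    return PairedTestResult(float(t), float(p), direction, n)


def _signed_rank_exact_sf(n: int, w: int) -> float:
    """P(W+ >= w) for n untied pairs, by convolution over ranks 1..n."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: max_w + 1 - r].copy()
    return float(counts[w:].sum() / 2.0**n)


def wilcoxon_signed_rank_paired(x, y, direction: str = "greater") -> PairedTestResult:
    """One-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon convention).  The p-value uses the
    exact null distribution for n <= 25 without ties in |d|, and the normal
    approximation with tie and continuity corrections otherwise.  All-zero
    differences give an undefined, degenerate result.
    """
    x, y = _check_pairs(x, y, direction)
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedTestResult(float("nan"), float("nan"), direction, 0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    stat = w_plus
    has_ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not has_ties:
        w = int(round(w_plus))
        if direction == "greater":
            p = _signed_rank_exact_sf(n, w)
        else:
            max_w = n * (n + 1) // 2
            p = _signed_rank_exact_sf(n, max_w - w)  # P(W+ <= w) by symmetry
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        if direction == "greater":
            z = (w_plus - mu - 0.5) / sigma
            p = float(sps.norm.sf(z))
        else:
            z = (w_plus - mu + 0.5) / sigma
            p = float(sps.norm.cdf(z))
    return PairedTestResult(stat, float(p), direction, n)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values; NaN p-values propagate."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def spearman_fdr(
    table: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Spearman rank correlations for declared variable pairs, BH-corrected.

    Each pair uses its complete observations (>= 4 required).  Constant
    variables yield undefined rho/p for that pair; the q-values are computed
    over the declared pair family.
    """
    rows = []
    for xcol, ycol in pairs:
        sub = table[[xcol, ycol]].dropna()
        n = len(sub)
        if n < 4:
            raise ValueError(f"pair ({xcol}, {ycol}): need >= 4 complete observations")
        x = sub[xcol].to_numpy(float)
        y = sub[ycol].to_numpy(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = sps.spearmanr(x, y)
        rows.append({"x": xcol, "y": ycol, "rho": float(rho), "p": float(p), "n": n})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class TuningTrendModel:
    """Blue fraction vs ln(Chl-a) below the oligotrophy threshold.

    blue_fraction = slope * ln(chl) + intercept, fitted by OLS on the
    fraction scale over samples with chl < chl_threshold (default
    0.25 ug/L); samples at or above the threshold form the unmodeled
    stratum summarized by their mean blue fraction.
    """

    slope: float
    intercept: float
    r_squared: float
    chl_threshold: float
    n_points: int
    fitted: bool
    high_chl_mean: float  # mean blue fraction of samples >= threshold (NaN if none)
    n_high: int


def fit_tuning_trend(
    chl, blue_fraction, chl_threshold: float = 0.25
) -> TuningTrendModel:
    """Fit the low-chlorophyll spectral-tuning trend.

    Requires at least 3 samples below ``chl_threshold``; otherwise returns an
    un-fitted model with the flag cleared rather than raising.
    """
    chl = np.asarray(chl, dtype=float)
    blue = np.asarray(blue_fraction, dtype=float)
    if chl.shape != blue.shape or chl.ndim != 1:
        raise ValueError("chl and blue_fraction must be 1-D and of equal length")
    if (chl <= 0).any():
        raise ValueError("chlorophyll concentrations must be positive")
    ok = ~np.isnan(blue)
    low = (chl < chl_threshold) & ok
    high = (chl >= chl_threshold) & ok
    n_low = int(low.sum())
    n_high = int(high.sum())
    high_mean = float(blue[high].mean()) if n_high else float("nan")
    if n_low < 3:
        return TuningTrendModel(
            slope=float("nan"),
            intercept=float("nan"),
            r_squared=float("nan"),
            chl_threshold=chl_threshold,
            n_points=n_low,
            fitted=False,
            high_chl_mean=high_mean,
            n_high=n_high,
        )
    lx = np.log(chl[low])
    y = blue[low]
    mx = lx.mean()
    my = y.mean()
    sxx = float(((lx - mx) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("all low-chlorophyll samples share one chl value; slope undefined")
    slope = float(((lx - mx) * (y - my)).sum() / sxx)
    intercept = float(my - slope * mx)
    resid = y - (slope * lx + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - my) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return TuningTrendModel(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        chl_threshold=chl_threshold,
        n_points=n_low,
        fitted=True,
        high_chl_mean=high_mean,
        n_high=n_high,
    )
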