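"""Paired nonparametric statistics and JZS Bayes factors.

Coregistration and surface errors are strictly positive and right
skewed, so paired conditions are compared with the two-tailed Wilcoxon
signed-rank test.  Pairwise mean comparisons use Welch's unequal
variance t-test, and evidence for the null is quantified with the
Jeffreys-Zellner-Siow Bayes factor BF01 (Cauchy prior on the
standardized effect, default scale sqrt(2)/2 as in the BayesFactor
package's ttestBF).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

DEFAULT_RSCALE = math.sqrt(2.0) / 2.0
EXACT_WILCOXON_MAX_N = 25


@dataclass
class StatResult:
    statistic: float
    p_value: float
    n: int
    method: str
    df: float | None = None
    bf01: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------

def _exact_signed_rank_p(ranks2: np.ndarray, w_plus2: int) -> float:
    """Two-sided exact p for the signed-rank statistic.

    ``ranks2`` holds the mid-ranks doubled so ties become integers; the
    exact null distribution of the (doubled) positive-rank sum is built
    by the shift algorithm (dynamic-programming convolution over all
    2^n sign assignments).  Two-sided p doubles the smaller tail,
    capped at 1.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    cdf = float(counts[: w_plus2 + 1].sum())
    sf = float(counts[w_plus2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(x, y) -> StatResult:
    """Two-tailed Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped, tied absolute differences mid-ranked.
    The null distribution is exact (full sign enumeration via the shift
    algorithm) for n <= 25 remaining pairs and a normal approximation
    with continuity correction and tie-corrected variance above.  The
    reported statistic is the signed rank sum W+ - W-.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D samples")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if n < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = w_plus - w_minus
    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        p = _exact_signed_rank_p(ranks2, int(round(2.0 * w_plus)))
        method = "wilcoxon-exact"
    else:
        mean = ranks.sum() / 2.0
        sd = math.sqrt(float(np.sum(ranks**2)) / 4.0)
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / sd
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "wilcoxon-normal"
    return StatResult(statistic=statistic, p_value=p, n=n, method=method)


# ---------------------------------------------------------------------
# Welch / paired t
# ---------------------------------------------------------------------

def welch_t(x, y, paired: bool = False) -> StatResult:
    """Two-sided t-test: Welch's unequal-variance test, or the paired
    one-sample t on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test needs matched samples")
        d = x - y
        n = len(d)
        if n < 2:
            raise ValueError("need at least 2 pairs")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance of differences; test undefined")
        t = d.mean() / (sd / math.sqrt(n))
        df = float(n - 1)
        p = float(2.0 * stats.t.sf(abs(t), df))
        return StatResult(statistic=float(t), p_value=p, n=n, method="t-paired", df=df)
    n1, n2 = len(x), len(y)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 observations per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance in both groups; test undefined")
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return StatResult(
        statistic=float(t), p_value=p, n=n1 + n2, method="t-welch", df=float(df)
    )


# ---------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------

def jzs_bf01(t: float, n: int, rscale: float = DEFAULT_RSCALE) -> float:
    """JZS Bayes factor BF01 for a one-sample/paired t statistic.

    The alternative places a Cauchy(0, rscale) prior on the
    standardized effect size; its marginal likelihood is the Cauchy
    mixture of noncentral-t densities, integrated by adaptive
    quadrature.  BF01 > 1 favors the null.
    """
    if not np.isfinite(t):
        raise ValueError("t statistic must be finite")
    if n < 2:
        raise ValueError("need n >= 2")
    if rscale <= 0:
        raise ValueError("rscale must be positive")
    nu = n - 1
    sqrt_n = math.sqrt(n)
    m0 = stats.t.pdf(t, nu)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, nu, delta * sqrt_n) * stats.cauchy.pdf(
            delta, loc=0.0, scale=rscale
        )

    m1 = 0.0
    for a, b in ((-np.inf, 0.0), (0.0, np.inf)):
        val, _ = integrate.quad(integrand, a, b, epsabs=1e-12, epsrel=1e-10, limit=400)
        m1 += val
    if m1 <= 0:
        raise RuntimeError("marginal likelihood quadrature failed")
    return float(m0 / m1)
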