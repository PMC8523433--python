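"""Agreement, repeatability and group-comparison statistics.

Implements the validation/repeatability toolbox used for mosaic metrics:

* Bland–Altman agreement with limits of agreement (mean ± 1.96 sd of the
  paired differences) and a proportional-bias regression of difference on
  pairwise mean;
* ICC(2,1) — intraclass correlation for a two-way random-effects,
  absolute-agreement, single-measurement design, with the F-distribution
  confidence interval (McGraw–Wong construction);
* Friedman test with mid-rank tie correction;
* Wilcoxon signed-rank test, exact by enumeration for small untied samples,
  otherwise normal approximation with tie-corrected variance and continuity
  correction;
* Holm–Bonferroni step-down multiple-testing correction.

These are authored to a fixed, documented contract so results are
bit-reproducible; scipy/pingouin implementations serve as independent
cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary for paired measurements a vs b (d = a − b)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_statistic: float
    t_p: float
    prop_bias_slope: float
    prop_bias_p: float
    n: int


@dataclass(frozen=True)
class RepeatabilityResult:
    """ICC(2,1) with its 95% confidence bounds."""

    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_sessions: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Bland–Altman agreement analysis of two paired measurement series.

    Differences d = a − b are summarized by their mean, sd (n−1
    denominator) and limits of agreement mean ± 1.96·sd; a two-sided
    one-sample t-test checks mean(d) = 0 and an ordinary least-squares
    regression of d on (a+b)/2 checks for proportional bias.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("measurements must be finite")
    d = a - b
    means = (a + b) / 2.0
    if np.ptp(means) == 0:
        raise ValueError("zero variance in pairwise means; proportional-bias regression undefined")
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t, tp = sps.ttest_1samp(d, 0.0)
    reg = sps.linregress(means, d)
    slope_p = float(reg.pvalue) if np.isfinite(reg.pvalue) else float("nan")
    return AgreementResult(
        mean_diff=md,
        sd_diff=sd,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        t_statistic=float(t),
        t_p=float(tp),
        prop_bias_slope=float(reg.slope),
        prop_bias_p=slope_p,
        n=len(d),
    )


def _two_way_mean_squares(x: np.ndarray) -> Tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way layout (rows = subjects, cols = sessions)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0)


def icc_2way_random_single_absolute(
    x: np.ndarray, confidence: float = 0.95
) -> RepeatabilityResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``x`` is an n-subject × k-session table with no missing cells.  The
    point estimate is (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n);
    the confidence interval uses the F-distribution construction with
    Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be a 2-D table (subjects × sessions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if not np.all(np.isfinite(x)):
        raise ValueError("table must be complete (no missing values); no imputation")

    if np.all(x == x[:, [0]]) and np.ptp(x[:, 0]) > 0:
        # sessions agree exactly on a non-constant table: perfect agreement
        return RepeatabilityResult(icc=1.0, ci_low=1.0, ci_high=1.0, n_subjects=n, k_sessions=k)

    msr, msc, mse = _two_way_mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("zero total variance; ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0 and msc == 0:
        # perfect agreement: the interval construction degenerates
        return RepeatabilityResult(icc=icc, ci_low=icc, ci_high=icc, n_subjects=n, k_sessions=k)

    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    if not np.isfinite(v) or v <= 0:
        return RepeatabilityResult(icc=icc, ci_low=float("nan"), ci_high=float("nan"),
                                   n_subjects=n, k_sessions=k)
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return RepeatabilityResult(
        icc=float(icc), ci_low=float(lower), ci_high=float(upper),
        n_subjects=n, k_sessions=k,
    )


def friedman_test(x: np.ndarray) -> TestResult:
    """Friedman test on an n-block × k-treatment table.

    Within-block mid-ranks; the classic statistic
    12n/(k(k+1)) · Σ_j (R̄_j − (k+1)/2)² is divided by the standard tie
    correction 1 − Σ(t³−t)/(n·k·(k²−1)); p from χ² with k−1 df.  Blocks
    entirely tied contribute mid-ranks; if every block is fully tied the
    statistic is 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (blocks × treatments)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")

    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rbar = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * float(((rbar - (k + 1) / 2.0) ** 2).sum())

    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:
        return TestResult(statistic=0.0, p_value=1.0, n=n, method="friedman")
    stat /= correction
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult(statistic=float(stat), p_value=p, n=n, method="friedman")


def _exact_signed_rank_sf_table(ranks: np.ndarray) -> np.ndarray:
    """Null distribution of W+ over all sign assignments (integer ranks)."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classical treatment); |d| receives
    mid-ranks; the statistic is W = min(W+, W−).  The p-value is exact by
    enumeration over sign assignments for n ≤ 20 with untied magnitudes,
    otherwise a normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test degenerate")

    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    no_ties = len(np.unique(absd)) == n
    if n <= 20 and no_ties:
        pmf = _exact_signed_rank_sf_table(ranks)
        wp = int(round(w_plus))
        p_le = float(pmf[: wp + 1].sum())
        p_ge = float(pmf[wp:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "wilcoxon-exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_sum = 0.0
        _, counts = np.unique(absd, return_counts=True)
        tie_sum = float((counts**3 - counts).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_sum / 48.0
        if var <= 0:
            raise ValueError("zero variance under the null; test degenerate")
        z = (w - mean + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * float(sps.norm.cdf(z)))
        method = "wilcoxon-normal"
    return TestResult(statistic=w, p_value=p, n=n, method=method)


def holm_bonferroni(
    pvals: Sequence[float], alpha: float = 0.05
) -> Tuple[List[bool], List[float]]:
    """Holm–Bonferroni step-down correction.

    Returns (reject flags, adjusted p-values), both in input order.
    Adjusted p(i) is the running maximum of (m−i+1)·p(i) over the
    ascending-sorted sequence, capped at 1.
    """
    p = list(pvals)
    if any((pi < 0 or pi > 1) for pi in p):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    m = len(p)
    if m == 0:
        return [], []
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    reject = [False] * m
    running_max = 0.0
    still_rejecting = True
    for pos, idx in enumerate(order):
        factor = m - pos
        running_max = max(running_max, min(1.0, factor * p[idx]))
        adjusted[idx] = running_max
        if still_rejecting and p[idx] <= alpha / factor:
            reject[idx] = True
        else:
            still_rejecting = False
    return reject, adjusted
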