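"""Agreement statistics for delineation comparisons.

Conformity index (Jaccard overlap of two masks), descriptive pairwise CI
summaries, intraclass correlation (two-way random effects, absolute
agreement, single rater — ICC(2,1)) with its 95% lower confidence limit,
paired t / Wilcoxon tests, the Friedman test with Holm-corrected pairwise
Wilcoxon post-hocs, Bland-Altman statistics, and relative volume variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volumes import BinaryMask


@dataclass
class PairwiseCIStats:
    """Descriptive summary of conformity indices over a case series."""

    pair: str
    n: int
    mean: float
    sd: float
    se: float
    min: float
    max: float
    t_p: float
    wilcoxon_p: float


@dataclass
class IccResult:
    icc: float
    ci95_lower: float


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def conformity_index(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection volume over union volume of two masks on one grid.

    Equals the Jaccard index; 1 for identical masks, 0 for disjoint ones.
    Raises for a grid mismatch (resample explicitly first) or when both
    masks are empty (the ratio is undefined).
    """
    if a.grid != b.grid:
        raise ValueError("masks must share a grid; resample one explicitly first")
    inter = int(np.count_nonzero(a.member & b.member))
    union = int(np.count_nonzero(a.member | b.member))
    if union == 0:
        raise ValueError("conformity index is undefined for two empty masks")
    return inter / union


def ci_summary(cis: np.ndarray, pair: str = "") -> PairwiseCIStats:
    """Summarize per-case conformity indices and test H0: mean = 1.

    The one-sample t-test and the Wilcoxon signed-rank test are run against
    1 (perfect conformity). When every CI equals 1 both tests are degenerate
    (zero variance / all-zero differences) and are reported as p = 1.
    """
    cis = np.asarray(cis, dtype=float)
    n = cis.size
    if n < 1:
        raise ValueError("need at least one case")
    mean = float(cis.mean())
    sd = float(cis.std(ddof=1)) if n > 1 else 0.0
    diffs = cis - 1.0
    if np.allclose(diffs, 0.0) or sd == 0.0:
        t_p = w_p = 1.0
        if sd == 0.0 and not np.allclose(diffs, 0.0):
            t_p = 0.0  # constant, but away from 1: difference is exact
            w_p = float(stats.wilcoxon(diffs).pvalue) if n > 1 else 1.0
    else:
        t_p = float(stats.ttest_1samp(cis, 1.0).pvalue)
        w_p = float(stats.wilcoxon(diffs, zero_method="wilcox").pvalue)
    return PairwiseCIStats(
        pair=pair, n=n, mean=mean, sd=sd, se=sd / np.sqrt(n),
        min=float(cis.min()), max=float(cis.max()), t_p=t_p, wilcoxon_p=w_p,
    )


def icc_agreement(matrix: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``matrix`` is cases x methods and must be complete with at least 2 rows
    and 2 columns. The confidence limit follows the standard F-based
    interval; only the lower limit is reported (the conventional
    presentation for agreement tables).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete cases x methods matrix, >= 2 each")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be complete (finite)")
    if np.ptp(m) == 0:
        raise ValueError("constant matrix: ICC undefined (zero variance)")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 0.0

    # F-based lower limit (Satterthwaite df for the column/error mixture)
    if 1 - icc <= 0:
        lower = 1.0
    else:
        a = k * icc / (n * (1 - icc))
        b = 1 + k * icc * (n - 1) / (n * (1 - icc))
        num_v = (a * msc + b * mse) ** 2
        den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        lower = (
            n * (msr - f1 * mse)
            / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
    lower = float(min(lower, icc))
    return IccResult(icc=float(icc), ci95_lower=lower)


def paired_tests(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t and Wilcoxon signed-rank p-values.

    Zero differences follow the standard drop-zeros convention; identical
    series are degenerate and reported as p = 1 for both tests. A constant
    non-zero shift has zero variance: the t statistic is undefined and an
    error is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D series with n >= 2")
    d = x - y
    if np.allclose(d, 0.0):
        return 1.0, 1.0
    if np.std(d, ddof=1) == 0:
        raise ValueError("constant non-zero paired difference: t undefined")
    t_p = float(stats.ttest_rel(x, y).pvalue)
    w_p = float(stats.wilcoxon(d[d != 0], zero_method="wilcox").pvalue)
    return t_p, w_p


def friedman_test(matrix: np.ndarray) -> tuple[float, list[dict]]:
    """Friedman chi-square test across >= 3 methods, plus Holm-corrected
    pairwise Wilcoxon post-hocs.

    Returns ``(p, posthoc)`` where ``posthoc`` lists, for every method
    pair, the raw and Holm-adjusted Wilcoxon p. Identical columns give a
    zero statistic (p = 1); with fewer than 3 methods a paired test should
    be used instead and an error is raised.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("Friedman needs >= 3 methods; use paired_tests for 2")
    cols = [m[:, j] for j in range(m.shape[1])]
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        return 1.0, []
    p = float(stats.friedmanchisquare(*cols).pvalue)

    pairs = []
    for i in range(m.shape[1]):
        for j in range(i + 1, m.shape[1]):
            d = m[:, i] - m[:, j]
            if np.allclose(d, 0.0):
                wp = 1.0
            else:
                wp = float(stats.wilcoxon(d[d != 0], zero_method="wilcox").pvalue)
            pairs.append({"i": i, "j": j, "p_raw": wp})
    order = np.argsort([pr["p_raw"] for pr in pairs], kind="stable")
    mtot = len(pairs)
    running = 0.0
    for rank, oi in enumerate(order):
        adj = min(1.0, (mtot - rank) * pairs[oi]["p_raw"])
        running = max(running, adj)
        pairs[oi]["p_holm"] = running
    return p, pairs


def bland_altman(before: np.ndarray, after: np.ndarray) -> BlandAltman:
    """Bland-Altman agreement of paired measurements (after - before)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1 or before.size < 1:
        raise ValueError("need two equal-length 1-D series")
    diffs = after - before
    means = (after + before) / 2.0
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return BlandAltman(
        mean_diff=md, sd_diff=sd,
        loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd,
        means=means, diffs=diffs,
    )


def relative_volume_variation(v_ref: float, v_new: float) -> float:
    """Absolute relative volume change in percent: 100 |v_new - v_ref| / v_ref."""
    if v_ref <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * abs(v_new - v_ref) / v_ref
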