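"""Inferential tests: two-sided Brunner-Munzel and two-tailed Fisher's exact.

The Brunner-Munzel test compares two samples through the relative effect
``p = P(X < Y) + 0.5 P(X = Y)`` with a studentised statistic and
Satterthwaite-approximated degrees of freedom; it does not assume equal
variances or distribution shapes.  Fisher's exact test on 2x2 tables uses
the two-tailed sum-of-smaller-probabilities convention, with a conditional
maximum-likelihood odds ratio and exact confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio


@dataclass
class TestResult:
    statistic: float
    p_value: float
    effect: float  # relative effect (BM) or odds ratio (Fisher)
    ci: tuple[float, float]
    n: tuple[int, ...]
    degenerate: bool = False


def _relative_effect(x: np.ndarray, y: np.ndarray) -> float:
    """p_hat = P(X < Y) + 0.5 P(X = Y) via mid-ranks."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    ry = ranks[len(x):].mean()
    return (ry - (len(y) + 1) / 2) / len(x)


def brunner_munzel(x, y, alpha: float = 0.05,
                   method: str = "t", n_permutations: int = 10_000,
                   rng: np.random.Generator | None = None) -> TestResult:
    """Two-sided Brunner-Munzel rank test.

    ``method='t'`` uses the t-approximation with Satterthwaite degrees of
    freedom (the default, appropriate at the sample sizes this pipeline
    produces); ``method='permutation'`` estimates the null distribution of
    the studentised statistic by permutation, recommended below n ~ 10 per
    group.  Identical samples, or samples with zero rank variance in both
    groups, return the degenerate result ``p_hat = 0.5, p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    p_hat = _relative_effect(x, y)
    n = (len(x), len(y))

    # rank variances (degenerate when both are zero, e.g. all-tied data)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    rx, ry = ranks[:len(x)], ranks[len(x):]
    rx_in = sps.rankdata(x)
    ry_in = sps.rankdata(y)
    sx2 = np.var(rx - rx_in, ddof=1) if len(x) > 1 else 0.0
    sy2 = np.var(ry - ry_in, ddof=1) if len(y) > 1 else 0.0
    if sx2 == 0 and sy2 == 0:
        return TestResult(statistic=0.0, p_value=1.0, effect=p_hat,
                          ci=(p_hat, p_hat), n=n, degenerate=True)

    res = sps.brunnermunzel(x, y, alternative="two-sided", distribution="t")
    stat, p = float(res.statistic), float(res.pvalue)

    # s.e. of the relative effect, for the CI
    nx, ny = n
    se = np.sqrt(sx2 / (nx * ny ** 2) + sy2 / (ny * nx ** 2))

    if method == "permutation":
        rng = rng or np.random.default_rng(0)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(combined)
            px, py = perm[:nx], perm[nx:]
            r = sps.brunnermunzel(px, py, alternative="two-sided", distribution="t")
            if np.isnan(r.statistic):
                continue
            if abs(r.statistic) >= abs(stat):
                count += 1
        p = (count + 1) / (n_permutations + 1)

    # t-quantile CI on the relative effect
    df = _satterthwaite_df(sx2, sy2, nx, ny)
    tq = sps.t.ppf(1 - alpha / 2, df) if np.isfinite(df) and df > 0 else sps.norm.ppf(1 - alpha / 2)
    ci = (max(0.0, p_hat - tq * se), min(1.0, p_hat + tq * se))
    return TestResult(statistic=stat, p_value=p, effect=p_hat, ci=ci, n=n)


def _satterthwaite_df(sx2: float, sy2: float, nx: int, ny: int) -> float:
    num = (sx2 / nx + sy2 / ny) ** 2
    den = (sx2 / nx) ** 2 / (nx - 1) + (sy2 / ny) ** 2 / (ny - 1)
    return num / den if den > 0 else np.inf


def fisher_exact(table, alpha: float = 0.05) -> TestResult:
    """Two-tailed Fisher's exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities no larger than that of the
    observed table at fixed margins; the effect is the conditional-MLE odds
    ratio with its exact (conditional-likelihood) confidence interval.
    Tables with a zero margin return a degenerate result (OR = 1, p = 1).
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    n = tuple(int(v) for v in table.sum(axis=1))
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return TestResult(statistic=np.nan, p_value=1.0, effect=1.0,
                          ci=(0.0, np.inf), n=n, degenerate=True)
    _, p = sps.fisher_exact(table, alternative="two-sided")
    orr = _odds_ratio(table, kind="conditional")
    ci = orr.confidence_interval(confidence_level=1 - alpha)
    return TestResult(statistic=float(orr.statistic), p_value=float(p),
                      effect=float(orr.statistic),
                      ci=(float(ci.low), float(ci.high)), n=n)


def bonferroni_adjust(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance level: alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def significance_marker(p: float) -> str:
    """Banded significance markers: ns, *, **, ***."""
    if p > 0.01:
        return "ns"
    if p > 0.001:
        return "*"
    if p > 0.0001:
        return "**"
    return "***"
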