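"""Univariate and multivariate normality tests.

The closed-form selection-index theory (index moments, response, MSPE)
assumes joint multivariate normality of the merit and its predictors; this
module provides the tests used to check that assumption on traits, GEBVs,
residuals and (H_q, index) pairs:

* Shapiro-Wilk (univariate, one-sided) — delegated to scipy.
* Mardia's multivariate skewness and kurtosis (two-sided kurtosis).
* Henze-Zirkler's smooth test with the standard bandwidth ``beta(n, d)`` and
  the log-normal approximation for the p-value.

Royston and Henze-Wagner appear in the report schema for completeness but
are not implemented. All multivariate statistics are affine invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NormalityReport",
    "mardia_test",
    "henze_zirkler_test",
    "shapiro_univariate",
    "bivariate_merit_normality",
]

KNOWN_TESTS = (
    "shapiro_wilk",
    "mardia_skewness",
    "mardia_kurtosis",
    "henze_zirkler",
    "royston",       # reserved, not implemented
    "henze_wagner",  # reserved, not implemented
)


@dataclass
class NormalityReport:
    dataset: str
    test: str
    statistic: float
    p_value: float
    n: int
    d: int
    sided: str = "one-sided"

    def __post_init__(self) -> None:
        if self.test not in KNOWN_TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _validated(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, int]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an n x d matrix")
    n, d = X.shape
    if n <= d:
        raise ValueError("need more observations than dimensions")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n  # ML covariance, the classical convention for both tests
    evals = np.linalg.eigvalsh(S)
    if evals.min() <= 0 or evals.min() / evals.max() < 1e-12:
        raise ValueError("singular sample covariance")
    return Xc, S, n, d


def mardia_test(X: np.ndarray, dataset: str = "") -> list[NormalityReport]:
    """Mardia's multivariate skewness and kurtosis tests.

    Skewness: ``b1 = mean over pairs of (x_i' S^-1 x_j)^3`` with
    ``n b1 / 6 ~ chi2`` on ``d(d+1)(d+2)/6`` df (one-sided).
    Kurtosis: ``b2 = mean of squared Mahalanobis norms`` with the asymptotic
    normal reference ``(b2 - d(d+2)) / sqrt(8 d (d+2) / n)`` (two-sided).
    """
    Xc, S, n, d = _validated(X)
    A = Xc @ np.linalg.solve(S, Xc.T)
    b1 = float(np.mean(A**3))
    stat_skew = n * b1 / 6.0
    df = d * (d + 1) * (d + 2) / 6.0
    p_skew = float(stats.chi2.sf(stat_skew, df))
    di = np.diag(A)
    b2 = float(np.mean(di**2))
    stat_kurt = (b2 - d * (d + 2)) / np.sqrt(8.0 * d * (d + 2) / n)
    p_kurt = float(2.0 * stats.norm.sf(abs(stat_kurt)))
    return [
        NormalityReport(dataset, "mardia_skewness", stat_skew, p_skew, n, d, "one-sided"),
        NormalityReport(dataset, "mardia_kurtosis", float(stat_kurt), p_kurt, n, d, "two-sided"),
    ]


def henze_zirkler_test(X: np.ndarray, dataset: str = "") -> NormalityReport:
    """Henze-Zirkler test with the standard smoothing parameter beta(n, d)."""
    Xc, S, n, d = _validated(X)
    A = Xc @ np.linalg.solve(S, Xc.T)
    di = np.diag(A)
    Dij = di[:, None] + di[None, :] - 2.0 * A
    b = ((2.0 * d + 1.0) * n / 4.0) ** (1.0 / (d + 4.0)) / np.sqrt(2.0)
    b2 = b * b
    term1 = np.mean(np.exp(-0.5 * b2 * Dij))
    term2 = 2.0 * (1.0 + b2) ** (-d / 2.0) * np.mean(np.exp(-b2 * di / (2.0 * (1.0 + b2))))
    hz = n * (term1 - term2 + (1.0 + 2.0 * b2) ** (-d / 2.0))

    # log-normal approximation to the null distribution
    a = 1.0 + 2.0 * b2
    wb = (1.0 + b2) * (1.0 + 3.0 * b2)
    mu = 1.0 - a ** (-d / 2.0) * (1.0 + d * b2 / a + d * (d + 2.0) * b2**2 / (2.0 * a**2))
    si2 = (
        2.0 * (1.0 + 4.0 * b2) ** (-d / 2.0)
        + 2.0 * a ** (-d)
        * (1.0 + 2.0 * d * b2**2 / a**2 + 3.0 * d * (d + 2.0) * b2**4 / (4.0 * a**4))
        - 4.0 * wb ** (-d / 2.0)
        * (1.0 + 3.0 * d * b2**2 / (2.0 * wb) + d * (d + 2.0) * b2**4 / (2.0 * wb**2))
    )
    pmu = np.log(np.sqrt(mu**4 / (si2 + mu**2)))
    psi = np.sqrt(np.log1p(si2 / mu**2))
    p = float(stats.lognorm.sf(hz, psi, scale=np.exp(pmu)))
    return NormalityReport(dataset, "henze_zirkler", float(hz), p, n, d, "one-sided")


def shapiro_univariate(x: np.ndarray, dataset: str = "") -> NormalityReport:
    """Shapiro-Wilk W test for a single variable (scipy implementation)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: normality test undefined")
    w, p = stats.shapiro(x)
    return NormalityReport(dataset, "shapiro_wilk", float(w), float(p), x.size, 1, "one-sided")


def bivariate_merit_normality(
    hq: np.ndarray, index_scores: np.ndarray, dataset: str = ""
) -> list[NormalityReport]:
    """Joint bivariate normality of (H_q, index): Mardia + Henze-Zirkler.

    The reports carry p-values only; the decision (credibility of joint
    normality) is left to the reader at their chosen level.
    """
    hq = np.asarray(hq, dtype=float).ravel()
    scores = np.asarray(index_scores, dtype=float).ravel()
    if hq.size != scores.size:
        raise ValueError("hq and index scores must be aligned")
    X = np.column_stack([hq, scores])
    return mardia_test(X, dataset) + [henze_zirkler_test(X, dataset)]
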