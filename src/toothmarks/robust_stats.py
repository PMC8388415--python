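"""Univariate gating, robust descriptives, equivalence testing, correlations.

Workflow for each linear tooth-score measurement (WIS, WIM, WIB, D, LDC, RDC):

1. gate the distribution with a Shapiro-Wilk test at the three-sigma evidence
   threshold (p < 0.003 -> non-Gaussian -> robust branch);
2. describe with mean/SD (Gaussian) or median/sqrt(biweight midvariance)
   (robust);
3. compare groups by *equivalence* testing (TOST): the null hypothesis states
   the groups DIFFER by at least the margin, so a small p is evidence of
   equivalence.  The parametric variant uses Welch's t; the robust variant
   (rTOST) uses Yuen's trimmed t.  The equivalence margin epsilon is expressed
   in Cohen's d units (default 0.2, a small effect).

Multivariate equivalence applies rTOST per retained principal component
(components explaining up to 95% of pooled variance), reporting the PC-wise
maximum p and the summed |d|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .results import TestResult

__all__ = [
    "MetricSample",
    "Descriptives",
    "EquivalenceResult",
    "normality_test",
    "is_gaussian",
    "bwmv",
    "describe",
    "tost",
    "tost_multivariate",
    "correlation",
    "NORMALITY_THRESHOLD",
]

#: Shapiro-Wilk gate: three standard deviations from the mean (0.3%).
NORMALITY_THRESHOLD = 0.003


@dataclass
class MetricSample:
    """Measurements of one variable for one group (mm)."""

    values: np.ndarray
    variable: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("measurements must be finite")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Descriptives:
    min: float
    max: float
    central: float
    deviation: float
    robust: bool


@dataclass(frozen=True)
class EquivalenceResult:
    """TOST outcome: |d|, p (small p => evidence of equivalence), margin."""

    d: float
    p: float
    method: str
    epsilon: float
    df: float = float("nan")


def _values(x) -> np.ndarray:
    if isinstance(x, MetricSample):
        return x.values
    return np.asarray(x, dtype=float)


# -- gating ------------------------------------------------------------------

def normality_test(x: MetricSample | Sequence[float]) -> TestResult:
    """Shapiro-Wilk test of normality."""
    v = _values(x)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: normality undefined")
    w, p = stats.shapiro(v)
    return TestResult(statistic=float(w), p=float(p), method="shapiro_wilk")


def is_gaussian(x, threshold: float = NORMALITY_THRESHOLD) -> bool:
    """True if the Shapiro-Wilk gate does not reject at the 0.003 threshold."""
    return normality_test(x).p >= threshold


# -- descriptives ------------------------------------------------------------

def bwmv(x, c: float = 9.0) -> float:
    """Biweight midvariance: an outlier-resistant variance estimator.

    Deviations are standardised by ``c * MAD`` (tuning constant c = 9);
    observations beyond that band get zero weight.
    """
    v = _values(x)
    n = v.size
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return 0.0
    u = (v - med) / (c * mad)
    mask = np.abs(u) < 1.0
    num = n * np.sum(((v - med) ** 2 * (1 - u ** 2) ** 4)[mask])
    den = np.sum(((1 - u ** 2) * (1 - 5 * u ** 2))[mask]) ** 2
    return float(num / den)


def describe(x: MetricSample | Sequence[float], robust: bool) -> Descriptives:
    """Mean/SD (robust=False) or median/sqrt(BWMV) (robust=True)."""
    v = _values(x)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if robust:
        central = float(np.median(v))
        dev = math.sqrt(bwmv(v))
    else:
        central = float(np.mean(v))
        dev = float(np.std(v, ddof=1))
    return Descriptives(min=float(v.min()), max=float(v.max()),
                        central=central, deviation=dev, robust=robust)


# -- equivalence (TOST) ------------------------------------------------------

def _trimmed_stats(v: np.ndarray, trim: float) -> tuple[float, float, int]:
    """(trimmed mean, winsorised variance, effective n after trimming)."""
    n = v.size
    g = int(math.floor(trim * n))
    if n - 2 * g < 2:
        raise ValueError("sample too small after trimming")
    vs = np.sort(v)
    tmean = float(vs[g:n - g].mean())
    w = vs.copy()
    w[:g] = vs[g]
    w[n - g:] = vs[n - g - 1]
    wvar = float(np.var(w, ddof=1))
    return tmean, wvar, n - 2 * g


def tost(
    x: MetricSample | Sequence[float],
    y: MetricSample | Sequence[float],
    epsilon: float = 0.2,
    method: Literal["welch", "yuen"] = "welch",
    trim: float = 0.2,
    seed: int | None = None,
) -> EquivalenceResult:
    """Two one-sided equivalence tests with margin epsilon in Cohen's d units.

    The null hypothesis is |difference| >= epsilon * scale (groups differ);
    p is the larger of the two one-sided p-values, so small p supports
    equivalence.  ``welch`` uses means and Welch's t; ``yuen`` uses trimmed
    means and winsorised variances (robust).  ``seed`` is accepted for
    interface symmetry with the randomisation tests; both variants here are
    deterministic.
    """
    del seed
    vx, vy = _values(x), _values(y)
    n1, n2 = vx.size, vy.size
    if n1 < 5 or n2 < 5:
        raise ValueError("TOST requires n >= 5 per group")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not 0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")

    if method == "welch":
        m1, m2 = vx.mean(), vy.mean()
        s1, s2 = vx.var(ddof=1), vy.var(ddof=1)
        if s1 == 0 and s2 == 0:
            raise ValueError("degenerate variance in both samples")
        scale = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
        se = math.sqrt(s1 / n1 + s2 / n2)
        df = (s1 / n1 + s2 / n2) ** 2 / (
            (s1 / n1) ** 2 / (n1 - 1) + (s2 / n2) ** 2 / (n2 - 1)
        )
    elif method == "yuen":
        m1, w1, h1 = _trimmed_stats(vx, trim)
        m2, w2, h2 = _trimmed_stats(vy, trim)
        if w1 == 0 and w2 == 0:
            raise ValueError("degenerate variance in both samples")
        scale = math.sqrt(((n1 - 1) * w1 + (n2 - 1) * w2) / (n1 + n2 - 2))
        d1 = (n1 - 1) * w1 / (h1 * (h1 - 1))
        d2 = (n2 - 1) * w2 / (h2 * (h2 - 1))
        se = math.sqrt(d1 + d2)
        df = (d1 + d2) ** 2 / (d1 ** 2 / (h1 - 1) + d2 ** 2 / (h2 - 1))
    else:
        raise ValueError(f"unknown method: {method!r}")

    diff = m1 - m2
    margin = epsilon * scale
    if se == 0:
        p = 0.0 if abs(diff) < margin else 1.0
        return EquivalenceResult(d=abs(diff) / scale if scale else 0.0, p=p,
                                 method=method, epsilon=epsilon, df=float("inf"))
    t_lower = (diff + margin) / se   # H0: diff <= -margin
    t_upper = (diff - margin) / se   # H0: diff >= +margin
    p_lower = stats.t.sf(t_lower, df)
    p_upper = stats.t.cdf(t_upper, df)
    p = float(max(p_lower, p_upper))
    d = abs(diff) / scale if scale > 0 else 0.0
    return EquivalenceResult(d=float(d), p=p, method=method,
                             epsilon=epsilon, df=float(df))


def tost_multivariate(
    X: np.ndarray,
    Y: np.ndarray,
    epsilon: float = 0.2,
    method: Literal["welch", "yuen"] = "yuen",
    trim: float = 0.2,
    var_explained: float = 0.95,
) -> dict:
    """Equivalence across retained principal components of pooled data.

    PCA (covariance, centred) is fit on the stacked groups; components are
    retained up to ``var_explained`` of total variance.  TOST runs per
    component; the aggregate reports the PC-wise maximum p (the weakest
    equivalence claim) and the summed |d|.  The aggregation rule is a package
    convention and is recorded in the output.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("groups must share a feature space")
    pooled = np.vstack([X, Y])
    mean = pooled.mean(axis=0)
    centred = pooled - mean
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    var = svals ** 2
    frac = var / var.sum()
    keep = int(np.searchsorted(np.cumsum(frac), var_explained) + 1)
    keep = min(keep, len(frac))
    scores = centred @ vt[:keep].T
    sx, sy = scores[: X.shape[0]], scores[X.shape[0]:]
    per_pc = [
        tost(sx[:, j], sy[:, j], epsilon=epsilon, method=method, trim=trim)
        for j in range(keep)
    ]
    return {
        "per_pc": per_pc,
        "n_components": keep,
        "variance_explained": float(np.cumsum(frac)[keep - 1]),
        "p": max(r.p for r in per_pc),
        "d": sum(r.d for r in per_pc),
        "aggregation": "max p over PCs; summed |d| (package convention)",
    }


# -- correlations ------------------------------------------------------------

def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "kendall"] = "kendall",
) -> TestResult:
    """Pearson r (parametric) or Kendall tau (rank-based), two-sided."""
    vx, vy = _values(x), _values(y)
    if vx.size != vy.size:
        raise ValueError("x and y must have equal length")
    if vx.size < 5:
        raise ValueError("correlation requires n >= 5")
    if method == "pearson":
        r, p = stats.pearsonr(vx, vy)
    elif method == "kendall":
        r, p = stats.kendalltau(vx, vy)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return TestResult(statistic=float(r), p=float(p), method=method)
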