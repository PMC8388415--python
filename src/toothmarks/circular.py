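"""Circular statistics for tooth-score opening angles.

Opening angles behave as directional data on the circle and are treated with
the trigonometric toolkit: mean/median directions, circular variance
(v = 1 - mean resultant length), standardised skew and kurtosis from the
second central trigonometric moment, the Rayleigh uniformity test, a robust
reflective-symmetry test about the median direction, and three two-sample
randomisation tests:

* ``watson_mean`` -- a bootstrapped version of Watson's large-sample test for
  a common mean direction (statistic Y_g);
* ``fisher_median`` -- the randomised variant of Fisher's nonparametric test
  for a common median direction (statistic P_g);
* ``mww_distribution`` -- the randomised Mardia-Watson-Wheeler uniform-scores
  test for a common distribution (statistic W_g).

All angles are handled in radians internally and in degrees at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .results import TestResult

__all__ = [
    "AngleSample",
    "CircularSummary",
    "circ_descriptives",
    "rayleigh_test",
    "symmetry_test",
    "circ_two_sample",
]

TWO_PI = 2.0 * math.pi


class InsufficientDataError(ValueError):
    pass


@dataclass
class AngleSample:
    """A sample of angles, stored wrapped to [0, 2*pi) radians."""

    radians: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.radians, dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        self.radians = np.mod(a, TWO_PI)

    @classmethod
    def from_degrees(cls, degrees: Sequence[float], label: str = "") -> "AngleSample":
        return cls(np.deg2rad(np.asarray(degrees, dtype=float)), label)

    @property
    def degrees(self) -> np.ndarray:
        return np.rad2deg(self.radians)

    @property
    def n(self) -> int:
        return self.radians.size


@dataclass(frozen=True)
class CircularSummary:
    """Descriptives for one angle sample (directions in degrees)."""

    theta_bar: float      # mean direction
    theta_tilde: float    # median direction
    v: float              # sample circular variance, 1 - Rbar
    k_hat: float          # standardised kurtosis
    s_hat: float          # standardised skew
    min: float            # minimum angle
    n: int


# -- internals --------------------------------------------------------------

def _mean_direction(a: np.ndarray) -> tuple[float, float]:
    """(mean direction, mean resultant length Rbar)."""
    c, s = np.mean(np.cos(a)), np.mean(np.sin(a))
    return math.atan2(s, c), math.hypot(c, s)


def _circ_dist(a: np.ndarray, b: float) -> np.ndarray:
    """Circular distance pi - |pi - |a - b||, in [0, pi]."""
    d = np.abs(np.mod(a - b, TWO_PI))
    return np.pi - np.abs(np.pi - d)


def circular_median(a: np.ndarray) -> float:
    """Direction minimising the mean circular distance to the sample.

    For even n (or tied minima) the midpoint direction of the minimising data
    directions is used, with ties broken toward the mean direction.
    """
    a = np.asarray(a, dtype=float)
    obj = np.array([_circ_dist(a, phi).mean() for phi in a])
    best = obj.min()
    cands = np.unique(np.mod(a[obj <= best + 1e-12], TWO_PI))
    if cands.size == 1:
        return float(cands[0])
    c = np.mean(np.cos(cands))
    s = np.mean(np.sin(cands))
    mu, _ = _mean_direction(a)
    if math.hypot(c, s) < 1e-12:  # antipodal tie: break toward mean direction
        return float(np.mod(mu, TWO_PI))
    mid = math.atan2(s, c)
    # the resultant midpoint and its antipode both bisect; keep the better one
    alt = mid + math.pi
    d_mid = _circ_dist(a, mid).mean()
    d_alt = _circ_dist(a, alt).mean()
    if d_alt < d_mid - 1e-12 or (
        abs(d_alt - d_mid) <= 1e-12
        and _circ_dist(np.array([alt]), mu)[0] < _circ_dist(np.array([mid]), mu)[0]
    ):
        mid = alt
    return float(np.mod(mid, TWO_PI))


def _trig_moment(a: np.ndarray, p: int, center: float) -> tuple[float, float]:
    """p-th trigonometric moment about ``center``: (cos part, sin part)."""
    return (float(np.mean(np.cos(p * (a - center)))),
            float(np.mean(np.sin(p * (a - center)))))


# -- descriptives ------------------------------------------------------------

def circ_descriptives(sample: AngleSample) -> CircularSummary:
    """Mean/median direction, circular variance, standardised skew/kurtosis.

    Skew and kurtosis follow the standardised forms
    ``s_hat = b2 / (1 - Rbar)^{3/2}`` and
    ``k_hat = (a2 - Rbar^4) / (1 - Rbar)^2`` where (a2, b2) is the second
    trigonometric moment about the mean direction.
    """
    if sample.n < 2:
        raise InsufficientDataError("need at least 2 angles")
    a = sample.radians
    mu, rbar = _mean_direction(a)
    v = 1.0 - rbar
    a2, b2 = _trig_moment(a, 2, mu)
    if v > 1e-12:
        s_hat = b2 / v ** 1.5
        k_hat = (a2 - rbar ** 4) / v ** 2
    else:  # degenerate: all mass at one direction
        s_hat = 0.0
        k_hat = 0.0
    med = circular_median(a)
    return CircularSummary(
        theta_bar=float(np.mod(math.degrees(mu), 360.0)),
        theta_tilde=float(np.mod(math.degrees(med), 360.0)),
        v=float(v),
        k_hat=float(k_hat),
        s_hat=float(s_hat),
        min=float(np.min(sample.degrees)),
        n=sample.n,
    )


# -- one-sample tests --------------------------------------------------------

def rayleigh_test(sample: AngleSample) -> TestResult:
    """Rayleigh test of circular uniformity; statistic is Rbar."""
    if sample.n < 5:
        raise InsufficientDataError("Rayleigh test needs n >= 5")
    n = sample.n
    _, rbar = _mean_direction(sample.radians)
    z = n * rbar ** 2
    # large-sample series approximation (Zar / Fisher)
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z ** 2) / (4.0 * n)
        - (24.0 * z - 132.0 * z ** 2 + 76.0 * z ** 3 - 9.0 * z ** 4) / (288.0 * n ** 2)
    )
    p = min(max(p, 0.0), 1.0)
    return TestResult(statistic=float(rbar), p=p, method="rayleigh")


def symmetry_test(sample: AngleSample, reps: int = 1999) -> TestResult:
    """Robust test of reflective symmetry about the median direction.

    The statistic is the standardised second sine moment of the deviations
    from the circular median, b2 = mean sin 2(theta - median).  Under
    reflective symmetry a deviation and its mirror image are exchangeable, so
    the null distribution is generated by randomly reflecting the deviations
    (sign-flipping), which calibrates the test without distributional
    assumptions.  The reported statistic is b2 standardised by the
    reflection-null spread; p is two-sided, (exceedances + 1) / (reps + 1).
    The reflection draw is internally derandomised so results are
    reproducible.
    """
    if sample.n < 10:
        raise InsufficientDataError("symmetry test needs n >= 10")
    a = sample.radians
    n = sample.n
    med = circular_median(a)
    dev = np.mod(a - med + math.pi, TWO_PI) - math.pi  # deviations in (-pi, pi]
    s2 = np.sin(2.0 * dev)
    b2 = float(s2.mean())
    rng = np.random.default_rng(abs(hash((n, round(b2, 12)))) % (2 ** 31))
    signs = rng.choice([-1.0, 1.0], size=(reps, n))
    flipped = signs * dev[None, :]
    # re-centre every replicate on its own median so the null distribution
    # reflects median re-estimation, not just the raw sine moment
    flipped = flipped - np.median(flipped, axis=1, keepdims=True)
    null = np.sin(2.0 * flipped).mean(axis=1)
    spread = float(null.std())
    z = b2 / spread if spread > 0 else 0.0
    p = (np.sum(np.abs(null) >= abs(b2) - 1e-15) + 1) / (reps + 1)
    return TestResult(statistic=float(z), p=float(min(p, 1.0)),
                      method="reflective_symmetry_randomised")


# -- two-sample randomisation tests ------------------------------------------

def _watson_Y(groups: list[np.ndarray]) -> float:
    """Watson's large-sample statistic for a common mean direction."""
    W = C = S = 0.0
    for g in groups:
        mu, rbar = _mean_direction(g)
        a2, _ = _trig_moment(g, 2, mu)
        disp = (1.0 - a2) / (2.0 * max(rbar, 1e-12) ** 2)  # circular dispersion
        sigma2 = max(disp / g.size, 1e-12)
        w = 1.0 / sigma2
        W += w
        C += w * math.cos(mu)
        S += w * math.sin(mu)
    return 2.0 * (W - math.hypot(C, S))


def _fisher_P(groups: list[np.ndarray], median: float) -> float:
    """Fisher's common-median statistic P_g given the pooled median."""
    N = sum(g.size for g in groups)
    m_total = 0.0
    term = 0.0
    ms = []
    for g in groups:
        # count observations in the half-circle (median, median + pi)
        d = np.mod(g - median, TWO_PI)
        m = int(np.sum((d > 0) & (d < math.pi)))
        ms.append(m)
        m_total += m
    M = m_total
    if M == 0 or M == N:
        return 0.0
    for g, m in zip(groups, ms):
        term += m ** 2 / g.size
    return (N ** 2 / (M * (N - M))) * term - N * M / (N - M)


def _mww_W(groups: list[np.ndarray]) -> float:
    """Mardia-Watson-Wheeler uniform-scores statistic W_g."""
    pooled = np.concatenate(groups)
    N = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(N)
    ranks[order] = np.arange(1, N + 1)
    beta = TWO_PI * ranks / N
    W = 0.0
    start = 0
    for g in groups:
        b = beta[start:start + g.size]
        W += (np.cos(b).sum() ** 2 + np.sin(b).sum() ** 2) / g.size
        start += g.size
    return 2.0 * W


Method = Literal["watson_mean", "fisher_median", "mww_distribution"]


def circ_two_sample(
    a: AngleSample,
    b: AngleSample,
    method: Method,
    reps: int = 9999,
    seed: int | None = None,
) -> TestResult:
    """Two-sample randomisation test on the circle.

    ``watson_mean`` bootstraps Watson's Y statistic under a common mean
    (groups recentred to mean direction zero, resampled within groups);
    ``fisher_median`` and ``mww_distribution`` permute group labels.
    p = (exceedances + 1) / (reps + 1); bit-reproducible under a fixed seed.
    """
    if a.n < 8 or b.n < 8:
        raise InsufficientDataError("two-sample circular tests need n >= 8 per group")
    if reps < 99:
        raise ValueError("reps must be >= 99")
    rng = np.random.default_rng(seed)
    ga, gb = a.radians, b.radians

    if method == "watson_mean":
        observed = _watson_Y([ga, gb])
        # recentre each group to a common (zero) mean direction
        centred = []
        for g in (ga, gb):
            mu, _ = _mean_direction(g)
            centred.append(np.mod(g - mu, TWO_PI))
        exceed = 0
        for _ in range(reps):
            boot = [rng.choice(g, size=g.size, replace=True) for g in centred]
            if _watson_Y(boot) >= observed:
                exceed += 1
        p = (exceed + 1) / (reps + 1)
        return TestResult(float(observed), float(p), "watson_mean_bootstrap")

    pooled = np.concatenate([ga, gb])
    na = ga.size

    if method == "fisher_median":
        med = circular_median(pooled)
        observed = _fisher_P([ga, gb], med)
        exceed = 0
        for _ in range(reps):
            perm = rng.permutation(pooled)
            if _fisher_P([perm[:na], perm[na:]], med) >= observed:
                exceed += 1
        p = (exceed + 1) / (reps + 1)
        return TestResult(float(observed), float(p), "fisher_median_randomised")

    if method == "mww_distribution":
        observed = _mww_W([ga, gb])
        exceed = 0
        for _ in range(reps):
            perm = rng.permutation(pooled)
            if _mww_W([perm[:na], perm[na:]]) >= observed:
                exceed += 1
        p = (exceed + 1) / (reps + 1)
        return TestResult(float(observed), float(p), "mww_randomised")

    raise ValueError(f"unknown method: {method!r}")
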