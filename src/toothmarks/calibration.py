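"""p-value evidence calibration: Bayes Factor Bound, False Positive Risk, p(H0).

The pipeline never declares "significance".  Instead every frequentist p-value
is mapped onto an evidential scale:

* ``bfb`` -- the upper bound on the Bayes factor in favour of the alternative
  implied by a p-value, ``1 / (-e * p * ln p)`` (Sellke-Bayarri-Berger bound,
  popularised by Benjamin & Berger).  The bound is only informative for
  ``p <= 1/e``; beyond that it saturates at 1 and the sub-unit branch value is
  exposed separately as evidence *for* the null.
* ``fpr`` -- the False Positive Risk: the posterior probability that a claimed
  effect is absent, given the bound and prior odds of a real effect.
* ``p_h0`` -- a continuous calibrated posterior probability of the null with
  branch point at p* = 0.3681 (the point of maximum curvature of the
  calibration curve, numerically ~1/e): below p* the evidence branch
  ``x/(1+x)`` applies, above it the saturated branch ``1/(1+x)``, with
  ``x = -e * p * ln p``.  The two branches agree (0.5) at p = 1/e.

Evidence threshold convention: 0.003 (the third standard deviation from the
mean of a Gaussian, extending Fisher's two-sigma 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EVIDENCE_THRESHOLD",
    "P_STAR",
    "CalibrationRecord",
    "bfb",
    "fpr",
    "p_h0",
    "calibrate",
]

#: Branch point of the p(H0) calibration (point of maximum curvature, ~1/e).
P_STAR = 0.3681

#: Evidence threshold used throughout the pipeline (three-sigma, 0.3%).
EVIDENCE_THRESHOLD = 0.003


def _check_p(p: float) -> float:
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"p-value must lie strictly in (0, 1); got {p}")
    return p


def _x(p: float) -> float:
    """The bound kernel x = -e * p * ln p (odds of H0 vs Ha on the evidence branch)."""
    return -math.e * p * math.log(p)


def bfb(p: float) -> float:
    """Upper bound on the Bayes factor in favour of the alternative.

    Returns ``1 / (-e p ln p)`` for ``p <= 1/e``; for larger p the bound
    saturates at 1 (a p-value cannot favour the alternative there).

    >>> round(bfb(0.01), 2)
    7.99
    """
    p = _check_p(p)
    x = _x(p)
    if p <= 1.0 / math.e:
        return 1.0 / x
    return 1.0


def bfb_raw(p: float) -> float:
    """Unsaturated reciprocal kernel ``1/x``.

    Since ``x = -e p ln p <= 1`` everywhere (with equality at p = 1/e), this
    is always >= 1.  On the evidence branch (p <= 1/e) it is the Bayes factor
    bound for the alternative; on the saturated branch (p > 1/e) it reads as
    the odds bound in favour of the *null* instead.
    """
    return 1.0 / _x(_check_p(p))


def fpr(p: float, prior_prob_real: float = 0.5) -> float:
    """False Positive Risk: P(effect absent | p), using the Bayes factor bound.

    Parameters
    ----------
    p : p-value in (0, 1).
    prior_prob_real : prior probability that a real effect exists, in (0, 1).
        The default 0.5 encodes complete prior ignorance (prior odds 1).
    """
    p = _check_p(p)
    if not 0.0 < prior_prob_real < 1.0:
        raise ValueError("prior_prob_real must lie strictly in (0, 1)")
    prior_odds = prior_prob_real / (1.0 - prior_prob_real)
    posterior_odds = bfb(p) * prior_odds
    return 1.0 / (1.0 + posterior_odds)


def p_h0(p: float) -> float:
    """Calibrated posterior probability of the null hypothesis.

    Continuous and strictly increasing on (0, 1); equals 0.5 at p = 1/e.
    """
    p = _check_p(p)
    x = _x(p)
    if p <= P_STAR:
        return x / (1.0 + x)
    return 1.0 / (1.0 + x)


@dataclass(frozen=True)
class CalibrationRecord:
    """Evidence calibration attached to a single p-value."""

    p: float
    bfb: float
    prior_odds: float
    posterior_odds: float
    fpr: float
    p_h0: float
    p_ha: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_ha", 1.0 - self.p_h0)

    def as_dict(self) -> dict:
        return {
            "p": self.p,
            "BFB": self.bfb,
            "prior_odds": self.prior_odds,
            "posterior_odds": self.posterior_odds,
            "FPR": self.fpr,
            "p_H0": self.p_h0,
            "p_Ha": self.p_ha,
        }


def calibrate(p: float, prior_prob_real: float = 0.5) -> CalibrationRecord:
    """Build the full calibration record for one p-value."""
    p = _check_p(p)
    if not 0.0 < prior_prob_real < 1.0:
        raise ValueError("prior_prob_real must lie strictly in (0, 1)")
    b = bfb(p)
    prior_odds = prior_prob_real / (1.0 - prior_prob_real)
    post = b * prior_odds
    return CalibrationRecord(
        p=p,
        bfb=b,
        prior_odds=prior_odds,
        posterior_odds=post,
        fpr=1.0 / (1.0 + post),
        p_h0=p_h0(p),
    )


def calibrate_column(pvalues, prior_prob_real: float = 0.5):
    """Vectorised calibration of a sequence of p-values -> dict of arrays."""
    pvalues = np.asarray(pvalues, dtype=float)
    recs = [calibrate(p, prior_prob_real) for p in pvalues]
    return {
        "p": pvalues,
        "BFB": np.array([r.bfb for r in recs]),
        "FPR": np.array([r.fpr for r in recs]),
        "p_H0": np.array([r.p_h0 for r in recs]),
        "p_Ha": np.array([r.p_ha for r in recs]),
    }
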