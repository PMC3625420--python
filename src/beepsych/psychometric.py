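"""Three-parameter Weibull psychometric function for 2-AFC choice data.

The function maps a relative stimulus intensity ``x`` (the absolute
difference between two sucrose concentrations divided by their mean, a
Weber-fraction-like measure) to the probability that a forager visits the
sweeter of the two options:

.. math::

    \\Psi(x; m, s, \\pi_l) = \\tfrac{1}{2}\\Bigl[\\pi_l + (1-\\pi_l)
        \\bigl[2 - \\exp(-\\exp(\\tfrac{2sm}{\\ln 2}(\\ln x - \\ln m)
        + \\ln\\ln 2))\\bigr]\\Bigr]

in the Kuss-style parameterization where *m* is the threshold (intensity at
which performance is halfway between the asymptotes; 75 % correct with no
lapsing), *s* is the slope at threshold of the underlying discrimination
function ``F = 2*Psi - 1``, and *pi_l* is the lapse rate — the probability of
a stimulus-independent choice, which pins the upper asymptote at
``1 - pi_l/2``.  The lower asymptote is the 2-AFC chance level 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PsychometricParams",
    "psychometric_value",
    "psychometric_inverse",
    "lapse_from_upper_asymptote",
    "BEE_POOLED_PARAMS",
    "BAT_PARAMS",
]

_LN2 = math.log(2.0)
_LNLN2 = math.log(_LN2)
# |argument| of the double exponential beyond this is numerically identical
# to the asymptote in double precision
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class PsychometricParams:
    """Threshold, slope and lapse rate of a 2-AFC Weibull psychometric curve.

    Parameters
    ----------
    threshold_m
        Relative intensity at which performance is halfway between the
        asymptotes (dimensionless, > 0).
    slope_s
        Slope of the underlying discrimination function at the threshold
        (dimensionless, > 0).
    lapse_pi
        Probability of responding independently of the stimulus, in [0, 1);
        the upper asymptote of the curve is ``1 - lapse_pi / 2``.
    """

    threshold_m: float
    slope_s: float
    lapse_pi: float = 0.0

    def __post_init__(self) -> None:
        if not (self.threshold_m > 0 and np.isfinite(self.threshold_m)):
            raise ValueError(f"threshold_m must be positive, got {self.threshold_m}")
        if not (self.slope_s > 0 and np.isfinite(self.slope_s)):
            raise ValueError(f"slope_s must be positive, got {self.slope_s}")
        if not (0.0 <= self.lapse_pi < 1.0):
            raise ValueError(f"lapse_pi must lie in [0, 1), got {self.lapse_pi}")

    @property
    def upper_asymptote(self) -> float:
        return 1.0 - self.lapse_pi / 2.0


#: Pooled-data estimate for Bombus impatiens workers (all bees combined).
BEE_POOLED_PARAMS = PsychometricParams(threshold_m=0.251, slope_s=5.30, lapse_pi=0.23)

#: Published estimate for the nectar-feeding bat Glossophaga commissarisi,
#: used for cross-taxon comparison of discrimination performance.
BAT_PARAMS = PsychometricParams(threshold_m=0.50, slope_s=3.41, lapse_pi=0.04)


def psychometric_value(x, params: PsychometricParams):
    """Evaluate the psychometric function at relative intensity ``x``.

    Accepts a scalar or array of positive intensities and returns the
    probability of choosing the sweeter option, strictly increasing in ``x``
    and confined to ``(0.5, 1 - lapse_pi/2)``.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(~(xa > 0)):
        raise ValueError("x (relative intensity) must be strictly positive")
    m, s, pl = params.threshold_m, params.slope_s, params.lapse_pi
    arg = (2.0 * s * m / _LN2) * (np.log(xa) - math.log(m)) + _LNLN2
    arg = np.clip(arg, -_EXP_CLAMP, _EXP_CLAMP)
    psi = 0.5 * (pl + (1.0 - pl) * (2.0 - np.exp(-np.exp(arg))))
    return psi if psi.ndim else float(psi)


def psychometric_inverse(p: float, params: PsychometricParams) -> float:
    """Intensity at which the curve attains probability ``p``.

    Solves ``psychometric_value(x) = p`` by monotone bisection on ``ln x``,
    valid for ``0.5 < p < 1 - lapse_pi/2`` (the open asymptote interval).
    """
    upper = params.upper_asymptote
    if not (0.5 < p < upper):
        raise ValueError(
            f"p must lie strictly between 0.5 and the upper asymptote {upper}, got {p}"
        )
    lm = math.log(params.threshold_m)
    lo, hi = lm, lm
    step = 1.0
    while psychometric_value(math.exp(lo), params) >= p:
        lo -= step
        step *= 2.0
    step = 1.0
    while psychometric_value(math.exp(hi), params) <= p:
        hi += step
        step *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if psychometric_value(math.exp(mid), params) < p:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14:
            break
    return math.exp(0.5 * (lo + hi))


def lapse_from_upper_asymptote(upper: float) -> float:
    """Lapse rate implied by an upper asymptote: ``2 * (1 - upper)``.

    A lapsing forager chooses at the 0.5 chance level, so the base rate of
    incorrect choices at saturating intensity is half the lapse rate.
    """
    if not (0.5 < upper <= 1.0):
        raise ValueError(f"upper asymptote must lie in (0.5, 1], got {upper}")
    return 2.0 * (1.0 - upper)
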