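"""Binomial analysis of multichannel patches and the cooperativity ratio.

For a patch holding N independent, identical channels of open
probability p, the probability of k channels being simultaneously open
is binomial.  For a two-channel patch whose channels have unequal open
probabilities p1 and p2 the level occupancies are

    P(0) = (1-p1)(1-p2)
    P(1) = p1(1-p2) + p2(1-p1)
    P(2) = p1 p2

and the cooperativity ratio

    CR = [P(1)^2 / (P(0) P(2))]  /  [2N / (N-1)]

distinguishes independent identical channels (CR = 1), independent but
nonidentical channels (CR > 1) and cooperative gating (CR < 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .errors import ValidationError

__all__ = ["LevelOccupancy", "binomial_pk", "predicted_occupancies",
           "cooperativity_ratio", "classify_cr", "compare_predicted_observed",
           "level_occupancy_report"]


@dataclass
class LevelOccupancy:
    """Observed vs predicted level occupancies for a 2-channel patch."""

    n_channels: int
    observed: np.ndarray          # P(0), P(1), P(2)
    predicted: np.ndarray
    p1: float                     # small-conductance channel open probability
    p2: float                     # wild-type-like channel open probability
    cr: float
    classification: str

    def __post_init__(self):
        for name, tri in (("observed", self.observed),
                          ("predicted", self.predicted)):
            if abs(float(np.sum(tri)) - 1.0) > 1e-6:
                raise ValidationError(f"{name} occupancies must sum to 1")
        if not (0 <= self.p1 <= 1 and 0 <= self.p2 <= 1):
            raise ValidationError("open probabilities must lie in [0, 1]")
        if self.cr <= 0:
            raise ValidationError("CR must be positive")


def binomial_pk(n: int, p: float, k: int) -> float:
    """P(k of N channels simultaneously open) = C(N,k) p^k (1-p)^(N-k)."""
    if not 0 <= p <= 1:
        raise ValidationError("p must lie in [0, 1]")
    if k < 0 or k > n:
        raise ValidationError("k must lie in [0, N]")
    return float(comb(n, k, exact=True) * p ** k * (1 - p) ** (n - k))


def predicted_occupancies(p1: float, p2: float) -> np.ndarray:
    """Level occupancies of two independent channels with unequal P_o."""
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValidationError("open probabilities must lie in [0, 1]")
    return np.array([(1 - p1) * (1 - p2),
                     p1 * (1 - p2) + p2 * (1 - p1),
                     p1 * p2])


def cooperativity_ratio(p0: float, p1: float, p2: float, n: int = 2) -> float:
    """CR = [P(1)^2 / (P(0) P(2))] / [2N/(N-1)].

    Normalized so that independent identical channels give exactly 1 for
    any N; requires occupancy of both the fully closed and fully open
    levels.
    """
    if n < 2:
        raise ValidationError("N must be >= 2")
    if p0 <= 0 or p2 <= 0:
        raise ValidationError("CR undefined when P(0) or P(2) is zero")
    return float((p1 * p1 / (p0 * p2)) / (2.0 * n / (n - 1.0)))


def classify_cr(cr: float, tolerance: float = 0.1) -> str:
    """Label a CR value: independent-identical, nonidentical, or cooperative."""
    if abs(cr - 1.0) <= tolerance:
        return "independent_identical"
    return "nonidentical" if cr > 1.0 else "cooperative"


def compare_predicted_observed(observed, p1: float, p2: float) -> dict:
    """Per-level divergence of observed occupancies from the Eq-3/5 prediction.

    Returns absolute differences and a chi-square-style summary
    sum((obs-pred)^2/pred).  Divergence implies the channels are either
    dependent or nonidentical; the CR then separates those cases.
    """
    obs = np.asarray(observed, float)
    pred = predicted_occupancies(p1, p2)
    if obs.shape != pred.shape:
        raise ValidationError("observed occupancies must be a length-3 triple")
    if abs(obs.sum() - 1.0) > 1e-6:
        raise ValidationError("observed occupancies must sum to 1")
    diff = np.abs(obs - pred)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum(np.where(pred > 0, (obs - pred) ** 2 / pred, 0.0)))
    return {"observed": obs.tolist(), "predicted": pred.tolist(),
            "abs_diff": diff.tolist(), "max_abs_diff": float(diff.max()),
            "chi2_style": chi2}


def level_occupancy_report(observed, p1: float, p2: float,
                           cr_tolerance: float = 0.1) -> LevelOccupancy:
    """Assemble the full 2-channel binomial analysis from an observed triple."""
    obs = np.asarray(observed, float)
    pred = predicted_occupancies(p1, p2)
    cr = cooperativity_ratio(obs[0], obs[1], obs[2], n=2)
    return LevelOccupancy(2, obs, pred, p1, p2, cr,
                          classify_cr(cr, cr_tolerance))
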