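"""Collision and division event probabilities and control variables.

A collision between two cells announces itself through two morphological
cues: the merged blob's area is about twice a single cell's area in the
previous frame (area ratio alpha_1 = s_k / s_{k-1} near 2), and the
centroid distance between the cells shrinks toward zero.  A division shows
the mirror signature: each daughter has about half the parent's area
(alpha_2 near 0.5) while the daughters are still close together.

Both cues are combined multiplicatively with peak-normalized kernels:

    P(c_k)    = f1 * exp(-(alpha_1 - mu1)^2 / (2 sigma1^2)) * exp(-sigma |d_{k-1}|)
    P(beta_k) = f2 * exp(-C (alpha_2 - 0.5)^2)              * exp(-gamma |d_k|)

The kernels are normalized to peak at 1 (f1, f2 <= 1 absorb any
proportionality) so that the derived control variables stay in their
design ranges: the collision control lambda = 1 + P(c) in [1, 2] scales a
merging blob's area upward, the division control kappa = P(beta) in [0, 1]
scales a splitting blob's area downward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: default mean cell diameter (px) used to set the distance decay rates
DEFAULT_MEAN_DIAMETER = 12.0


@dataclass(frozen=True)
class EventParams:
    """Kernel parameters for the collision/division event probabilities.

    Parameters
    ----------
    f1, f2:
        Adjusted coefficients in (0, 1]; the peak value of each probability.
    mu1, sigma1:
        Mean and std of the collision area-ratio kernel.  ``mu1 = 2``
        encodes "merged area is about the sum of two similar cells".
    sigma, gamma:
        Distance decay rates (1/px) for collision and division; by default
        both are 1 / mean cell diameter, tying the length scale of "close"
        to the size of the studied cell population.
    C:
        Curvature of the division area-ratio kernel exp(-C (a - 0.5)^2).
    """

    f1: float = 0.9
    f2: float = 0.9
    mu1: float = 2.0
    sigma1: float = 0.4
    sigma: float = 1.0 / DEFAULT_MEAN_DIAMETER
    gamma: float = 1.0 / DEFAULT_MEAN_DIAMETER
    C: float = 25.0

    def __post_init__(self) -> None:
        for name in ("f1", "f2", "mu1", "sigma1", "sigma", "gamma", "C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"EventParams.{name} must be > 0")
        if self.f1 > 1 or self.f2 > 1:
            logger.warning(
                "EventParams f1/f2 > 1: probabilities will be clamped to 1"
            )


@dataclass(frozen=True)
class EventAssessment:
    """Per-track event evidence for one frame and the derived controls."""

    alpha1: float = 1.0
    alpha2: float = 1.0
    d_prev: float = math.inf
    d_curr: float = math.inf
    P_c: float = 0.0
    P_beta: float = 0.0
    lambda_k: float = 1.0
    kappa_k: float = 0.0


def area_ratio(s_curr: float, s_prev: float) -> float:
    """Ratio of a cell's detected area in the current frame to the previous
    one; near 2 for a merge, near 0.5 for a division."""
    if s_prev <= 0:
        raise ValueError("previous area must be positive")
    return float(s_curr) / float(s_prev)


def collision_probability(
    alpha1: float, d_prev: float, params: EventParams
) -> float:
    """Probability of a collision event given area ratio and distance."""
    g = math.exp(-((alpha1 - params.mu1) ** 2) / (2.0 * params.sigma1**2))
    e = math.exp(-params.sigma * abs(d_prev))
    return min(1.0, params.f1 * g * e)


def division_probability(
    alpha2: float, d_curr: float, params: EventParams
) -> float:
    """Probability of a division/splitting event given area ratio and
    distance."""
    g = math.exp(-params.C * (alpha2 - 0.5) ** 2)
    e = math.exp(-params.gamma * abs(d_curr))
    return min(1.0, params.f2 * g * e)


def collision_control(P_c: float) -> float:
    """Collision area-scaling control lambda = 1 + P(c), in [1, 2]."""
    if not 0.0 <= P_c <= 1.0:
        raise ValueError("collision probability must lie in [0, 1]")
    return 1.0 + P_c


def division_control(P_beta: float) -> float:
    """Division area-scaling control kappa = P(beta), in [0, 1]."""
    if not 0.0 <= P_beta <= 1.0:
        raise ValueError("division probability must lie in [0, 1]")
    return float(P_beta)


def assess(
    alpha1: float,
    alpha2: float,
    d_prev: float,
    d_curr: float,
    params: EventParams,
) -> EventAssessment:
    """Evaluate both event probabilities and the derived controls."""
    pc = collision_probability(alpha1, d_prev, params)
    pb = division_probability(alpha2, d_curr, params)
    return EventAssessment(
        alpha1=alpha1,
        alpha2=alpha2,
        d_prev=d_prev,
        d_curr=d_curr,
        P_c=pc,
        P_beta=pb,
        lambda_k=collision_control(pc),
        kappa_k=division_control(pb),
    )
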