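"""Joint belief model for two dependent cure probabilities.

Eliciting a joint distribution for two dependent cure rates — theta1 (first
treatment alone) and theta2 (first plus adjunct treatment) — is hard, so the
problem is restructured through an auxiliary variable theta3, the cure
probability of the adjunct given the first treatment failed:

    theta2 = theta1 + (1 - theta1) * theta3

theta1 and theta3 are treated as independent with beta marginals
``Beta(alpha, beta)`` and ``Beta(alpha', beta')``.  The change of variables
(theta1, theta3) -> (theta1, theta2) has Jacobian ``1/(1 - theta1)``, giving
the joint density on the triangle ``0 <= theta1 <= theta2 <= 1``:

    f(theta1, theta2) = phi * theta1^(alpha-1) (1-theta1)^(beta-2)
                        * ((theta2-theta1)/(1-theta1))^(alpha'-1)
                        * ((1-theta2)/(1-theta1))^(beta'-1)

with normaliser ``phi = 1/(B(alpha,beta) B(alpha',beta'))``, and zero
elsewhere.  The construction forces ``theta2 >= theta1`` — the adjunct can at
worst add nothing — which the elicited ``P(theta2 < theta1)`` values (all at
most 0.05, mostly exactly 0) support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import betaln

from .elicit import BetaParams

__all__ = [
    "BeliefPair",
    "JointSurface",
    "theta2_from",
    "joint_density",
    "normaliser",
    "sample_joint",
    "surface_grid",
]


@dataclass(frozen=True)
class BeliefPair:
    """Fitted marginal priors for one expert: theta1 and theta3 betas."""

    theta1_prior: BetaParams
    theta3_prior: BetaParams
    expert_id: str = ""
    p_worse: float = 0.0  # elicited P(theta2 < theta1); small by construction

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_worse <= 1.0:
            raise ValueError("p_worse must be a probability")


@dataclass(frozen=True)
class JointSurface:
    """Joint density evaluated on a cell-centred lattice over [0,1]^2.

    ``density[i, j]`` is the joint density at ``theta1 = centres[i]``,
    ``theta2 = centres[j]``; the support is the upper triangle ``j >= i``.
    """

    centres: np.ndarray
    density: np.ndarray
    normaliser: float

    @property
    def cell_area(self) -> float:
        return (1.0 / self.centres.size) ** 2

    def riemann_mass(self) -> float:
        """Lattice Riemann sum of the density; close to 1 for fine grids."""
        return float(self.density.sum() * self.cell_area)


def theta2_from(theta1, theta3):
    """Overall cure probability of the combined treatment.

    theta2 = theta1 + (1 - theta1) * theta3: cows cured by the first
    treatment plus the fraction of the remainder rescued by the adjunct.
    Accepts scalars or arrays; always satisfies theta1 <= theta2 <= 1.
    """
    t1 = np.asarray(theta1, dtype=float)
    t3 = np.asarray(theta3, dtype=float)
    if np.any((t1 < 0) | (t1 > 1)) or np.any((t3 < 0) | (t3 > 1)):
        raise ValueError("theta1 and theta3 must lie in [0, 1]")
    out = t1 + (1.0 - t1) * t3
    if out.ndim == 0:
        return float(out)
    return out


def normaliser(pair: BeliefPair) -> float:
    """phi = 1 / (B(alpha, beta) * B(alpha', beta'))."""
    a, b = pair.theta1_prior.alpha, pair.theta1_prior.beta
    a2, b2 = pair.theta3_prior.alpha, pair.theta3_prior.beta
    return float(math.exp(-betaln(a, b) - betaln(a2, b2)))


def joint_density(pair: BeliefPair, theta1, theta2):
    """Joint prior density f(theta1, theta2) for one expert.

    Evaluated in log space (beta log-pdfs plus the log-Jacobian) and
    exponentiated at the end, so large hyperparameters do not overflow.
    Zero off the support triangle and, by convention, on the measure-zero
    boundary theta1 = 1 where the ratio terms are 0/0.
    """
    t1, t2 = np.broadcast_arrays(
        np.asarray(theta1, dtype=float), np.asarray(theta2, dtype=float)
    )
    if np.any((t1 < 0) | (t1 > 1)) or np.any((t2 < 0) | (t2 > 1)):
        raise ValueError("theta1 and theta2 must lie in [0, 1]")
    a, b = pair.theta1_prior.alpha, pair.theta1_prior.beta
    a2, b2 = pair.theta3_prior.alpha, pair.theta3_prior.beta

    scalar = t1.ndim == 0
    t1 = np.atleast_1d(t1)
    t2 = np.atleast_1d(t2)
    out = np.zeros(t1.shape, dtype=float)
    ok = (t1 <= t2) & (t1 < 1.0)
    if np.any(ok):
        u1 = t1[ok]
        t3 = (t2[ok] - u1) / (1.0 - u1)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            logd = (
                stats.beta.logpdf(u1, a, b)
                + stats.beta.logpdf(t3, a2, b2)
                - np.log1p(-u1)
            )
            out[ok] = np.exp(logd)
    if scalar:
        return float(out[0])
    return out


def sample_joint(pair: BeliefPair, n: int, seed) -> np.ndarray:
    """Exact draws of (theta1, theta2) from the joint prior.

    theta1 and theta3 are independent betas, so sampling them directly and
    mapping through ``theta2_from`` gives exact joint draws — no MCMC error.
    Returns an (n, 2) array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t1 = rng.beta(pair.theta1_prior.alpha, pair.theta1_prior.beta, size=n)
    t3 = rng.beta(pair.theta3_prior.alpha, pair.theta3_prior.beta, size=n)
    return np.column_stack([t1, theta2_from(t1, t3)])


def surface_grid(pair: BeliefPair, resolution: int = 200) -> JointSurface:
    """Evaluate the joint density on a cell-centred lattice for contouring."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    centres = (np.arange(resolution) + 0.5) / resolution
    t1, t2 = np.meshgrid(centres, centres, indexing="ij")
    density = joint_density(pair, t1, t2)
    return JointSurface(centres=centres, density=density, normaliser=normaliser(pair))
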