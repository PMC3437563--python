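"""Fit beta distributions to elicited quantile judgements.

An expert's belief about a cure probability is captured during a structured
interview as five points of their subjective cumulative distribution: a
plausible minimum and maximum (treated as extreme tail quantiles), the median
and the two quartiles.  A ``Beta(alpha, beta)`` density is fitted to each set
of judgements by least squares on the CDF — minimise

    sum_k ( F_Beta(value_k; alpha, beta) - prob_k )^2

with a derivative-free simplex (Nelder–Mead) search in ``(log alpha,
log beta)`` so positivity is automatic.  The same procedure underlies the
SHELF family of elicitation tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BetaParams",
    "QuantileJudgement",
    "FitResult",
    "CohortFit",
    "moment_start",
    "fit_beta_from_quantiles",
    "implied_probabilities",
    "fit_cohort",
]

#: Cumulative probabilities assigned to (minimum, lower quartile, median,
#: upper quartile, maximum).  The plausible extremes are "extremely unlikely
#: but not impossible", taken as the 1% and 99% quantiles.
DEFAULT_PROBS: tuple[float, ...] = (0.01, 0.25, 0.50, 0.75, 0.99)

#: Judgements whose whole plausible range is narrower than this trigger a
#: warning: the fit is attempted but the expert is unusually confident.
NARROW_RANGE = 0.02


@dataclass(frozen=True)
class BetaParams:
    """Hyperparameters of a beta distribution; both must be positive."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def var(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)

    @property
    def median(self) -> float:
        return float(stats.beta.ppf(0.5, self.alpha, self.beta))

    def quantile(self, p):
        return stats.beta.ppf(p, self.alpha, self.beta)

    def cdf(self, x):
        return stats.beta.cdf(x, self.alpha, self.beta)

    def pdf(self, x):
        return stats.beta.pdf(x, self.alpha, self.beta)


@dataclass(frozen=True)
class QuantileJudgement:
    """One expert's elicited CDF points for a probability-valued variable.

    ``probs`` are cumulative probabilities, ``values`` the corresponding
    elicited cure rates.  Pairs may arrive in any order — they are sorted by
    probability on construction, so the fit cannot depend on presentation
    order — but after sorting both sequences must be strictly increasing,
    and at least three points are needed for the two-parameter fit to be
    over-determined.
    """

    probs: tuple[float, ...]
    values: tuple[float, ...]

    def __init__(self, probs: Sequence[float], values: Sequence[float]) -> None:
        p = [float(x) for x in probs]
        v = [float(x) for x in values]
        if len(p) != len(v):
            raise ValueError("probs and values must have equal length")
        if len(p) < 3:
            raise ValueError("need at least 3 quantile judgements")
        order = sorted(range(len(p)), key=p.__getitem__)
        object.__setattr__(self, "probs", tuple(p[i] for i in order))
        object.__setattr__(self, "values", tuple(v[i] for i in order))
        self._validate()

    def _validate(self) -> None:
        p = np.asarray(self.probs)
        v = np.asarray(self.values)
        if not (np.all(p > 0) and np.all(p < 1)):
            raise ValueError("probs must lie strictly inside (0, 1)")
        if not (np.all(v >= 0) and np.all(v <= 1)):
            raise ValueError("values must lie in [0, 1]")
        if not np.all(np.diff(p) > 0):
            raise ValueError("probs must be strictly increasing")
        if not np.all(np.diff(v) > 0):
            raise ValueError("values must be strictly increasing")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares beta fit."""

    params: BetaParams
    objective: float
    converged: bool
    start: BetaParams | None = None
    message: str = ""


@dataclass
class CohortFit:
    """Per-expert fits for a whole cohort; failures are isolated, not fatal."""

    pairs: list  # list[BeliefPair] — typed loosely to avoid a circular import
    failures: list[tuple[str, str]] = field(default_factory=list)
    theta1_fits: dict = field(default_factory=dict)
    theta3_fits: dict = field(default_factory=dict)


def _objective(judgement: QuantileJudgement):
    p = np.asarray(judgement.probs)
    v = np.asarray(judgement.values)

    def fun(log_ab: np.ndarray) -> float:
        a, b = np.exp(np.clip(log_ab, -30.0, 30.0))
        resid = stats.beta.cdf(v, a, b) - p
        return float(resid @ resid)

    return fun


def moment_start(judgement: QuantileJudgement) -> BetaParams:
    """Deterministic moment-matched starting point for the simplex search.

    The median approximates the mean and the quartile spread maps to a normal
    standard deviation (IQR/1.349); beta parameters follow from the usual
    mean/variance inversion, clipped into a numerically safe box.
    """
    p = np.asarray(judgement.probs)
    v = np.asarray(judgement.values)
    m = float(np.clip(np.interp(0.5, p, v), 0.01, 0.99))
    spread = float(np.interp(0.75, p, v) - np.interp(0.25, p, v))
    sd = float(np.clip(spread / 1.349, 1e-3, 0.28))
    nu = max(m * (1.0 - m) / sd**2 - 1.0, 0.02)
    a = float(np.clip(m * nu, 1e-2, 1e4))
    b = float(np.clip((1.0 - m) * nu, 1e-2, 1e4))
    return BetaParams(a, b)


def _minimise(fun, x0: np.ndarray, ftol: float, maxiter: int):
    res = optimize.minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={"fatol": ftol, "xatol": 1e-8, "maxiter": maxiter, "maxfev": 4 * maxiter},
    )
    # restart once from the found vertex: standard simplex practice, costs
    # little and recovers from premature shrinkage
    res2 = optimize.minimize(
        fun,
        res.x,
        method="Nelder-Mead",
        options={"fatol": ftol, "xatol": 1e-10, "maxiter": maxiter, "maxfev": 4 * maxiter},
    )
    return res2 if res2.fun <= res.fun else res


def fit_beta_from_quantiles(
    judgement: QuantileJudgement,
    *,
    ftol: float = 1e-10,
    maxiter: int = 2000,
) -> FitResult:
    """Least-squares beta fit to one set of elicited quantiles.

    The objective is the sum of squared differences between the fitted and
    the elicited cumulative probabilities, minimised by Nelder–Mead in
    ``(log alpha, log beta)`` from a moment-matched start.  A handful of
    fixed fallback starts guard against the rare simplex stall; the reported
    ``converged`` flag is honest (an optimiser failure is flagged, never
    silently accepted).
    """
    if judgement.values[-1] - judgement.values[0] < NARROW_RANGE:
        warnings.warn(
            "plausible range narrower than 0.02; expert is extremely confident "
            "and the fitted beta will be near-degenerate",
            stacklevel=2,
        )
    fun = _objective(judgement)
    start = moment_start(judgement)
    best = _minimise(fun, np.log([start.alpha, start.beta]), ftol, maxiter)
    if best.fun > 1e-10:
        for alt in ((1.0, 1.0), (0.5, 0.5), (2.0, 8.0), (8.0, 2.0)):
            trial = _minimise(fun, np.log(alt), ftol, maxiter)
            if trial.fun < best.fun:
                best = trial
            if best.fun <= 1e-12:
                break
    a, b = np.exp(best.x)
    return FitResult(
        params=BetaParams(float(a), float(b)),
        objective=float(best.fun),
        converged=bool(best.success and np.isfinite(best.fun)),
        start=start,
        message=str(best.message),
    )


def implied_probabilities(params: BetaParams, thresholds: Iterable[float]) -> list[float]:
    """Implied (not elicited) probabilities ``P(theta <= t)`` for feedback.

    During an interview these are read back to the expert — e.g. "your fitted
    belief implies a 30% chance the cure rate is below 0.2" — so the expert
    can veto assertions the raw quantiles never probed.
    """
    th = np.asarray(list(thresholds), dtype=float)
    if th.size and (th.min() < 0 or th.max() > 1):
        raise ValueError("thresholds must lie in [0, 1]")
    return [float(x) for x in stats.beta.cdf(th, params.alpha, params.beta)]


def fit_cohort(records: Sequence) -> CohortFit:
    """Fit independent theta1 and theta3 priors for every expert in a cohort.

    Each record must expose ``expert_id``, ``probs``, ``theta1_values``,
    ``theta3_values`` and ``p_worse`` (the cohort schema).  A record whose
    judgements are invalid or whose fit fails is reported in ``failures`` and
    excluded; the rest of the batch is unaffected.
    """
    from .belief import BeliefPair  # deferred: belief imports BetaParams from here

    if len(records) == 0:
        raise ValueError("empty cohort")
    out = CohortFit(pairs=[])
    for rec in records:
        try:
            j1 = QuantileJudgement(rec.probs, rec.theta1_values)
            j3 = QuantileJudgement(rec.probs, rec.theta3_values)
            f1 = fit_beta_from_quantiles(j1)
            f3 = fit_beta_from_quantiles(j3)
        except ValueError as exc:
            out.failures.append((str(rec.expert_id), str(exc)))
            continue
        out.theta1_fits[rec.expert_id] = f1
        out.theta3_fits[rec.expert_id] = f3
        out.pairs.append(
            BeliefPair(
                theta1_prior=f1.params,
                theta3_prior=f3.params,
                expert_id=str(rec.expert_id),
                p_worse=float(rec.p_worse),
            )
        )
    return out
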