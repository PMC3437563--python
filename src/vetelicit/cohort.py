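"""Synthetic elicitation cohorts and synthetic null-effect trial data.

No elicitation data were deposited with the study this package models, so
every downstream stage is exercised on synthetic cohorts that reproduce its
statistical structure: 24 experts across 5 practices whose beliefs about the
conditional cure rate theta3 fall into three archetypes — confident optimism,
confident pessimism, and high uncertainty.  Each synthetic expert owns a
ground-truth beta for theta1 and for theta3; their "elicited" quantiles are
the exact quantiles of those betas (optionally rounded to whole cows out of
100), so parameter-recovery tests have a known answer.

The trial generator produces the null-effect datasets used in the
trial-size sweep: ``n1`` cows per arm, ``x1`` cures under treatment 1,
``n3 = n1 - x1`` failures eligible for rescue, and ``x3 = 0`` extra cures —
data showing no benefit of the adjunct treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .elicit import DEFAULT_PROBS, BetaParams

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "TrialDesign",
    "TrialDataset",
    "ElicitationRecord",
    "ARCHETYPES",
    "default_cohort_config",
    "generate_cohort",
    "generate_trial",
    "cohort_to_frame",
    "write_cohort",
    "read_cohort",
]

_Q_LABELS = ("min", "q25", "median", "q75", "max")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Ground-truth belief generator for one expert archetype.

    ``label`` names the archetype; the two beta parameter sets generate the
    archetype's typical beliefs about theta1 (first-treatment cure rate) and
    theta3 (conditional adjunct cure rate).  Confident archetypes have a
    theta3 standard deviation below 0.10; the uncertain archetype above 0.15.
    """

    label: str
    theta1_truth: BetaParams
    theta3_truth: BetaParams


#: The three belief archetypes observed in the field: optimists expect the
#: adjunct to rescue a fifth or more of failures with little doubt,
#: pessimists expect essentially no rescue with little doubt, and uncertain
#: experts spread their belief widely.
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "confident-optimist": ArchetypeSpec(
        "confident-optimist", BetaParams(15.0, 10.0), BetaParams(8.0, 20.0)
    ),
    "confident-pessimist": ArchetypeSpec(
        "confident-pessimist", BetaParams(18.0, 9.0), BetaParams(1.2, 30.0)
    ),
    "uncertain": ArchetypeSpec(
        "uncertain", BetaParams(3.0, 3.0), BetaParams(2.0, 4.0)
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Shape of a synthetic cohort: practices, sizes, archetype mix, seed."""

    n_practices: int
    vets_per_practice: tuple[int, ...]
    archetype_mix: tuple[tuple[tuple[str, float], ...], ...]  # per practice
    seed: int = 0
    probs: tuple[float, ...] = DEFAULT_PROBS
    round_to_cows: bool = False  # round quantiles to whole cows out of 100
    truth_jitter_sd: float = 0.15  # log-scale spread of expert truths within an archetype

    def __post_init__(self) -> None:
        if self.n_practices != len(self.vets_per_practice):
            raise ValueError("vets_per_practice must list one size per practice")
        if self.n_practices != len(self.archetype_mix):
            raise ValueError("archetype_mix must list one mix per practice")
        for mix in self.archetype_mix:
            total = sum(w for _, w in mix)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"archetype weights must sum to 1, got {total}")
            for name, _ in mix:
                if name not in ARCHETYPES:
                    raise ValueError(f"unknown archetype {name!r}")

    @property
    def cohort_size(self) -> int:
        return sum(self.vets_per_practice)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The stated-world cohort: 24 vets in 5 practices (sizes 4,5,5,5,5).

    The per-practice archetype mix mirrors the observed pattern: practice 1
    uniformly optimistic about the adjunct, practice 3 uniformly pessimistic,
    practice 4 predominantly so, practices 2 and 5 diverse.
    """
    return CohortConfig(
        n_practices=5,
        vets_per_practice=(4, 5, 5, 5, 5),
        archetype_mix=(
            (("confident-optimist", 1.0),),
            (("confident-optimist", 0.4), ("confident-pessimist", 0.2), ("uncertain", 0.4)),
            (("confident-pessimist", 1.0),),
            (("confident-pessimist", 0.8), ("uncertain", 0.2)),
            (("confident-optimist", 0.4), ("uncertain", 0.4), ("confident-pessimist", 0.2)),
        ),
        seed=seed,
    )


@dataclass(frozen=True)
class TrialDesign:
    """Design of one synthetic randomised trial.

    ``n_per_arm`` infected cows receive each treatment; ``assumed_theta1``
    sets the treatment-1 cure count (the deposited study never states the
    value it used; 0.5 is the non-informative midpoint default).  With
    ``null_effect`` the data show no adjunct benefit (x3 = 0); otherwise
    ``assumed_theta3`` drives the extra cures.  ``stochastic`` switches the
    counts from deterministic rounding to binomial draws.
    """

    n_per_arm: int
    assumed_theta1: float = 0.5
    null_effect: bool = True
    assumed_theta3: float = 0.0
    stochastic: bool = False

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if not 0.0 < self.assumed_theta1 < 1.0:
            raise ValueError("assumed_theta1 must lie strictly in (0, 1)")
        if not 0.0 <= self.assumed_theta3 <= 1.0:
            raise ValueError("assumed_theta3 must lie in [0, 1]")


@dataclass(frozen=True)
class TrialDataset:
    """Observed counts of one two-arm trial, in conditional form.

    n1 cows on treatment 1 with x1 cures; n3 = n1 - x1 treatment-1 failures,
    of which x3 were cured by the adjunct arm (x3 = x2 - x1).
    """

    n1: int
    x1: int
    n3: int
    x3: int

    def __post_init__(self) -> None:
        if not 0 <= self.x1 <= self.n1:
            raise ValueError("need 0 <= x1 <= n1")
        if self.n3 != self.n1 - self.x1:
            raise ValueError("need n3 = n1 - x1")
        if not 0 <= self.x3 <= max(self.n3, 0):
            raise ValueError("need 0 <= x3 <= n3")

    def to_dict(self) -> dict[str, int]:
        return {"n1": self.n1, "x1": self.x1, "n3": self.n3, "x3": self.x3}


@dataclass(frozen=True)
class ElicitationRecord:
    """One expert's elicited quantiles plus generator ground truth.

    ``theta1_values`` / ``theta3_values`` are the five elicited cure rates at
    cumulative probabilities ``probs``; ``p_worse`` is the separately
    elicited probability that the adjunct makes things worse.  For synthetic
    experts the generating beta parameters are retained for recovery tests;
    ``pilot`` marks records included in the scaling analysis but not the
    Bayesian one.
    """

    expert_id: str
    practice: int
    archetype: str
    probs: tuple[float, ...]
    theta1_values: tuple[float, ...]
    theta3_values: tuple[float, ...]
    p_worse: float
    theta1_truth: BetaParams | None = None
    theta3_truth: BetaParams | None = None
    pilot: bool = False


def _jitter(params: BetaParams, rng: np.random.Generator, sd: float) -> BetaParams:
    if sd == 0.0:
        return params
    fa, fb = np.exp(rng.normal(0.0, sd, size=2))
    return BetaParams(params.alpha * fa, params.beta * fb)


def _theta3_within_archetype(label: str, params: BetaParams) -> bool:
    """Defining theta3 constraints of each archetype: confidence is a
    standard deviation below 0.10 (above 0.15 for the uncertain archetype),
    optimism a median of at least 0.20, pessimism a median of at most 0.05."""
    if label == "confident-optimist":
        return params.sd < 0.10 and params.median >= 0.20
    if label == "confident-pessimist":
        return params.sd < 0.10 and params.median <= 0.05
    return params.sd > 0.15


def _jitter_theta3(
    label: str, params: BetaParams, rng: np.random.Generator, sd: float
) -> BetaParams:
    # rejection keeps the expert a genuine member of their archetype
    for _ in range(100):
        cand = _jitter(params, rng, sd)
        if _theta3_within_archetype(label, cand):
            return cand
    raise RuntimeError(f"could not jitter within archetype {label!r}")


def _round_to_cows(values: np.ndarray) -> tuple[float, ...]:
    """Round to whole cows out of 100, repairing ties so quantiles stay
    strictly increasing inside (0, 1)."""
    v = np.round(values, 2)
    v[0] = max(v[0], 0.005)
    for i in range(1, v.size):
        v[i] = max(v[i], v[i - 1] + 0.01)
    for i in range(v.size - 1, -1, -1):
        cap = 0.995 - 0.01 * (v.size - 1 - i)
        v[i] = min(v[i], cap)
    if not np.all(np.diff(v) > 0):
        raise ValueError("rounded quantiles cannot be made strictly increasing")
    return tuple(float(x) for x in v)


def generate_cohort(config: CohortConfig) -> list[ElicitationRecord]:
    """Generate one synthetic elicitation cohort.

    Each expert's archetype is drawn from their practice's mix; their
    personal ground-truth betas jitter the archetype's on the log scale
    (within-archetype variation); the elicited quantiles are the exact beta
    quantiles at ``config.probs``.  About 15 in 24 experts state
    ``P(theta2 < theta1) = 0`` and the rest a value at most 0.05.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ElicitationRecord] = []
    for p_idx, (size, mix) in enumerate(
        zip(config.vets_per_practice, config.archetype_mix), start=1
    ):
        names = [n for n, _ in mix]
        weights = np.array([w for _, w in mix])
        for v_idx in range(1, size + 1):
            label = names[int(rng.choice(len(names), p=weights))]
            spec = ARCHETYPES[label]
            if spec.theta3_truth.sd < 1e-6 or spec.theta1_truth.sd < 1e-6:
                raise ValueError(f"degenerate (zero-variance) archetype {label!r}")
            t1_truth = _jitter(spec.theta1_truth, rng, config.truth_jitter_sd)
            t3_truth = _jitter_theta3(label, spec.theta3_truth, rng, config.truth_jitter_sd)
            probs = np.asarray(config.probs)
            v1 = t1_truth.quantile(probs)
            v3 = t3_truth.quantile(probs)
            if config.round_to_cows:
                vals1 = _round_to_cows(v1)
                vals3 = _round_to_cows(v3)
            else:
                vals1 = tuple(float(x) for x in v1)
                vals3 = tuple(float(x) for x in v3)
            # 15 of 24 experts said exactly zero; the rest at most 0.05
            p_worse = 0.0 if rng.random() < 15.0 / 24.0 else float(rng.uniform(0.0, 0.05))
            records.append(
                ElicitationRecord(
                    expert_id=f"{p_idx}{v_idx}",
                    practice=p_idx,
                    archetype=label,
                    probs=tuple(config.probs),
                    theta1_values=vals1,
                    theta3_values=vals3,
                    p_worse=p_worse,
                    theta1_truth=t1_truth,
                    theta3_truth=t3_truth,
                )
            )
    return records


def generate_trial(design: TrialDesign, seed: int = 0) -> TrialDataset:
    """Generate one synthetic trial dataset from a design.

    Deterministic mode sets ``x1 = round(n1 * assumed_theta1)`` (and, when
    the effect is not null, ``x3 = round(n3 * assumed_theta3)``); stochastic
    mode replaces the rounding with binomial draws.  Null-effect data always
    have ``x3 = 0``.
    """
    n1 = design.n_per_arm
    rng = np.random.default_rng(seed)
    if design.stochastic:
        x1 = int(rng.binomial(n1, design.assumed_theta1))
    else:
        x1 = int(round(n1 * design.assumed_theta1))
    n3 = n1 - x1
    if design.null_effect or n3 == 0:
        x3 = 0
    elif design.stochastic:
        x3 = int(rng.binomial(n3, design.assumed_theta3))
    else:
        x3 = int(round(n3 * design.assumed_theta3))
    return TrialDataset(n1=n1, x1=x1, n3=n3, x3=x3)


# ---------------------------------------------------------------------------
# cohort I/O: one row per expert, delimited text; the same schema accepts
# real elicitation data (truth columns simply left empty)
# ---------------------------------------------------------------------------

def cohort_to_frame(records: Sequence[ElicitationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "expert_id": r.expert_id,
            "practice": r.practice,
            "archetype": r.archetype,
            "pilot": r.pilot,
            "p_worse": r.p_worse,
        }
        for lab, p in zip(_Q_LABELS, r.probs):
            row[f"prob_{lab}"] = p
        for lab, v in zip(_Q_LABELS, r.theta1_values):
            row[f"theta1_{lab}"] = v
        for lab, v in zip(_Q_LABELS, r.theta3_values):
            row[f"theta3_{lab}"] = v
        row["truth_alpha1"] = r.theta1_truth.alpha if r.theta1_truth else np.nan
        row["truth_beta1"] = r.theta1_truth.beta if r.theta1_truth else np.nan
        row["truth_alpha3"] = r.theta3_truth.alpha if r.theta3_truth else np.nan
        row["truth_beta3"] = r.theta3_truth.beta if r.theta3_truth else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[ElicitationRecord], path, header_note: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        cohort_to_frame(records).to_csv(fh, index=False)


def read_cohort(path) -> list[ElicitationRecord]:
    df = pd.read_csv(path, comment="#")
    records = []
    for _, row in df.iterrows():
        probs = tuple(float(row[f"prob_{lab}"]) for lab in _Q_LABELS)
        v1 = tuple(float(row[f"theta1_{lab}"]) for lab in _Q_LABELS)
        v3 = tuple(float(row[f"theta3_{lab}"]) for lab in _Q_LABELS)
        truth1 = truth3 = None
        if np.isfinite(row.get("truth_alpha1", np.nan)):
            truth1 = BetaParams(float(row["truth_alpha1"]), float(row["truth_beta1"]))
            truth3 = BetaParams(float(row["truth_alpha3"]), float(row["truth_beta3"]))
        records.append(
            ElicitationRecord(
                expert_id=str(row["expert_id"]),
                practice=int(row["practice"]),
                archetype=str(row["archetype"]),
                probs=probs,
                theta1_values=v1,
                theta3_values=v3,
                p_worse=float(row["p_worse"]),
                theta1_truth=truth1,
                theta3_truth=truth3,
                pilot=bool(row.get("pilot", False)),
            )
        )
    return records
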