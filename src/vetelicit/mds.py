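"""Classical (Torgerson) multidimensional scaling of belief vectors.

Each expert contributes a 10-vector of elicited values (five quantiles for
theta1 followed by five for theta3).  Dissimilarity between experts i and j
is the squared Euclidean distance d_ij = (x_i - x_j)^T (x_i - x_j).  Double
centring -D/2 gives the inner-product matrix whose eigendecomposition yields
principal coordinates; the goodness of fit of an m-dimensional map is

    gof(m) = sum_{j<=m} lambda_j / sum_{i<=10} lambda_i

with the denominator running over the first 10 eigenvalues (the vectors live
in 10 dimensions, so at most 10 are positive).  Because the dissimilarities
are genuinely squared-Euclidean, negative eigenvalues can arise only from
floating-point noise and are truncated to zero.

Axis interpretation uses variable loadings: for squared-Euclidean input,
classical scaling coincides with principal components of the centred data
matrix, and the loading of elicited position p on axis k is the unit right
singular vector entry X_c^T u_k / sqrt(lambda_k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeliefVector",
    "ScalingResult",
    "POSITION_LABELS",
    "belief_vectors",
    "distance_matrix",
    "classical_scale",
    "scale_vectors",
    "axis_loadings",
]

POSITION_LABELS = (
    "theta1_min",
    "theta1_q25",
    "theta1_median",
    "theta1_q75",
    "theta1_max",
    "theta3_min",
    "theta3_q25",
    "theta3_median",
    "theta3_q75",
    "theta3_max",
)


@dataclass(frozen=True)
class BeliefVector:
    """One expert's 10 elicited values: 5 for theta1 then 5 for theta3."""

    expert_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 10:
            raise ValueError("belief vectors have exactly 10 entries")
        v = np.asarray(self.values)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("elicited values are probabilities in [0, 1]")


@dataclass
class ScalingResult:
    """Eigenvalues, coordinates and goodness of fit from classical scaling.

    ``eigenvalues`` are sorted descending with negatives truncated to zero;
    ``coordinates`` (n x r) hold eigenvectors scaled by sqrt(lambda) for the
    r positive eigenvalues; ``gof[m-1]`` is the fit of an m-dimensional map;
    ``loadings`` (10 x r) are per-variable axis loadings, present only when
    the scaling was computed from raw vectors.
    """

    eigenvalues: np.ndarray
    coordinates: np.ndarray
    gof: np.ndarray
    eigenvectors: np.ndarray
    loadings: np.ndarray | None = None
    expert_ids: tuple[str, ...] | None = None

    @property
    def rank(self) -> int:
        return self.coordinates.shape[1]


def belief_vectors(records: Sequence) -> list[BeliefVector]:
    """Assemble belief vectors from cohort records (real or synthetic)."""
    return [
        BeliefVector(
            expert_id=str(r.expert_id),
            values=tuple(r.theta1_values) + tuple(r.theta3_values),
        )
        for r in records
    ]


def distance_matrix(vectors: Sequence[BeliefVector]) -> np.ndarray:
    """Squared-Euclidean dissimilarity matrix between belief vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    X = np.array([v.values for v in vectors], dtype=float)
    sq = (X * X).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    # reproducible axis orientation: largest-magnitude entry positive
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def classical_scale(distances: np.ndarray, n_denominator: int = 10) -> ScalingResult:
    """Torgerson scaling of a squared-distance matrix.

    Double-centres -D/2, eigendecomposes, orders eigenvalues descending and
    returns coordinates for the positive eigenvalues.  ``gof`` uses the
    first ``n_denominator`` eigenvalues in the denominator (the
    dimensionality of the raw vectors).
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * (J @ D @ J)
    B = 0.5 * (B + B.T)
    w, V = np.linalg.eigh(B)
    order = np.argsort(w, kind="stable")[::-1]
    w = w[order]
    V = V[:, order]
    lam = np.clip(w, 0.0, None)
    tol = max(n, 10) * np.finfo(float).eps * max(lam.max(initial=0.0), 1.0)
    pos = lam > tol
    if not np.any(pos):
        raise ValueError("all eigenvalues are zero: degenerate (constant) configuration")
    V = _fix_signs(V.copy())
    coords = V[:, pos] * np.sqrt(lam[pos])
    denom = lam[: min(n_denominator, n)].sum()
    gof = np.cumsum(lam) / denom
    return ScalingResult(
        eigenvalues=lam,
        coordinates=coords,
        gof=gof,
        eigenvectors=V[:, pos],
    )


def scale_vectors(vectors: Sequence[BeliefVector]) -> ScalingResult:
    """Full scaling from raw belief vectors, with axis loadings attached."""
    result = classical_scale(distance_matrix(vectors))
    X = np.array([v.values for v in vectors], dtype=float)
    Xc = X - X.mean(axis=0)
    lam = result.eigenvalues[: result.rank]
    # unit right singular vectors of Xc: variable weights defining each axis
    result.loadings = (Xc.T @ result.eigenvectors) / np.sqrt(lam)
    result.expert_ids = tuple(v.expert_id for v in vectors)
    return result


def axis_loadings(result: ScalingResult, dimension: int) -> pd.Series:
    """Loadings of the 10 elicited positions on one axis, ranked by size.

    ``dimension`` is zero-based.  Requires a result produced by
    ``scale_vectors`` (loadings need the raw vectors, not just distances).
    """
    if result.loadings is None:
        raise ValueError("no loadings available: scale from raw vectors")
    if not 0 <= dimension < result.rank:
        raise IndexError(
            f"dimension {dimension} outside positive-eigenvalue rank {result.rank}"
        )
    s = pd.Series(result.loadings[:, dimension], index=list(POSITION_LABELS))
    return s.reindex(s.abs().sort_values(ascending=False).index)
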