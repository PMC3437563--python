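"""Two-stage equal-probability sampling of experts from practices.

Stage one selects k practices ("clusters") with probability proportional to
size by the systematic method: each cluster is assigned a run of integers
equal to its size along a cumulated list, the sampling interval is
total/k, a random start is drawn on [0, interval), and the selection points
start + j*interval (j = 0..k-1) — accumulated unrounded, floored per point —
are mapped to the clusters whose ranges contain them.  The method is
without-replacement provided the interval exceeds the largest cluster.
Stage two selects individuals within each chosen cluster by simple random
sampling without replacement; clusters smaller than the within-cluster quota
contribute all their members.  Together the two stages give every individual
the same inclusion probability (an "epsem" design) whenever no cluster is
exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ClusterFrame",
    "sampling_interval",
    "systematic_pps",
    "select_within",
    "two_stage_sample",
]


@dataclass(frozen=True)
class ClusterFrame:
    """Ordered sampling frame of (label, size) clusters.

    Cluster ``i`` is assigned the half-open integer range
    ``[cumsum(sizes[:i]), cumsum(sizes[:i+1]))``; the ranges partition
    ``[0, total)`` with cluster 1 starting at 0.
    """

    labels: tuple[str, ...]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sizes):
            raise ValueError("labels and sizes must have equal length")
        if len(self.sizes) == 0:
            raise ValueError("frame must contain at least one cluster")
        if any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be >= 1")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, int]]) -> "ClusterFrame":
        return cls(
            labels=tuple(str(lab) for lab, _ in pairs),
            sizes=tuple(int(s) for _, s in pairs),
        )

    @property
    def total(self) -> int:
        return sum(self.sizes)

    @property
    def ranges(self) -> list[tuple[int, int]]:
        starts = np.concatenate([[0], np.cumsum(self.sizes)])
        return [(int(starts[i]), int(starts[i + 1])) for i in range(len(self.sizes))]

    def size_of(self, label: str) -> int:
        return self.sizes[self.labels.index(label)]


def sampling_interval(total: int, k: int) -> float:
    """Systematic sampling interval total/k (e.g. 77/5 = 15.4)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if total < k:
        raise ValueError("total must be >= k")
    return total / k


def systematic_pps(frame: ClusterFrame, k: int, start: float) -> list[str]:
    """Systematic PPS selection of k distinct clusters.

    Selection points accumulate the unrounded interval from ``start``; each
    point is floored to an integer and looked up in the assigned ranges.
    Raises when the interval does not exceed the largest cluster, since the
    same cluster could then be hit twice.
    """
    interval = sampling_interval(frame.total, k)
    if not 0 <= start < interval:
        raise ValueError(f"start must lie in [0, {interval})")
    largest = max(frame.sizes)
    if interval <= largest:
        raise ValueError(
            f"sampling interval {interval} must exceed the largest cluster "
            f"({largest}) to guarantee without-replacement selection"
        )
    points = start + interval * np.arange(k)
    floored = np.floor(points).astype(int)
    bounds = np.cumsum(frame.sizes)  # exclusive upper bounds of the ranges
    idx = np.searchsorted(bounds, floored, side="right")
    chosen = [frame.labels[i] for i in idx]
    assert len(set(chosen)) == k  # guaranteed by the interval condition
    return chosen


def select_within(cluster_size: int, k: int, seed) -> list[int]:
    """Simple random sample of min(k, size) member indices, no replacement."""
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    rng = np.random.default_rng(seed)
    take = min(k, cluster_size)
    return sorted(int(i) for i in rng.choice(cluster_size, size=take, replace=False))


def two_stage_sample(
    frame: ClusterFrame,
    k_clusters: int,
    k_within: int,
    seed,
    start: float | None = None,
) -> list[tuple[str, list[int]]]:
    """Full two-stage design: PPS cluster selection, then SRS within.

    When ``start`` is None a uniform random start on [0, interval) is drawn
    from ``seed``; within-cluster draws use seeds spawned deterministically
    from the same sequence.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng = np.random.default_rng(ss.spawn(1)[0])
    interval = sampling_interval(frame.total, k_clusters)
    if start is None:
        start = float(rng.uniform(0.0, interval))
    chosen = systematic_pps(frame, k_clusters, start)
    children = ss.spawn(len(chosen) + 1)[1:]
    return [
        (lab, select_within(frame.size_of(lab), k_within, child))
        for lab, child in zip(chosen, children)
    ]
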