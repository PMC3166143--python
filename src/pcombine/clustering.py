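"""Normalization and greedy radius clustering of inverse weights.

Only the ratios of weights affect the combined p-value, so the inverse
weights ``1/w_i`` are rescaled to sum to ``L`` (average 1).  Nearly equal
inverse weights are then agglomerated: exactly identical values form one
cluster outright; afterwards the closest pair of cluster centers is merged
(occurrence-weighted mean) while their gap is below the radius ``r``.  The
surviving centers, multiplicities and per-member deviations parametrize the
stable series expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import InputDomainError, WeightedPValueSet, validate

__all__ = [
    "ClusterSet",
    "ClusterMoments",
    "normalize_inverse_weights",
    "cluster_inverse_weights",
    "cluster_moments",
]


@dataclass(frozen=True)
class ClusterSet:
    """Terminated clustering of normalized inverse weights.

    ``centers[j]`` is the mean of ``members[j]`` and distinct centers are
    pairwise separated by at least ``radius``.  ``deviations[j][i]`` is
    ``members[j][i] - centers[j]``; within each cluster the deviations sum
    to zero to machine precision.
    """

    radius: float
    centers: tuple[float, ...]
    members: tuple[tuple[float, ...], ...]

    @property
    def multiplicities(self) -> tuple[int, ...]:
        return tuple(len(m) for m in self.members)

    @property
    def deviations(self) -> tuple[tuple[float, ...], ...]:
        return tuple(
            tuple(x - c for x in mem) for c, mem in zip(self.centers, self.members)
        )

    @property
    def n_values(self) -> int:
        return sum(self.multiplicities)

    def max_relative_deviation(self) -> float:
        """``rho = max |delta_{j,i}| / center_j`` — the expansion parameter."""
        rho = 0.0
        for c, devs in zip(self.centers, self.deviations):
            for d in devs:
                rho = max(rho, abs(d) / c)
        return rho


@dataclass(frozen=True)
class ClusterMoments:
    """Power sums ``D_{j,k} = sum_i (delta_{j,i})^k`` for ``k = 1..max_order``.

    ``D_{j,1}`` vanishes by centering; ``D_{j,2}`` is the spread and
    ``D_{j,3}`` the skewness of the cluster's inverse weights.
    """

    sums: tuple[tuple[float, ...], ...]  # sums[j][k-1] = D_{j,k}
    max_order: int

    def D(self, j: int, k: int) -> float:
        if not 1 <= k <= self.max_order:
            raise ValueError(f"moment order {k} not computed (max {self.max_order})")
        return self.sums[j][k - 1]


def normalize_inverse_weights(pset: WeightedPValueSet) -> list[float]:
    """Inverse weights rescaled to sum to ``L``: ``lam_i = (1/w_i) L / sum(1/w_k)``."""
    validate(pset)
    inv = [1.0 / w for w in pset.weights]
    scale = len(inv) / math.fsum(inv)
    return [x * scale for x in inv]


def cluster_inverse_weights(lambdas: list[float], radius: float) -> ClusterSet:
    """Greedy hierarchical merge of inverse weights at clustering radius ``radius``.

    Identical values are pre-merged at distance zero regardless of the
    radius.  Then, repeatedly, the closest pair of current cluster centers
    is merged by its occurrence-weighted mean while the gap is strictly
    below ``radius``; ties are broken by merging the leftmost closest pair
    of the ascending-sorted centers.  Terminates when all center gaps are
    at least ``radius``.  Final centers are recomputed as exact member
    means, so within-cluster deviations sum to zero at machine precision.
    """
    if radius < 0:
        raise InputDomainError(f"clustering radius must be nonnegative, got {radius}")
    if not lambdas:
        raise InputDomainError("no inverse weights to cluster")
    # pre-merge exact duplicates, sort ascending
    groups: dict[float, list[float]] = {}
    for x in lambdas:
        groups.setdefault(float(x), []).append(float(x))
    clusters = sorted(groups.values(), key=lambda g: g[0])
    centers = [g[0] for g in clusters]

    def _center(members: list[float]) -> float:
        # mean of identical values is that value, bit-exactly
        if all(x == members[0] for x in members):
            return members[0]
        return math.fsum(members) / len(members)

    while len(centers) > 1:
        gaps = [centers[i + 1] - centers[i] for i in range(len(centers) - 1)]
        i = min(range(len(gaps)), key=lambda k: (gaps[k], k))  # leftmost closest
        if not gaps[i] < radius:
            break
        merged = clusters[i] + clusters[i + 1]
        clusters[i : i + 2] = [merged]
        # occurrence-weighted mean of the two centers == mean of all members
        centers[i : i + 2] = [_center(merged)]

    return ClusterSet(
        radius=float(radius),
        centers=tuple(_center(m) for m in clusters),
        members=tuple(tuple(m) for m in clusters),
    )


def cluster_moments(cs: ClusterSet, max_order: int) -> ClusterMoments:
    """Deviation power sums ``D_{j,k}`` for all clusters, ``k = 1..max_order``."""
    if max_order < 1:
        raise ValueError(f"max_order must be >= 1, got {max_order}")
    sums = []
    for devs in cs.deviations:
        sums.append(
            tuple(math.fsum(d**k for d in devs) for k in range(1, max_order + 1))
        )
    return ClusterMoments(sums=tuple(sums), max_order=max_order)
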