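"""k-medoids (PAM) over precomputed distance matrices and majority-rule scoring.

Family recovery is scored with the majority rule: each cluster is associated
with the true family of the majority of its members, and every member not of
that family counts as misclassified.  Because PAM is a heuristic, the
clustering is repeated over many seeds and the mean misclassification rate
(MMR) across repeats is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "ClusteringResult",
    "EvaluationReport",
    "k_medoids",
    "majority_misclassification",
    "mean_misclassification",
]


@dataclass
class ClusteringResult:
    assignments: dict[str, int]  # structure id -> cluster label 1..k
    medoids: list[str]
    seed: int
    n_iter: int
    converged: bool

    def labels(self, ids: Sequence[str]) -> list[int]:
        return [self.assignments[i] for i in ids]


@dataclass
class EvaluationReport:
    misclassification_rates: list[float]  # percent, one per repeat
    mmr: float  # percent
    repeats: int
    k: int
    base_seed: int
    per_cluster_majority: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mmr_percent": self.mmr,
            "repeats": self.repeats,
            "k": self.k,
            "base_seed": self.base_seed,
            "rates_percent": self.misclassification_rates,
            "last_run_majority": {str(k): v for k, v in self.per_cluster_majority.items()},
        }


def _init_medoids(values: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """k-medoids++-style seeding: next medoid drawn with prob ~ min-distance^2."""
    n = values.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        dmin = values[:, medoids].min(axis=1)
        w = dmin**2
        total = w.sum()
        if total == 0:  # duplicate points; fall back to uniform over non-medoids
            candidates = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(candidates)))
        else:
            medoids.append(int(rng.choice(n, p=w / total)))
    return medoids


def k_medoids(
    dm: DistanceMatrix, k: int, seed: int, max_iter: int = 300
) -> ClusteringResult:
    """PAM-style k-medoids on a precomputed distance matrix.

    Alternates nearest-medoid assignment with per-cluster medoid update (the
    member minimising total intra-cluster distance) until the medoid set is
    unchanged or ``max_iter`` is reached.  Deterministic given ``seed``; ties
    break towards the lowest index.
    """
    n = len(dm)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be between 1 and the number of items {n}")
    values = dm.values
    rng = np.random.default_rng(seed)
    medoids = _init_medoids(values, k, rng)

    def assign_points(meds: list[int]) -> np.ndarray:
        a = np.argmin(values[:, meds], axis=1)  # argmin is first-index on ties
        for c, mi in enumerate(meds):
            a[mi] = c  # a medoid always anchors its own cluster, even on ties
        return a

    assign = np.empty(n, dtype=int)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        assign = assign_points(medoids)
        new_medoids = list(medoids)
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue  # empty cluster keeps its medoid
            costs = values[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = int(members[int(np.argmin(costs))])
        if new_medoids == medoids:
            converged = True
            break
        medoids = new_medoids

    assign = assign_points(medoids)
    assignments = {dm.ids[i]: int(assign[i]) + 1 for i in range(n)}
    return ClusteringResult(
        assignments=assignments,
        medoids=[dm.ids[m] for m in medoids],
        seed=seed,
        n_iter=it,
        converged=converged,
    )


def majority_misclassification(
    assignments: Mapping[str, int], true_labels: Mapping[str, str]
) -> tuple[float, dict[int, str]]:
    """Majority-rule misclassification rate in percent.

    Each cluster is mapped to the family of the majority of its members (ties
    break to the lexicographically smallest family name); members of other
    families are misclassified.  Returns ``(rate_percent, cluster->family)``.
    """
    if set(assignments) != set(true_labels):
        raise ValueError("assignments and true labels must cover the same ids")
    clusters: dict[int, list[str]] = {}
    for sid, c in assignments.items():
        clusters.setdefault(c, []).append(true_labels[sid])
    majority: dict[int, str] = {}
    wrong = 0
    for c, fams in clusters.items():
        counts: dict[str, int] = {}
        for f in fams:
            counts[f] = counts.get(f, 0) + 1
        best = min(counts, key=lambda f: (-counts[f], f))
        majority[c] = best
        wrong += len(fams) - counts[best]
    rate = 100.0 * wrong / len(assignments)
    return rate, majority


def mean_misclassification(
    dm: DistanceMatrix,
    true_labels: Mapping[str, str],
    k: int,
    repeats: int,
    base_seed: int,
    max_iter: int = 300,
) -> EvaluationReport:
    """Repeat seeded k-medoids and average the majority-rule rates (the MMR).

    Run ``r`` uses seed ``base_seed + r`` so the whole experiment is exactly
    reproducible from ``base_seed``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rates: list[float] = []
    majority: dict[int, str] = {}
    for r in range(repeats):
        res = k_medoids(dm, k, seed=base_seed + r, max_iter=max_iter)
        rate, majority = majority_misclassification(res.assignments, true_labels)
        rates.append(rate)
    return EvaluationReport(
        misclassification_rates=rates,
        mmr=float(np.mean(rates)),
        repeats=repeats,
        k=k,
        base_seed=base_seed,
        per_cluster_majority=majority,
    )
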