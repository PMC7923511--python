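"""Deterministic Partitioning Around Medoids (PAM) and label alignment.

PAM assigns objects to K clusters, each anchored by a medoid (the member
minimizing total distance to the others), by minimizing the sum of distances
of every object to its cluster medoid. The implementation is the classical
Kaufman-Rousseeuw BUILD + SWAP algorithm with fully deterministic tie-breaking
(lowest index wins everywhere), so repeated runs are bit-identical - a
requirement for synchronized cluster labels across views.

Because cluster ids from any unsupervised method are arbitrary,
:func:`align_labels` matches another partition's clusters to a reference
partition by maximizing total membership overlap (Hungarian assignment on the
contingency table); unmatched clusters get fresh ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples

from .distance import DistanceMatrix, pairwise_binary_distance
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["Partition", "AlignmentMap", "PAMClusterer", "pam", "silhouette",
           "align_labels"]


@dataclass
class Partition:
    """Cluster labels (1..K), medoid object ids, and the total PAM cost."""

    labels: dict[str, int]
    medoids: list[str]
    K: int
    cost: float

    def label_array(self, ids: list[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return dict(sorted(sizes.items()))

    def members(self, c: int) -> list[str]:
        return [i for i, lab in self.labels.items() if lab == c]

    def to_tsv(self, path) -> None:
        meds = set(self.medoids)
        with open(path, "w") as fh:
            fh.write("object\tcluster\tis_medoid\n")
            for i, lab in self.labels.items():
                fh.write(f"{i}\t{lab}\t{int(i in meds)}\n")


class PAMClusterer(BaseEstimator, ClusterMixin):
    """K-medoid clustering on a precomputed distance matrix (or binary rows).

    Parameters
    ----------
    n_clusters : int
    metric : str
        ``"precomputed"`` (fit X is an n x n distance matrix) or one of the
        binary metric names (fit X is a 0/1 matrix, rows are objects).
    exact_limit : int
        When the number of candidate medoid sets C(n, K) is at most this
        bound, the globally optimal set is found by exhaustive enumeration
        (lexicographically smallest set on cost ties). BUILD+SWAP is a local
        search and can stall one swap short of the optimum even on tiny
        instances; enumeration guarantees the exact-cost contract there.
        Set to 0 to force BUILD+SWAP everywhere.

    Fitted attributes: ``labels_`` (0-based, ordered by medoid index),
    ``medoid_indices_`` (sorted), ``inertia_`` (total cost),
    ``build_inertia_`` (cost after the BUILD phase; equals ``inertia_`` on
    the exact path).
    """

    def __init__(self, n_clusters: int = 2, metric: str = "precomputed",
                 exact_limit: int = 5000):
        self.n_clusters = n_clusters
        self.metric = metric
        self.exact_limit = exact_limit

    def fit(self, X, y=None):
        import math

        D = np.asarray(X, dtype=np.float64)
        if self.metric != "precomputed":
            D = pairwise_binary_distance(D, self.metric)
        n = D.shape[0]
        if D.shape != (n, n):
            raise ValidationError("precomputed distance matrix must be square")
        K = self.n_clusters
        if not 1 <= K <= n:
            raise ValidationError(f"K={K} outside 1..{n}")

        if math.comb(n, K) <= self.exact_limit:
            medoids = self._exact(D, K)
            self.build_inertia_ = float(np.min(D[medoids], axis=0).sum())
        else:
            medoids = self._build(D, K)
            self.build_inertia_ = float(np.min(D[medoids], axis=0).sum())
            medoids = self._swap(D, medoids)
        medoids.sort()
        Dm = D[medoids]
        assign = np.argmin(Dm, axis=0)  # ties -> lowest medoid index
        self.medoid_indices_ = np.array(medoids)
        self.labels_ = assign
        self.inertia_ = float(Dm[assign, np.arange(n)].sum())
        return self

    @staticmethod
    def _exact(D: np.ndarray, K: int) -> list[int]:
        import itertools

        n = D.shape[0]
        best_cost = np.inf
        best: tuple[int, ...] | None = None
        for combo in itertools.combinations(range(n), K):
            cost = float(D[list(combo)].min(axis=0).sum())
            if cost < best_cost - 1e-12:  # ties -> first (lexicographic) set
                best_cost = cost
                best = combo
        return list(best)

    @staticmethod
    def _build(D: np.ndarray, K: int) -> list[int]:
        n = D.shape[0]
        first = int(np.argmin(D.sum(axis=1)))
        medoids = [first]
        nearest = D[first].copy()
        while len(medoids) < K:
            costs = np.minimum(nearest[None, :], D).sum(axis=1)
            costs[medoids] = np.inf
            c = int(np.argmin(costs))  # ties -> lowest index
            medoids.append(c)
            nearest = np.minimum(nearest, D[c])
        return medoids

    @staticmethod
    def _swap(D: np.ndarray, medoids: list[int]) -> list[int]:
        n = D.shape[0]
        medoids = sorted(medoids)
        if len(medoids) == n:
            return medoids
        while True:
            med = np.array(medoids)
            Dm = D[med]
            order = np.argsort(Dm, axis=0, kind="stable")
            idx = np.arange(n)
            d1 = Dm[order[0], idx]
            cost = d1.sum()
            d2 = Dm[order[1], idx] if len(medoids) > 1 else np.full(n, np.inf)
            nonmed = np.setdiff1d(idx, med)
            best_cost = cost
            best_swap: tuple[int, int] | None = None
            for mi in range(len(medoids)):  # medoids ascending -> lexicographic ties
                base = np.where(order[0] == mi, d2, d1)
                cand = np.minimum(base[None, :], D[nonmed]).sum(axis=1)
                j = int(np.argmin(cand))  # first minimum -> lowest candidate index
                if cand[j] < best_cost:
                    best_cost = float(cand[j])
                    best_swap = (mi, int(nonmed[j]))
            if best_swap is None:
                return medoids
            mi, h = best_swap
            medoids[mi] = h
            medoids.sort()


def pam(dm: DistanceMatrix, K: int) -> Partition:
    """Deterministic PAM on a distance matrix; labels 1..K by medoid order."""
    est = PAMClusterer(n_clusters=K, metric="precomputed").fit(dm.values)
    if est.inertia_ > est.build_inertia_ + 1e-9:
        raise AssertionError("SWAP increased cost")  # structural invariant
    labels = {dm.ids[i]: int(est.labels_[i]) + 1 for i in range(dm.n)}
    medoids = [dm.ids[i] for i in est.medoid_indices_]
    return Partition(labels=labels, medoids=medoids, K=K, cost=est.inertia_)


def silhouette(dm: DistanceMatrix, p: Partition) -> tuple[np.ndarray, float]:
    """Per-object silhouette widths and their mean (singletons score 0)."""
    if p.K < 2:
        raise ValidationError("silhouette needs K >= 2")
    labels = p.label_array(dm.ids)
    s = silhouette_samples(dm.values, labels, metric="precomputed")
    return s, float(s.mean())


@dataclass
class AlignmentMap:
    """cluster id (other) -> cluster id (reference); fresh ids for unmatched."""

    mapping: dict[int, int]
    overlap: pd.DataFrame  # rows = reference clusters, columns = other clusters
    matched: set[int]

    def apply(self, other: Partition) -> Partition:
        labels = {i: self.mapping[c] for i, c in other.labels.items()}
        medoids = list(other.medoids)
        return Partition(labels=labels, medoids=medoids, K=other.K, cost=other.cost)


def align_labels(ref: Partition, other: Partition) -> AlignmentMap:
    """Hungarian matching of ``other``'s clusters onto ``ref``'s cluster ids."""
    if set(ref.labels) != set(other.labels):
        raise ValidationError("partitions cover different object sets")
    ids = sorted(ref.labels)
    a = pd.Categorical([ref.labels[i] for i in ids])
    b = pd.Categorical([other.labels[i] for i in ids])
    tab = pd.crosstab(a, b)
    cost = -tab.to_numpy()
    rows, cols = linear_sum_assignment(cost)
    mapping: dict[int, int] = {}
    matched: set[int] = set()
    for r, c in zip(rows, cols):
        if tab.iloc[r, c] > 0:
            oc = int(tab.columns[c])
            mapping[oc] = int(tab.index[r])
            matched.add(oc)
    fresh = max(ref.labels.values(), default=0)
    for oc in sorted(int(c) for c in tab.columns):
        if oc not in mapping:
            fresh += 1
            mapping[oc] = fresh
    return AlignmentMap(mapping=mapping, overlap=tab, matched=matched)
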