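"""Binary distance metrics over 2x2 contingency counts.

Every metric here is a function of the contingency table of two 0/1 vectors:
``N11`` positions where both are 1, ``N10`` / ``N01`` mismatches, and ``N00``
positions where both are 0.  The flagship metric for sparse aberration data is
the Jaccard distance ``1 - N11/(N11 + N10 + N01)``, which ignores the
uninformative 0-0 matches; nine companions from the classical binary-similarity
literature (Choi et al.'s taxonomy) are provided so the whole pipeline can be
re-run under a different notion of similarity.

Degenerate-denominator conventions (all chosen so identical vectors are always
at distance 0):

* Jaccard / Binary on two all-zero vectors -> 0;
* Pearson with a zero marginal -> 0 if the vectors are equal, else 1;
* Goodman-Kruskal with ``2n == sigma'`` -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import BinaryMatrix

__all__ = [
    "ContingencyCounts", "DistanceMatrix", "METRICS", "contingency",
    "metric_distance", "distance_matrix", "pairwise_binary_distance",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """The 2x2 table underlying every binary metric."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def contingency(u: Sequence[int], v: Sequence[int]) -> ContingencyCounts:
    """Count 1-1, 1-0, 0-1 and 0-0 positions of two equal-length 0/1 vectors."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError(f"length mismatch: {u.shape} vs {v.shape}")
    if u.size < 1:
        raise ValidationError("vectors must have length >= 1")
    ub = u.astype(bool)
    vb = v.astype(bool)
    n11 = int(np.sum(ub & vb))
    n10 = int(np.sum(ub & ~vb))
    n01 = int(np.sum(~ub & vb))
    n00 = int(np.sum(~ub & ~vb))
    return ContingencyCounts(n11, n10, n01, n00)


# -- metric formulas (vectorized over count arrays) -------------------------

def _jaccard(n11, n10, n01, n00):
    den = n11 + n10 + n01
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - n11 / den
    return np.where(den == 0, 0.0, d)


def _sokal_michener(n11, n10, n01, n00):
    n = n11 + n10 + n01 + n00
    return 1.0 - (n11 + n00) / n


def _hamming(n11, n10, n01, n00):
    n = n11 + n10 + n01 + n00
    return (n10 + n01) / n


def _russell_rao(n11, n10, n01, n00):
    n = n11 + n10 + n01 + n00
    return 1.0 - n11 / n


def _pearson(n11, n10, n01, n00):
    den2 = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n11 * n00 - n10 * n01) / np.sqrt(den2)
        d = (1.0 - phi) / 2.0
    equal = (n10 + n01) == 0
    return np.where(den2 == 0, np.where(equal, 0.0, 1.0), d)


def _goodman_kruskal(n11, n10, n01, n00):
    n = n11 + n10 + n01 + n00
    sigma = (np.maximum(n11, n10) + np.maximum(n01, n00)
             + np.maximum(n11, n01) + np.maximum(n10, n00))
    sigma_p = (np.maximum(n11 + n01, n10 + n00)
               + np.maximum(n11 + n10, n01 + n00))
    den = 2.0 * n - sigma_p
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - (sigma - sigma_p) / den
    return np.where(den == 0, 0.0, d)


def _manhattan(n11, n10, n01, n00):
    return (n10 + n01).astype(float) if hasattr(n10, "astype") else float(n10 + n01)


def _euclidean(n11, n10, n01, n00):
    return np.sqrt(n10 + n01)


def _canberra(n11, n10, n01, n00):
    # per position |u-v|/(u+v): 1 on mismatches, 0 elsewhere (0/0 -> 0)
    return _manhattan(n11, n10, n01, n00)


_METRIC_FUNCS = {
    "jaccard": _jaccard,
    "sokal-michener": _sokal_michener,
    "hamming": _hamming,
    "russell-rao": _russell_rao,
    "pearson": _pearson,
    "goodman-kruskal": _goodman_kruskal,
    "manhattan": _manhattan,
    "canberra": _canberra,
    "binary": _jaccard,  # same asymmetric-binary formula as Jaccard
    "euclidean": _euclidean,
}

METRICS = tuple(_METRIC_FUNCS)


def _normalize_metric(name: str) -> str:
    key = name.strip().lower().replace("_", "-").replace(" & ", "-").replace(" ", "-")
    aliases = {"sokal-and-michener": "sokal-michener",
               "goodman-and-kruskal": "goodman-kruskal",
               "russell-and-rao": "russell-rao"}
    key = aliases.get(key, key)
    if key not in _METRIC_FUNCS:
        raise ValidationError(f"unknown metric {name!r}; valid metrics: {sorted(METRICS)}")
    return key


def metric_distance(name: str, c: ContingencyCounts) -> float:
    """Evaluate one of the ten registered metrics on a contingency table."""
    func = _METRIC_FUNCS[_normalize_metric(name)]
    return float(func(np.float64(c.n11), np.float64(c.n10),
                      np.float64(c.n01), np.float64(c.n00)))


def pairwise_binary_distance(X: np.ndarray, metric: str = "jaccard") -> np.ndarray:
    """Full pairwise distance matrix over the rows of a 0/1 array.

    Contingency counts for all pairs come from one matrix product; the result
    is exactly symmetric with a zero diagonal, independent of evaluation order.
    """
    func = _METRIC_FUNCS[_normalize_metric(metric)]
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    n11 = X @ X.T
    r = X.sum(axis=1)
    n10 = r[:, None] - n11
    n01 = r[None, :] - n11
    n00 = d - n11 - n10 - n01
    D = np.asarray(func(n11, n10, n01, n00), dtype=np.float64)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class DistanceMatrix:
    """A labeled symmetric distance matrix over samples or features."""

    ids: list[str]
    values: np.ndarray
    metric: str
    axis: str = "samples"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.values.shape} "
                                  f"does not match {n} ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, index: Sequence[int]) -> "DistanceMatrix":
        index = list(index)
        return DistanceMatrix(ids=[self.ids[i] for i in index],
                              values=self.values[np.ix_(index, index)].copy(),
                              metric=self.metric, axis=self.axis)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", index_label=f"{self.metric}:{self.axis}")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        tag = str(df.index.name or "unknown:samples")
        metric, _, axis = tag.partition(":")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(),
                   metric=metric, axis=axis or "samples")


def distance_matrix(m: BinaryMatrix, metric: str = "jaccard",
                    axis: str = "samples") -> DistanceMatrix:
    """Pairwise distances between samples (rows) or features (columns)."""
    metric = _normalize_metric(metric)
    if axis == "samples":
        X = m.values
        ids = list(m.sample_ids)
    elif axis == "features":
        X = m.values.T
        ids = m.raw_names
    else:
        raise ValidationError(f"axis must be 'samples' or 'features', got {axis!r}")
    if X.shape[0] < 2:
        raise ValidationError(f"need at least 2 objects on axis {axis!r}")
    D = pairwise_binary_distance(X, metric)
    return DistanceMatrix(ids=ids, values=D, metric=metric, axis=axis)
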