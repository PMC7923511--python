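"""Redundant-feature reduction.

Whole-arm or whole-chromosome copy-number events set many cytoband columns to
the same value in every sample, so a cohort matrix typically carries large
groups of bitwise-identical feature columns. Collapsing each group to a single
representative (keeping a provenance map so full band lists can be recovered
later) shrinks the matrix without changing any sample-to-sample distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ValidationError
from .io import BinaryMatrix, FeatureName

logger = logging.getLogger(__name__)

__all__ = ["DedupMap", "DuplicateCollapser", "collapse_duplicates",
           "drop_empty", "expand_events"]


@dataclass
class DedupMap:
    """Representative feature -> list of original member features.

    Members partition the original feature set; the representative is the
    first member in original column order.
    """

    groups: dict[str, list[FeatureName]]

    @property
    def representatives(self) -> list[str]:
        return list(self.groups)

    def multiplicity(self, rep: str) -> int:
        return len(self.groups[rep])

    def members(self, rep: str) -> list[FeatureName]:
        if rep not in self.groups:
            raise ValidationError(f"unknown representative {rep!r}")
        return list(self.groups[rep])

    def report_name(self, rep: str) -> str:
        """Representative header with a '.x<multiplicity>' suffix for reports."""
        k = self.multiplicity(rep)
        return rep if k == 1 else f"{rep}.x{k}"

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("representative\tmember\n")
            for rep, members in self.groups.items():
                for m in members:
                    fh.write(f"{rep}\t{m.raw}\n")
        return path


class DuplicateCollapser(BaseEstimator, TransformerMixin):
    """Transformer collapsing bitwise-identical columns to unique representatives.

    Fitted attributes
    -----------------
    groups_ : list[list[int]]
        Column indices of each duplicate group, ordered by first occurrence.
    representative_indices_ : list[int]
        First column index of each group.
    """

    def fit(self, X, y=None):
        X = np.asarray(X)
        seen: dict[bytes, int] = {}
        groups: list[list[int]] = []
        for j in range(X.shape[1]):
            key = np.ascontiguousarray(X[:, j]).tobytes()
            if key in seen:
                groups[seen[key]].append(j)
            else:
                seen[key] = len(groups)
                groups.append([j])
        self.groups_ = groups
        self.representative_indices_ = [g[0] for g in groups]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        return X[:, self.representative_indices_]


def collapse_duplicates(m: BinaryMatrix) -> tuple[BinaryMatrix, DedupMap]:
    """Collapse identical feature columns; return the reduced matrix and map."""
    coll = DuplicateCollapser().fit(m.values)
    reduced = m.select_features(coll.representative_indices_)
    groups = {m.features[g[0]].raw: [m.features[j] for j in g]
              for g in coll.groups_}
    logger.info("collapsed %d features to %d unique columns", m.d, reduced.d)
    return reduced, DedupMap(groups=groups)


def drop_empty(m: BinaryMatrix) -> BinaryMatrix:
    """Remove all-zero feature columns (they carry no pattern information)."""
    keep = np.flatnonzero(m.values.any(axis=0))
    if keep.size == 0:
        raise ValidationError("every feature column is empty; nothing to analyze")
    dropped = m.d - keep.size
    if dropped:
        logger.info("dropped %d empty feature columns", dropped)
    return m.select_features(keep) if dropped else m


def expand_events(dmap: DedupMap, reps: Iterable[str | FeatureName]) -> set[FeatureName]:
    """Union of member features behind a set of representatives."""
    out: set[FeatureName] = set()
    for rep in reps:
        raw = rep.raw if isinstance(rep, FeatureName) else rep
        out.update(dmap.members(raw))
    return out
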