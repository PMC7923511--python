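"""Cluster characterization by recurrent cytogenetic events.

After sample clustering, the informative features are themselves clustered
into "elementary event" groups (a whole-arm loss, a recurrent translocation,
...). Each group is classified by the event types and chromosomes of its
member bands, and every sample cluster is summarized by the fraction of its
members exhibiting each event group - a sample "exhibits" a group when ANY
member feature (expanded through the duplicate-column map) equals 1. From the
resulting frequency table come the per-cluster top-event reports (default 60%
cutoff), the coverage summary over a ladder of thresholds, the per-cluster
disease-prevalence mix, and the two-way (1 - Pearson correlation, Ward)
heatmap ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list

from .cluster import Partition, pam
from .dimension import AuerGerviniDimension
from .distance import DistanceMatrix, distance_matrix
from .exceptions import ValidationError
from .graph_view import hclust_ward
from .io import BinaryMatrix, FeatureName
from .reduce import DedupMap, expand_events

logger = logging.getLogger(__name__)

__all__ = ["EventGroup", "FrequencyTable", "ClusterReport", "cluster_features",
           "event_signature", "event_frequency", "coverage_summary",
           "top_events", "disease_prevalence", "heatmap_order"]

_KLASS_RULES = {
    frozenset({"Loss"}): "loss-only",
    frozenset({"Gain"}): "gain-only",
    frozenset({"Fusion"}): "fusion-only",
    frozenset({"Fusion", "Loss"}): "fusion+loss",
    frozenset({"Fusion", "Gain"}): "fusion+gain",
}


@dataclass
class EventGroup:
    """A feature cluster interpreted as one elementary cytogenetic event."""

    id: int
    bands: set[str]
    types: set[str]
    chromosomes: set[str]
    klass: str
    members: list[str] = field(default_factory=list)  # representative headers


@dataclass
class FrequencyTable:
    """Sample-cluster x event-group table of exhibit fractions in [0, 1]."""

    values: np.ndarray            # C x G fractions
    counts: np.ndarray            # C x G integer numerators
    cluster_ids: list[int]
    group_ids: list[int]
    cluster_sizes: list[int]

    def row_max(self) -> np.ndarray:
        return self.values.max(axis=1)


@dataclass
class ClusterReportRow:
    cluster: int
    size: int
    events: list[tuple[int, float]]       # (group id, frequency), freq >= cutoff
    diseases: dict[str, float]
    characterized: bool


@dataclass
class ClusterReport:
    rows: list[ClusterReportRow]
    cutoff: float


def cluster_features(m: BinaryMatrix, metric: str = "jaccard",
                     q: int | None = None) -> tuple[Partition, int]:
    """Cluster features into event groups: PAM at the chosen PC dimension.

    ``m`` should already be deduplicated and outlier-filtered. ``q`` overrides
    the Auer-Gervini dimension choice (e.g. to pin a known group count).
    """
    if m.d < 2:
        raw = m.features[0].raw
        return Partition(labels={raw: 1}, medoids=[raw], K=1, cost=0.0), 1
    if q is None:
        est = AuerGerviniDimension(standardize=True).fit(m.values)
        q = est.n_components_
    K = max(1, min(int(q), m.d))
    dm = distance_matrix(m, metric=metric, axis="features")
    if K == 1:
        raws = m.raw_names
        med = raws[int(np.argmin(dm.values.sum(axis=1)))]
        part = Partition(labels={r: 1 for r in raws}, medoids=[med], K=1,
                         cost=float(dm.values[raws.index(med)].sum()))
    else:
        part = pam(dm, K)
    return part, K


def _classify(types: set[str]) -> str:
    known = frozenset(t for t in types if t != "Unknown")
    klass = _KLASS_RULES.get(known, "mixed")
    if klass == "mixed":
        logger.info("event group with types %s classified as 'mixed'", sorted(types))
    return klass


def event_signature(fp: Partition, dmap: DedupMap,
                    names: Sequence[FeatureName]) -> list[EventGroup]:
    """Interpret each feature cluster: expanded band set, event types, class."""
    by_raw = {f.raw: f for f in names}
    groups: list[EventGroup] = []
    for c in sorted(set(fp.labels.values())):
        reps = [r for r, lab in fp.labels.items() if lab == c]
        members = expand_events(dmap, [by_raw[r] for r in reps])
        types = {f.etype for f in members}
        bands = {f.band for f in members}
        chroms = {f.chromosome for f in members}
        groups.append(EventGroup(id=c, bands=bands, types=types,
                                 chromosomes=chroms, klass=_classify(types),
                                 members=sorted(reps)))
    return groups


def event_frequency(m: BinaryMatrix, sp: Partition, groups: Sequence[EventGroup],
                    dmap: DedupMap) -> FrequencyTable:
    """Fraction of each sample cluster exhibiting (>= 1 member feature) each group."""
    col = {r: j for j, r in enumerate(m.raw_names)}
    hit = np.zeros((m.n, len(groups)), dtype=bool)
    for g_idx, g in enumerate(groups):
        cols = [col[r] for r in g.members if r in col]
        if not cols:
            raise ValidationError(f"event group {g.id} has no feature in the matrix")
        hit[:, g_idx] = m.values[:, cols].any(axis=1)
    cluster_ids = sorted(set(sp.labels.values()))
    labels = sp.label_array(m.sample_ids)
    counts = np.zeros((len(cluster_ids), len(groups)), dtype=np.int64)
    sizes: list[int] = []
    for ci, c in enumerate(cluster_ids):
        mask = labels == c
        size = int(mask.sum())
        if size == 0:
            raise ValidationError(f"cluster {c} is empty")
        sizes.append(size)
        counts[ci] = hit[mask].sum(axis=0)
    values = counts / np.array(sizes)[:, None]
    return FrequencyTable(values=values, counts=counts, cluster_ids=cluster_ids,
                          group_ids=[g.id for g in groups], cluster_sizes=sizes)


def coverage_summary(ft: FrequencyTable,
                     thresholds: Sequence[float] = (0.99, 0.95, 0.90, 0.80, 0.70, 0.60)
                     ) -> dict[float, int]:
    """For each threshold, the number of clusters with some event above it."""
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValidationError(f"threshold {t} outside (0, 1]")
    row_max = ft.row_max()
    return {float(t): int(np.sum(row_max >= t)) for t in thresholds}


def top_events(ft: FrequencyTable, cutoff: float = 0.60,
               labels: Mapping[str, str] | None = None,
               sp: Partition | None = None) -> ClusterReport:
    """Per cluster, events at frequency >= cutoff, sorted by frequency then id."""
    if not 0 < cutoff <= 1:
        raise ValidationError(f"cutoff {cutoff} outside (0, 1]")
    prev = (disease_prevalence(sp, labels) if labels is not None and sp is not None
            else {})
    rows: list[ClusterReportRow] = []
    for ci, c in enumerate(ft.cluster_ids):
        freqs = ft.values[ci]
        ev = [(g, float(f)) for g, f in zip(ft.group_ids, freqs) if f >= cutoff]
        ev.sort(key=lambda t: (-t[1], t[0]))
        rows.append(ClusterReportRow(cluster=c, size=ft.cluster_sizes[ci],
                                     events=ev, diseases=prev.get(c, {}),
                                     characterized=bool(ev)))
    return ClusterReport(rows=rows, cutoff=cutoff)


def disease_prevalence(sp: Partition,
                       labels: Mapping[str, str]) -> dict[int, dict[str, float]]:
    """Per cluster, the fraction of each disease label (missing -> 'unknown')."""
    out: dict[int, dict[str, float]] = {}
    for c in sorted(set(sp.labels.values())):
        members = sp.members(c)
        tally: dict[str, int] = {}
        for s in members:
            disease = labels.get(s, "unknown") if labels else "unknown"
            tally[disease] = tally.get(disease, 0) + 1
        out[c] = {dz: k / len(members) for dz, k in sorted(tally.items())}
    return out


def _corr_distance(M: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; zero-variance rows -> corr 0."""
    sd = M.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.info("heatmap: %d zero-variance profiles (correlation set to 0)",
                    int(zero.sum()))
    Mc = M - M.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * M.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Mc @ Mc.T) / denom
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    D = 1.0 - corr
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return D


def heatmap_order(ft: FrequencyTable) -> tuple[list[int], list[int], np.ndarray, np.ndarray]:
    """Two-way (1 - Pearson, Ward) ordering of event groups and sample clusters.

    Returns (row order over group ids, column order over cluster ids,
    row linkage, column linkage); rows are event groups.
    """
    M = ft.values.T  # groups x clusters
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValidationError("heatmap needs >= 2 event groups and >= 2 clusters")
    Zr = hclust_ward(DistanceMatrix(ids=[str(g) for g in ft.group_ids],
                                    values=_corr_distance(M), metric="pearson",
                                    axis="features"))
    Zc = hclust_ward(DistanceMatrix(ids=[str(c) for c in ft.cluster_ids],
                                    values=_corr_distance(M.T), metric="pearson",
                                    axis="samples"))
    row_order = [ft.group_ids[i] for i in leaves_list(Zr)]
    col_order = [ft.cluster_ids[i] for i in leaves_list(Zc)]
    return row_order, col_order, Zr, Zc


def report_to_markdown(report: ClusterReport, group_names: Mapping[int, str] | None = None
                       ) -> str:
    """Markdown cluster report: cluster, size, events >= cutoff, disease mix."""
    lines = ["| cluster | size | events (frequency) | diseases |",
             "|---|---|---|---|"]
    for row in report.rows:
        evs = "; ".join(
            f"{(group_names or {}).get(g, f'G{g}')} ({f:.2f})" for g, f in row.events
        ) or "(uncharacterized)"
        dzs = "; ".join(f"{d} ({f:.2f})" for d, f in row.diseases.items())
        lines.append(f"| {row.cluster} | {row.size} | {evs} | {dzs} |")
    return "\n".join(lines) + "\n"
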