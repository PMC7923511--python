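"""Recovery metrics against the ground truth of a simulated cohort.

These helpers run the full reduction + clustering + characterization path on a
synthetic cohort and score the result against the generative truth: adjusted
Rand index of the sample partition, whether the chosen dimension brackets the
planted cluster count, and the mean absolute error between recovered event
frequencies and the planted penetrances (over the planted signature entries,
with recovered clusters matched to true clusters and recovered event groups
matched to true events by majority membership).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .characterize import cluster_features, event_frequency, event_signature
from .cluster import pam
from .dimension import (ThresherParams, auer_gervini, eigen_spectrum,
                        select_dimension, thresher_filter)
from .distance import distance_matrix
from .io import BinaryMatrix
from .reduce import DedupMap, collapse_duplicates, drop_empty
from .synthetic import GroundTruth, SimSpec, simulate

__all__ = ["RecoveryResult", "reduce_informative", "recover"]


@dataclass
class RecoveryResult:
    ari: float                     # PAM at true K vs planted clusters
    chosen_q: int                  # automatic (twice-mean) sample dimension
    broken_stick_q: int
    long_step_candidates: list[int]
    feature_candidates: list[int]  # long steps of the feature-side spectrum
    feature_ari: float             # feature clusters at true E vs planted events
    frequency_mae: float           # over planted signature entries
    mean_silhouette: float
    n_unique: int
    n_informative: int


def reduce_informative(m: BinaryMatrix, delta: float = 0.3
                       ) -> tuple[BinaryMatrix, DedupMap]:
    """drop_empty -> collapse_duplicates -> Thresher filter, returning the
    informative matrix and the (restricted) duplicate map."""
    reduced, dmap = collapse_duplicates(drop_empty(m))
    kept, _, _ = thresher_filter(reduced, ThresherParams(delta=delta))
    kept_raws = {f.raw for f in kept}
    keep_idx = [j for j, f in enumerate(reduced.features) if f.raw in kept_raws]
    informative = reduced.select_features(keep_idx)
    dmap = DedupMap(groups={r: g for r, g in dmap.groups.items()
                            if r in kept_raws})
    return informative, dmap


def _match_clusters(true_labels: np.ndarray, found_labels: np.ndarray
                    ) -> dict[int, int]:
    """found cluster id -> true cluster id, by Hungarian overlap matching."""
    tvals = np.unique(true_labels)
    fvals = np.unique(found_labels)
    tab = np.zeros((tvals.size, fvals.size), dtype=np.int64)
    for i, t in enumerate(tvals):
        for j, f in enumerate(fvals):
            tab[i, j] = int(np.sum((true_labels == t) & (found_labels == f)))
    rows, cols = linear_sum_assignment(-tab)
    return {int(fvals[j]): int(tvals[i]) for i, j in zip(rows, cols)}


def recover(spec: SimSpec, seed: int | None = None,
            metric: str = "jaccard") -> RecoveryResult:
    """Simulate one cohort from ``spec`` and score the pipeline against truth."""
    m, truth = simulate(spec, seed=seed)
    informative, dmap = reduce_informative(m)

    # automatic sample-side dimension (twice-mean long step)
    s = eigen_spectrum(informative)
    est = select_dimension(auer_gervini(s), s)

    # sample clustering at the true planted K
    dm = distance_matrix(informative, metric=metric, axis="samples")
    sp = pam(dm, spec.K)
    found = sp.label_array(m.sample_ids)
    ari = float(adjusted_rand_score(truth.cluster_labels, found))
    from .cluster import silhouette
    _, mean_sil = silhouette(dm, sp) if spec.K >= 2 else (None, float("nan"))

    # feature-side: long-step candidates + clustering at the true event count
    s2 = eigen_spectrum(informative, standardize=True)
    est2 = select_dimension(auer_gervini(s2), s2)
    E = len(spec.events)
    fp, _ = cluster_features(informative, metric=metric, q=E)
    ev_truth = [truth.feature_to_event[r] for r in informative.raw_names]
    feature_ari = float(adjusted_rand_score(
        ev_truth, fp.label_array(informative.raw_names)))

    # frequency table vs planted penetrances over signature entries
    groups = event_signature(fp, dmap, informative.features)
    ft = event_frequency(informative, sp, groups, dmap)
    mae = _frequency_mae(ft, groups, truth, found)

    return RecoveryResult(
        ari=ari, chosen_q=est.chosen_q, broken_stick_q=est.broken_stick_q,
        long_step_candidates=est.long_step_candidates,
        feature_candidates=est2.long_step_candidates,
        feature_ari=feature_ari, frequency_mae=mae,
        mean_silhouette=float(mean_sil),
        n_unique=len(dmap.groups), n_informative=informative.d,
    )


def _frequency_mae(ft, groups, truth: GroundTruth, found_labels: np.ndarray) -> float:
    """MAE between recovered frequencies and planted penetrances.

    Recovered clusters are matched to true clusters by overlap; each event
    group is matched to the majority true event of its member features; only
    entries with a planted (nonzero-penetrance) signature are compared.
    """
    c2t = _match_clusters(truth.cluster_labels, found_labels)
    group_event: dict[int, int | None] = {}
    for g in groups:
        evs = [truth.feature_to_event[r] for r in g.members
               if r in truth.feature_to_event]
        ev = max(set(evs), key=evs.count) if evs else "outlier"
        group_event[g.id] = int(ev[1:]) if ev.startswith("E") else None
    P = truth.penetrance
    errors: list[float] = []
    for ci, cid in enumerate(ft.cluster_ids):
        tc = c2t.get(cid)
        if tc is None:
            continue
        for gi, gid in enumerate(ft.group_ids):
            e = group_event[gid]
            if e is not None and P[tc, e] > 0:
                errors.append(abs(float(ft.values[ci, gi]) - float(P[tc, e])))
    return float(np.mean(errors)) if errors else float("nan")
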