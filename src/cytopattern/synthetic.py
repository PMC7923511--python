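"""Synthetic sparse binary cohorts with planted structure and full ground truth.

The generator emulates the shape of cytoband-level loss/gain/fusion data:

* **event blocks** - a cytogenetic event (say a whole-arm gain) switches on a
  contiguous block of ``n_bands`` feature columns together, mimicking the
  duplicated columns that large copy-number changes produce;
* **planted sample clusters** - each cluster has a signature: a set of events
  carried by its members with a per-event penetrance ``p``;
* **background noise** - independent 0->1 bit flips on the event columns
  (false aberration calls); flips never erase planted events, the way a called
  whole-arm gain is internally consistent across its bands;
* **outlier features** - iid Bernoulli columns unrelated to any structure,
  the kind of uninformative feature the outlier filter should remove.

Everything is deterministic given the seed, and the returned
:class:`GroundTruth` records the cluster of every sample, the event (or
"outlier") behind every feature, and the planted penetrance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io import BinaryMatrix, FeatureName, parse_feature_name

__all__ = ["EventSpec", "SimSpec", "GroundTruth", "simulate", "default_spec"]

_ETYPE_CODE = {"Loss": "L", "Gain": "G", "Fusion": "F"}


@dataclass(frozen=True)
class EventSpec:
    """One elementary event: type, chromosome, and the band count of its block."""

    etype: str
    chromosome: str
    n_bands: int

    def __post_init__(self) -> None:
        if self.etype not in _ETYPE_CODE:
            raise ValidationError(f"etype must be Loss/Gain/Fusion, got {self.etype!r}")
        if self.n_bands < 1:
            raise ValidationError("n_bands must be >= 1")


@dataclass(frozen=True)
class SimSpec:
    """Full description of a synthetic cohort."""

    n_samples: int
    proportions: tuple[float, ...]
    events: tuple[EventSpec, ...]
    signatures: tuple[tuple[tuple[int, float], ...], ...]  # per cluster: (event, p)
    noise_eps: float = 0.01
    n_outlier_features: int = 0
    outlier_rate: float = 0.02
    seed: int = 42
    symmetric_noise: bool = False

    def __post_init__(self) -> None:
        K = len(self.proportions)
        if K < 1 or abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError("mixing proportions must sum to 1")
        if len(self.signatures) != K:
            raise ValidationError("one signature per cluster required")
        for sig in self.signatures:
            for e, p in sig:
                if not 0 <= e < len(self.events):
                    raise ValidationError(f"signature references unknown event {e}")
                if not 0 <= p <= 1:
                    raise ValidationError(f"penetrance {p} outside [0, 1]")
        if not 0 <= self.noise_eps < 1:
            raise ValidationError("noise_eps must be in [0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ValidationError("outlier_rate must be in [0, 1)")
        if self.n_outlier_features < 0:
            raise ValidationError("n_outlier_features must be >= 0")
        counts = _cluster_counts(self.n_samples, self.proportions)
        if min(counts) < 1:
            raise ValidationError("a cluster would be empty at this n; "
                                  "increase n_samples or rebalance proportions")

    @property
    def K(self) -> int:
        return len(self.proportions)

    @property
    def n_event_features(self) -> int:
        return sum(e.n_bands for e in self.events)

    @property
    def d(self) -> int:
        return self.n_event_features + self.n_outlier_features

    def penetrance_matrix(self) -> np.ndarray:
        """K x E matrix of planted penetrances (0 where an event is unused)."""
        P = np.zeros((self.K, len(self.events)))
        for c, sig in enumerate(self.signatures):
            for e, p in sig:
                P[c, e] = p
        return P


@dataclass
class GroundTruth:
    """Generative truth for one simulated cohort."""

    sample_to_cluster: dict[str, int]
    feature_to_event: dict[str, str]  # raw header -> "E<k>" or "outlier"
    penetrance: np.ndarray            # K x E
    cluster_labels: np.ndarray = field(repr=False)  # per-sample, 0-based
    event_of_feature: np.ndarray = field(repr=False)  # per-column, -1 = outlier


def _cluster_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n samples over the clusters."""
    raw = [p * n for p in proportions]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _feature_names(spec: SimSpec) -> tuple[list[FeatureName], np.ndarray]:
    names: list[FeatureName] = []
    event_of: list[int] = []
    for e, ev in enumerate(spec.events):
        code = _ETYPE_CODE[ev.etype]
        for b in range(1, ev.n_bands + 1):
            names.append(parse_feature_name(f"{ev.chromosome}q{b}.{code}"))
            event_of.append(e)
    outlier_chroms = [str(c) for c in range(13, 23)] + ["X", "Y"]
    for j in range(spec.n_outlier_features):
        chrom = outlier_chroms[j % len(outlier_chroms)]
        idx = j // len(outlier_chroms) + 1
        names.append(parse_feature_name(f"{chrom}p{idx}.G"))
        event_of.append(-1)
    raws = [f.raw for f in names]
    if len(set(raws)) != len(raws):
        raise ValidationError("synthetic feature names collide; reduce block sizes")
    return names, np.array(event_of)


def simulate(spec: SimSpec, seed: int | None = None) -> tuple[BinaryMatrix, GroundTruth]:
    """Draw one cohort from ``spec`` (``seed`` overrides ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, K, E = spec.n_samples, spec.K, len(spec.events)
    counts = _cluster_counts(n, spec.proportions)
    clusters = np.repeat(np.arange(K), counts)
    rng.shuffle(clusters)

    P = spec.penetrance_matrix()
    carry = rng.random((n, E)) < P[clusters]          # sample i carries event e
    repeats = np.array([ev.n_bands for ev in spec.events])
    X_event = np.repeat(carry, repeats, axis=1)
    if spec.noise_eps > 0:
        noise = rng.random(X_event.shape) < spec.noise_eps
        if spec.symmetric_noise:
            X_event = X_event ^ noise
        else:
            X_event = X_event | noise                  # 0->1 flips only
    if spec.n_outlier_features > 0:
        X_out = rng.random((n, spec.n_outlier_features)) < spec.outlier_rate
        X = np.hstack([X_event, X_out])
    else:
        X = X_event

    features, event_of = _feature_names(spec)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    labels = {s: f"C{c + 1}" for s, c in zip(sample_ids, clusters)}
    m = BinaryMatrix(sample_ids=sample_ids, features=features,
                     values=X.astype(np.int8), labels=labels)
    truth = GroundTruth(
        sample_to_cluster={s: int(c) for s, c in zip(sample_ids, clusters)},
        feature_to_event={f.raw: ("outlier" if e < 0 else f"E{e}")
                          for f, e in zip(features, event_of)},
        penetrance=P,
        cluster_labels=clusters,
        event_of_feature=event_of,
    )
    return m, truth


def default_spec() -> SimSpec:
    """The documented study conditions used by all cross-module recovery tests.

    600 samples in 5 equally likely clusters; 12 events of 8 bands each on
    chromosomes 1-12 (event types cycling Loss, Gain, Fusion); cluster ``c``
    carries events ``e`` with ``e mod 5 == c`` at penetrance 0.9 (disjoint
    signatures of 2-3 events); 0->1 noise rate 0.01; 40 iid Bernoulli(0.02)
    outlier features; seed 42.
    """
    etypes = ("Loss", "Gain", "Fusion")
    events = tuple(EventSpec(etype=etypes[e % 3], chromosome=str(e + 1), n_bands=8)
                   for e in range(12))
    K = 5
    signatures = tuple(
        tuple((e, 0.9) for e in range(12) if e % K == c) for c in range(K)
    )
    return SimSpec(n_samples=600, proportions=(0.2,) * 5, events=events,
                   signatures=signatures, noise_eps=0.01,
                   n_outlier_features=40, outlier_rate=0.02, seed=42)
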