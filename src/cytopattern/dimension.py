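"""Principal-component dimension estimation and outlier-feature removal.

The number of sample clusters in the pipeline is tied to the number of
significant principal components of the binary matrix. Two estimators are
provided:

* the broken-stick rule, which keeps component ``k`` while its variance
  proportion exceeds the expected length ``b_k = (1/d) * sum_{i=k..d} 1/i`` of
  the k-th longest fragment of a randomly broken unit stick;
* the Auer-Gervini Bayesian method, which places an exponential prior with
  rate ``theta`` on the dimension and reports the maximum-a-posteriori
  dimension as a step function of ``theta``. Candidate dimensions are the
  "long" steps - values of ``q`` that stay optimal over a wide range of prior
  rates.

The MAP dimension maximizes ``L(q) - theta * q`` where, with eigenvalues
``l_1 >= ... >= l_d`` of the column-mean-centered covariance and an isotropic
residual model,

    L(q) = -(n/2) * [ sum_{j<=q} ln l_j + (d-q) * ln( sum_{j>q} l_j / (d-q) ) ]

for ``q in {0..d-1}``. Because the penalty is linear in ``q``, the step
function is exactly the upper convex hull of the points ``(q, L(q))``:
breakpoints in ``theta`` are the slopes between consecutive hull vertices.

A Thresher-style filter removes outlier features whose loading vectors on the
retained components are short: feature ``j`` is dropped when
``|| (sqrt(l_1) v_j1, ..., sqrt(l_q) v_jq) || < delta`` (default 0.3),
computed on the feature-standardized matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ValidationError
from .io import BinaryMatrix, FeatureName

logger = logging.getLogger(__name__)

__all__ = [
    "EigenSpectrum", "Step", "StepFunction", "DimensionEstimate",
    "ThresherParams", "AuerGerviniDimension", "ThresherFilter",
    "eigen_spectrum", "broken_stick", "broken_stick_thresholds",
    "auer_gervini", "select_dimension", "thresher_filter",
]

#: eigenvalues below RANK_TOL * largest are treated as zero
RANK_TOL = 1e-12


@dataclass
class EigenSpectrum:
    """Eigenvalues of the (centered) covariance of a matrix, descending."""

    eigenvalues: np.ndarray
    n: int
    centering: str = "column-mean"

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=np.float64)
        ev = np.clip(ev, 0.0, None)
        if ev.size and ev[0] > 0:
            ev[ev < RANK_TOL * ev[0]] = 0.0
        if np.any(np.diff(ev) > 1e-9 * max(ev[0], 1.0) if ev.size else False):
            raise ValidationError("eigenvalues must be non-increasing")
        self.eigenvalues = ev

    @property
    def d(self) -> int:
        return self.eigenvalues.size

    @property
    def proportions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total


@dataclass(frozen=True)
class Step:
    """One step of the MAP-dimension function: q is optimal on (theta_lo, theta_hi]."""

    q: int
    theta_lo: float
    theta_hi: float

    @property
    def length(self) -> float:
        return self.theta_hi - self.theta_lo


@dataclass
class StepFunction:
    """MAP dimension q*(theta), non-increasing in theta; steps ordered by theta."""

    steps: list[Step]

    def q_at(self, theta: float) -> int:
        """MAP dimension at prior rate ``theta > 0`` (ties resolved upward)."""
        for st in self.steps:
            if st.theta_lo < theta <= st.theta_hi:
                return st.q
        return self.steps[-1].q if self.steps else 0

    def finite_steps(self) -> list[Step]:
        return [s for s in self.steps if s.q >= 1 and math.isfinite(s.theta_hi)]


@dataclass
class DimensionEstimate:
    broken_stick_q: int
    long_step_candidates: list[int]
    chosen_q: int
    criterion: str
    step_function: StepFunction | None = None


@dataclass
class ThresherParams:
    """Outlier-filter settings: loading-length cutoff and retained dimension."""

    delta: float = 0.3
    q: int | None = None  # None -> choose via the Auer-Gervini step function
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.delta < 1:
            raise ValidationError(f"delta must be in [0, 1), got {self.delta}")


# ---------------------------------------------------------------------------
# spectrum

def eigen_spectrum(m: BinaryMatrix | np.ndarray, standardize: bool = False) -> EigenSpectrum:
    """Eigenvalues of the column-mean-centered covariance (descending).

    ``standardize=True`` scales every column to unit variance first (i.e. the
    spectrum of the correlation matrix); zero-variance columns are left as
    zeros and contribute nothing.
    """
    X = m.values if isinstance(m, BinaryMatrix) else np.asarray(m)
    X = X.astype(np.float64)
    n, d = X.shape
    if n < 2 or d < 2:
        raise ValidationError("need at least 2 samples and 2 features")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        nz = sd > 0
        if not nz.all():
            logger.info("standardize: %d zero-variance columns left unscaled",
                        int((~nz).sum()))
        Xc[:, nz] = Xc[:, nz] / sd[nz]
        Xc[:, ~nz] = 0.0
    s = np.linalg.svd(Xc, compute_uv=False)
    ev = np.zeros(d)
    ev[: s.size] = (s ** 2) / (n - 1)
    if ev[0] <= 0:
        raise ValidationError("constant matrix: zero total variance")
    return EigenSpectrum(eigenvalues=ev, n=n)


# ---------------------------------------------------------------------------
# broken stick

def broken_stick_thresholds(d: int) -> np.ndarray:
    """Expected ordered fragment lengths b_k = (1/d) * sum_{i=k..d} 1/i."""
    inv = 1.0 / np.arange(1, d + 1)
    return np.cumsum(inv[::-1])[::-1] / d


def broken_stick(s: EigenSpectrum) -> int:
    """Largest q with l_k/sum(l) > b_k for all k <= q (0 if the first fails)."""
    props = s.proportions
    b = broken_stick_thresholds(s.d)
    above = props > b
    if not above[0]:
        return 0
    q = 0
    for ok in above:
        if not ok:
            break
        q += 1
    return q


# ---------------------------------------------------------------------------
# Auer-Gervini

def _profile_loglik(ev: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """L(q) for q = 0..q_max under the isotropic-residual profile likelihood."""
    d = ev.size
    pos = int(np.sum(ev > 0))
    q_max = min(d - 1, pos - 1)
    qs = np.arange(q_max + 1)
    L = np.empty(q_max + 1)
    log_head = 0.0
    for q in qs:
        if q > 0:
            log_head += math.log(ev[q - 1])
        tail = ev[q:].sum()
        L[q] = -(n / 2.0) * (log_head + (d - q) * math.log(tail / (d - q)))
    return qs, L


def _upper_hull(qs: np.ndarray, L: np.ndarray) -> list[tuple[int, float]]:
    """Upper convex hull of (q, L(q)), q ascending; collinear middles dropped."""
    hull: list[tuple[int, float]] = []
    for q, y in zip(qs, L):
        while len(hull) >= 2:
            (q1, y1), (q2, y2) = hull[-2], hull[-1]
            # pop hull[-1] unless it lies strictly above chord (q1,y1)-(q,y)
            if (y2 - y1) * (q - q1) <= (y - y1) * (q2 - q1):
                hull.pop()
            else:
                break
        hull.append((int(q), float(y)))
    return hull


def auer_gervini(s: EigenSpectrum) -> StepFunction:
    """MAP dimension as an exact step function of the exponential prior rate."""
    ev = s.eigenvalues
    if int(np.sum(ev > 0)) < 2:
        logger.warning("fewer than 2 positive eigenvalues; single step at q=1")
        return StepFunction(steps=[Step(q=1, theta_lo=0.0, theta_hi=math.inf)])
    qs, L = _profile_loglik(ev, s.n)
    hull = _upper_hull(qs, L)
    # vertices ascending in q; slopes between consecutive vertices descend
    slopes = [(hull[i][1] - hull[i - 1][1]) / (hull[i][0] - hull[i - 1][0])
              for i in range(1, len(hull))]
    steps: list[Step] = []
    m = len(hull) - 1
    for i in range(m, -1, -1):  # from largest q down to q = hull[0][0]
        lo = slopes[i] if i <= m - 1 else 0.0  # slope above vertex i
        lo = max(lo, 0.0)
        hi = slopes[i - 1] if i >= 1 else math.inf
        if hi <= lo:
            continue  # vertex never optimal at positive theta
        steps.append(Step(q=hull[i][0], theta_lo=lo, theta_hi=hi))
    return StepFunction(steps=steps)


def select_dimension(sf: StepFunction, s: EigenSpectrum | None = None,
                     criterion: str = "twice-mean",
                     manual_q: int | None = None) -> DimensionEstimate:
    """Pick the component count from the step function.

    ``twice-mean`` flags steps (q >= 1, finite) longer than twice the mean step
    length as candidates and picks the candidate with the longest step (ties go
    to the larger q); with no candidate it falls back to the longest step.
    """
    bs_q = broken_stick(s) if s is not None else 0
    finite = sf.finite_steps()
    lengths = np.array([st.length for st in finite])
    candidates: list[int] = []
    if lengths.size:
        mean_len = lengths.mean()
        candidates = [st.q for st in finite if st.length > 2.0 * mean_len]

    def _longest(steps: list[Step]) -> int:
        best = max(steps, key=lambda st: (st.length, st.q))
        return best.q

    if manual_q is not None:
        d = s.d if s is not None else max((st.q for st in sf.steps), default=1) + 1
        if not 1 <= manual_q <= d - 1:
            raise ValidationError(f"manual_q={manual_q} outside 1..{d - 1}")
        return DimensionEstimate(bs_q, candidates, manual_q, "manual", sf)
    if criterion == "broken-stick":
        if s is None:
            raise ValidationError("broken-stick criterion needs the spectrum")
        return DimensionEstimate(bs_q, candidates, max(1, bs_q), "broken-stick", sf)
    if criterion == "longest-step":
        if not finite:
            return DimensionEstimate(bs_q, candidates, 1, "longest-step", sf)
        return DimensionEstimate(bs_q, candidates, _longest(finite), "longest-step", sf)
    if criterion == "twice-mean":
        if candidates:
            cand_steps = [st for st in finite if st.q in candidates]
            return DimensionEstimate(bs_q, candidates, _longest(cand_steps),
                                     "twice-mean", sf)
        chosen = _longest(finite) if finite else 1
        return DimensionEstimate(bs_q, candidates, chosen, "longest-step", sf)
    raise ValidationError(f"unknown criterion {criterion!r}")


class AuerGerviniDimension(BaseEstimator):
    """Estimator wrapper: fit() computes the spectrum, step function and q.

    Parameters
    ----------
    criterion : {"twice-mean", "longest-step", "broken-stick"}
    manual_q : int or None
        Pin the dimension (criterion recorded as "manual").
    standardize : bool
        Work on the correlation (feature-standardized) spectrum.
    """

    def __init__(self, criterion: str = "twice-mean", manual_q: int | None = None,
                 standardize: bool = False):
        self.criterion = criterion
        self.manual_q = manual_q
        self.standardize = standardize

    def fit(self, X, y=None):
        spectrum = eigen_spectrum(X, standardize=self.standardize)
        sf = auer_gervini(spectrum)
        est = select_dimension(sf, spectrum, criterion=self.criterion,
                               manual_q=self.manual_q)
        self.eigenvalues_ = spectrum.eigenvalues
        self.spectrum_ = spectrum
        self.step_function_ = sf
        self.broken_stick_q_ = est.broken_stick_q
        self.candidates_ = est.long_step_candidates
        self.n_components_ = est.chosen_q
        self.estimate_ = est
        return self


# ---------------------------------------------------------------------------
# Thresher outlier filter

class ThresherFilter(BaseEstimator, TransformerMixin):
    """Drop features whose loading vectors on the top-q components are short.

    Fitted attributes: ``lengths_`` (per-feature loading length), ``support_``
    (boolean keep mask), ``n_components_`` (q actually used).
    """

    def __init__(self, delta: float = 0.3, n_components: int | None = None,
                 standardize: bool = True):
        self.delta = delta
        self.n_components = n_components
        self.standardize = standardize

    def fit(self, X, y=None):
        params = ThresherParams(delta=self.delta, q=self.n_components,
                                standardize=self.standardize)
        X = np.asarray(X, dtype=np.float64)
        n, d = X.shape
        Xc = X - X.mean(axis=0)
        if params.standardize:
            sd = X.std(axis=0, ddof=1)
            nz = sd > 0
            Xc[:, nz] = Xc[:, nz] / sd[nz]
            Xc[:, ~nz] = 0.0
        U, sing, Vt = np.linalg.svd(Xc, full_matrices=False)
        ev = (sing ** 2) / (n - 1)
        full = np.zeros(d)
        full[: ev.size] = ev
        spectrum = EigenSpectrum(eigenvalues=full, n=n)
        q = params.q
        if q is None:
            q = select_dimension(auer_gervini(spectrum), spectrum).chosen_q
        q = min(q, int(np.sum(spectrum.eigenvalues > 0)))
        # loading length of feature j: ||(sqrt(l_k) * v_jk)_{k<=q}||
        scaled = Vt[:q, :] * np.sqrt(ev[:q, None])
        self.lengths_ = np.sqrt((scaled ** 2).sum(axis=0))
        self.support_ = self.lengths_ >= params.delta
        self.n_components_ = int(q)
        if not self.support_.any():
            raise ValidationError(
                f"all features dropped at delta={params.delta}; lower delta")
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        return self.support_


def thresher_filter(m: BinaryMatrix, params: ThresherParams | None = None
                    ) -> tuple[list[FeatureName], list[FeatureName], np.ndarray]:
    """Split features into (kept, dropped) by loading length; returns lengths too."""
    params = params or ThresherParams()
    filt = ThresherFilter(delta=params.delta, n_components=params.q,
                          standardize=params.standardize).fit(m.values)
    kept = [f for f, ok in zip(m.features, filt.support_) if ok]
    dropped = [f for f, ok in zip(m.features, filt.support_) if not ok]
    if dropped:
        logger.info("thresher: dropped %d outlier features (q=%d, delta=%.3g)",
                    len(dropped), filt.n_components_, params.delta)
    return kept, dropped, filt.lengths_
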