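"""Visual structures over a distance matrix.

Four complementary views of the same distance matrix are supported, all keyed
to a shared cluster color palette so that the same biological cluster keeps
the same color across methods:

* density-dependent down-sampling (SPADE-style): objects in dense regions are
  kept with probability inversely proportional to their local density, so rare
  clusters remain visible in sub-sampled graphs;
* a thresholded adjacency graph (edge iff distance < tau, default 0.6 on the
  Jaccard scale, i.e. similarity > 0.4);
* classical (Torgerson) multidimensional scaling coordinates;
* a Ward-linkage dendrogram (Ward.D2 dialect; a heuristic view for
  non-Euclidean binary distances).

An optional t-SNE embedding is exposed as a pluggable backend with a fixed
seed; its internals are delegated to scikit-learn.
"""

from __future__ import annotations

import colorsys
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .cluster import AlignmentMap, Partition
from .distance import DistanceMatrix
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DownsampleResult", "DensityDownsampler", "density_downsample",
    "adjacency", "ClassicalMDS", "classical_mds", "hclust_ward",
    "make_palette", "recolor", "tsne_embedding", "BASE_PALETTE",
]


# ---------------------------------------------------------------------------
# density-dependent down-sampling

@dataclass
class DownsampleResult:
    kept: list[str]
    densities: np.ndarray
    radius: float
    target: int
    seed: int


class DensityDownsampler(BaseEstimator):
    """Keep object i with probability min(1, TD / LD_i).

    ``LD_i`` is the local density (neighbor count within ``radius``, the
    object itself included); the target density ``TD`` is calibrated by
    bisection so the *expected* kept count equals ``target``.
    ``radius="auto"`` uses the 5th percentile of off-diagonal distances.
    """

    def __init__(self, target: int = 1000, radius: float | str = "auto",
                 random_state: int = 0):
        self.target = target
        self.radius = radius
        self.random_state = random_state

    def fit(self, X, y=None):
        D = np.asarray(X, dtype=np.float64)
        n = D.shape[0]
        if not 1 <= self.target <= n:
            raise ValidationError(f"target={self.target} outside 1..{n}")
        if self.radius == "auto":
            off = D[~np.eye(n, dtype=bool)]
            radius = float(np.percentile(off, 5))
            if radius <= 0:
                radius = float(np.min(off[off > 0], initial=1.0))
        else:
            radius = float(self.radius)
            if radius <= 0:
                raise ValidationError(f"radius must be positive, got {radius}")
        dens = (D < radius).sum(axis=1).astype(np.float64)  # counts self
        dens = np.maximum(dens, 1.0)

        def expected(td: float) -> float:
            return float(np.minimum(1.0, td / dens).sum())

        lo, hi = 0.0, float(dens.max())
        if expected(hi) <= self.target:
            td = hi
        else:
            for _ in range(100):
                mid = (lo + hi) / 2.0
                if expected(mid) < self.target:
                    lo = mid
                else:
                    hi = mid
            td = (lo + hi) / 2.0
        rng = np.random.default_rng(self.random_state)
        keep_prob = np.minimum(1.0, td / dens)
        mask = rng.random(n) < keep_prob
        self.densities_ = dens
        self.radius_ = radius
        self.target_density_ = td
        self.keep_probability_ = keep_prob
        self.support_ = mask
        self.kept_indices_ = np.flatnonzero(mask)
        return self


def density_downsample(dm: DistanceMatrix, target: int,
                       radius: float | str = "auto", seed: int = 0) -> DownsampleResult:
    """SPADE-inspired down-sampling of a distance matrix to ~``target`` objects."""
    ds = DensityDownsampler(target=target, radius=radius, random_state=seed)
    ds.fit(dm.values)
    return DownsampleResult(kept=[dm.ids[i] for i in ds.kept_indices_],
                            densities=ds.densities_, radius=ds.radius_,
                            target=target, seed=seed)


# ---------------------------------------------------------------------------
# adjacency graph

def adjacency(dm: DistanceMatrix, tau: float = 0.6,
              partition: Partition | None = None,
              palette: dict[int, str] | None = None) -> nx.Graph:
    """Undirected graph with an edge (i, j) iff d(i, j) < tau.

    Node attributes carry cluster labels (and palette colors) when a partition
    is supplied; edges carry the distance as attribute ``distance``.
    """
    if tau <= 0 and tau != 0:
        raise ValidationError("tau must be non-negative")
    g = nx.Graph(tau=tau, metric=dm.metric)
    for i, obj in enumerate(dm.ids):
        attrs = {}
        if partition is not None:
            c = partition.labels[obj]
            attrs["cluster"] = c
            if palette is not None:
                attrs["color"] = palette.get(c, "#000000")
        g.add_node(obj, **attrs)
    rows, cols = np.nonzero(np.triu(dm.values < tau, k=1))
    for i, j in zip(rows, cols):
        g.add_edge(dm.ids[i], dm.ids[j], distance=float(dm.values[i, j]))
    return g


def write_edgelist(g: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tdistance\n")
        for u, v, d in g.edges(data="distance"):
            fh.write(f"{u}\t{v}\t{d}\n")
    return path


# ---------------------------------------------------------------------------
# classical MDS

class ClassicalMDS(BaseEstimator):
    """Torgerson double-centering MDS on a precomputed distance matrix.

    ``fit_transform(D)`` returns n x k coordinates from the top-k eigenpairs of
    ``-0.5 * J D^2 J``; negative eigenvalues are clipped at zero and missing
    positive directions are zero-padded with a warning. Column signs are fixed
    (largest-magnitude entry positive) so results are reproducible.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit_transform(self, X, y=None):
        D = np.asarray(X, dtype=np.float64)
        n = D.shape[0]
        k = self.n_components
        if k < 1:
            raise ValidationError("n_components must be >= 1")
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        w = np.clip(w[order], 0.0, None)
        V = V[:, order]
        npos = int(np.sum(w > 1e-12 * max(w[0], 1.0)))
        if k > npos:
            warnings.warn(f"only {npos} positive eigenvalues; padding "
                          f"{k - npos} coordinate columns with zeros")
        coords = np.zeros((n, k))
        kk = min(k, npos)
        coords[:, :kk] = V[:, :kk] * np.sqrt(w[:kk])
        for j in range(kk):  # deterministic sign convention
            i = int(np.argmax(np.abs(coords[:, j])))
            if coords[i, j] < 0:
                coords[:, j] = -coords[:, j]
        self.eigenvalues_ = w
        self.embedding_ = coords
        return coords

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def classical_mds(dm: DistanceMatrix, k: int = 2) -> np.ndarray:
    """n x k classical MDS coordinates for a distance matrix."""
    return ClassicalMDS(n_components=k).fit_transform(dm.values)


# ---------------------------------------------------------------------------
# Ward dendrogram

def hclust_ward(dm: DistanceMatrix) -> np.ndarray:
    """Ward.D2 agglomerative merge tree (scipy linkage matrix format)."""
    if dm.n < 2:
        raise ValidationError("need at least 2 objects")
    condensed = squareform(dm.values, checks=False)
    return linkage(condensed, method="ward")


# ---------------------------------------------------------------------------
# shared palette

#: 18 visually distinct base colors (cycled with shade variation beyond 18)
BASE_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
    "#98df8a", "#ff9896", "#c5b0d5", "#c49c94", "#f7b6d2", "#dbdb8d",
]


def _shade(hex_color: str, cycle: int) -> str:
    if cycle == 0:
        return hex_color
    r, g, b = (int(hex_color[i:i + 2], 16) / 255 for i in (1, 3, 5))
    h, l, s = colorsys.rgb_to_hls(r, g, b)
    if cycle % 2 == 1:  # darken on odd cycles, lighten on even
        l = l * (0.65 ** ((cycle + 1) // 2))
    else:
        l = 1 - (1 - l) * (0.65 ** (cycle // 2))
    r, g, b = colorsys.hls_to_rgb(h, min(max(l, 0.05), 0.95), s)
    return "#{:02x}{:02x}{:02x}".format(int(r * 255), int(g * 255), int(b * 255))


def _palette_color(i: int, base: list[str]) -> str:
    return _shade(base[i % len(base)], i // len(base))


def make_palette(ref: Partition, base: list[str] | None = None) -> dict[int, str]:
    """Color per cluster id: descending cluster size, fixed cyclic base palette."""
    base = base or BASE_PALETTE
    sizes = ref.cluster_sizes()
    order = sorted(sizes, key=lambda c: (-sizes[c], c))
    return {c: _palette_color(i, base) for i, c in enumerate(order)}


def recolor(other: Partition, pal: dict[int, str], amap: AlignmentMap,
            base: list[str] | None = None) -> dict[int, str]:
    """Route reference colors through an alignment map; fresh colors otherwise."""
    base = base or BASE_PALETTE
    out: dict[int, str] = {}
    next_i = len(pal)
    sizes = other.cluster_sizes()
    for c in sorted(sizes, key=lambda c: (-sizes[c], c)):
        ref_c = amap.mapping.get(c)
        if ref_c is not None and ref_c in pal and c in amap.matched:
            out[c] = pal[ref_c]
        else:
            out[c] = _palette_color(next_i, base)
            next_i += 1
    return out


# ---------------------------------------------------------------------------
# pluggable t-SNE backend

def tsne_embedding(dm: DistanceMatrix, seed: int = 0,
                   perplexity: float = 30.0) -> np.ndarray:
    """n x 2 t-SNE coordinates (scikit-learn backend, fixed seed)."""
    from sklearn.manifold import TSNE

    perplexity = min(perplexity, max(1.0, (dm.n - 1) / 3.0))
    ts = TSNE(n_components=2, metric="precomputed", init="random",
              random_state=seed, perplexity=perplexity)
    return ts.fit_transform(dm.values)
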