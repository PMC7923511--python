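"""End-to-end pipeline: read -> reduce -> filter -> distances -> dimension ->
PAM -> characterize -> views, with a manifest of every parameter and seed."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characterize import (cluster_features, coverage_summary, disease_prevalence,
                           event_frequency, event_signature, heatmap_order,
                           report_to_markdown, top_events)
from .cluster import pam, silhouette
from .dimension import (ThresherParams, auer_gervini, eigen_spectrum,
                        select_dimension, thresher_filter)
from .distance import METRICS, _normalize_metric, distance_matrix
from .exceptions import ValidationError
from .graph_view import (adjacency, classical_mds, density_downsample,
                         hclust_ward, make_palette, write_edgelist)
from .io import BinaryMatrix, attach_labels, read_labels, read_matrix
from .reduce import collapse_duplicates, drop_empty

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "compare_metrics"]


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults follow the standard analysis settings
    (Jaccard metric, edge threshold tau=0.6, report cutoff 0.60, delta=0.3)."""

    input: str | None = None
    input_format: str = "dense-tsv"
    labels: str | None = None
    metric: str = "jaccard"
    dimension_criterion: str = "twice-mean"
    manual_q: int | None = None
    delta: float = 0.3
    tau: float = 0.6
    cutoff: float = 0.60
    feature_q: int | None = None
    downsample_target: int | None = None
    seed: int = 0
    outdir: str | None = None
    transpose: bool = False
    make_plots: bool = False

    def validate(self) -> None:
        _normalize_metric(self.metric)  # raises on unknown metric
        if not 0 < self.cutoff <= 1:
            raise ValidationError(f"cutoff {self.cutoff} outside (0, 1]")
        if self.input is not None and not Path(self.input).exists():
            raise ValidationError(f"input file {self.input} does not exist")
        if self.labels is not None and not Path(self.labels).exists():
            raise ValidationError(f"labels file {self.labels} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    matrix: BinaryMatrix
    reduced: BinaryMatrix
    dedup_map: Any
    sample_partition: Any
    feature_partition: Any
    groups: list
    frequency: Any
    coverage: dict
    report: Any
    prevalence: dict
    dimension: Any
    manifest: dict = field(default_factory=dict)
    mds_coords: np.ndarray | None = None
    graph: Any = None
    linkage: np.ndarray | None = None


def _checksum(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, matrix: BinaryMatrix | None = None) -> PipelineResult:
    """Run every stage in order; artifacts land under ``cfg.outdir`` if set."""
    cfg.validate()
    if matrix is None:
        if cfg.input is None:
            raise ValidationError("no input matrix (config.input or matrix=)")
        matrix = read_matrix(cfg.input, format=cfg.input_format,
                             transpose=cfg.transpose)
        if cfg.labels:
            matrix = attach_labels(matrix, read_labels(cfg.labels))
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "input_checksum": _checksum(matrix.values),
        "counts": {"n_samples": matrix.n, "d_raw": matrix.d},
    }

    # 1-2. reduction
    m1 = drop_empty(matrix)
    reduced, dmap = collapse_duplicates(m1)
    manifest["counts"]["d_nonempty"] = m1.d
    manifest["counts"]["d_unique"] = reduced.d

    # 3. outlier-feature removal
    kept, dropped, lengths = thresher_filter(
        reduced, ThresherParams(delta=cfg.delta))
    keep_idx = [j for j, f in enumerate(reduced.features)
                if f.raw in {k.raw for k in kept}]
    informative = reduced.select_features(keep_idx)
    dmap.groups = {r: g for r, g in dmap.groups.items()
                   if r in set(informative.raw_names)}
    manifest["counts"]["d_informative"] = informative.d

    # 4. sample distances + dimension
    dm = distance_matrix(informative, metric=cfg.metric, axis="samples")
    spectrum = eigen_spectrum(informative)
    sf = auer_gervini(spectrum)
    dim = select_dimension(sf, spectrum, criterion=cfg.dimension_criterion,
                           manual_q=cfg.manual_q)
    K = dim.chosen_q
    manifest["counts"]["chosen_q"] = K
    manifest["counts"]["broken_stick_q"] = dim.broken_stick_q
    manifest["counts"]["long_step_candidates"] = dim.long_step_candidates

    # 5. sample clustering
    sp = pam(dm, K)
    manifest["counts"]["K"] = K
    manifest["counts"]["cluster_sizes"] = sp.cluster_sizes()
    if K >= 2:
        _, mean_sil = silhouette(dm, sp)
        manifest["counts"]["mean_silhouette"] = round(mean_sil, 6)

    # 6. characterization
    fp, feature_K = cluster_features(informative, metric=cfg.metric,
                                     q=cfg.feature_q)
    groups = event_signature(fp, dmap, informative.features)
    ft = event_frequency(informative, sp, groups, dmap)
    coverage = coverage_summary(ft)
    report = top_events(ft, cutoff=cfg.cutoff, labels=matrix.labels, sp=sp)
    prevalence = disease_prevalence(sp, matrix.labels or {})
    manifest["counts"]["feature_K"] = feature_K
    manifest["counts"]["clusters_characterized"] = sum(
        r.characterized for r in report.rows)

    # 7. views
    pal = make_palette(sp)
    view_dm = dm
    if cfg.downsample_target is not None and cfg.downsample_target < dm.n:
        ds = density_downsample(dm, cfg.downsample_target, seed=cfg.seed)
        keep = [dm.ids.index(i) for i in ds.kept]
        view_dm = dm.subset(keep)
        manifest["counts"]["downsampled_to"] = len(ds.kept)
    g = adjacency(view_dm, tau=cfg.tau, partition=sp, palette=pal)
    manifest["counts"]["edges_at_tau"] = g.number_of_edges()
    coords = classical_mds(dm, k=2)
    Z = hclust_ward(view_dm)

    result = PipelineResult(matrix=matrix, reduced=informative, dedup_map=dmap,
                            sample_partition=sp, feature_partition=fp,
                            groups=groups, frequency=ft, coverage=coverage,
                            report=report, prevalence=prevalence, dimension=dim,
                            manifest=manifest, mds_coords=coords, graph=g,
                            linkage=Z)
    if outdir:
        _write_artifacts(result, outdir, cfg)
    return result


def _write_artifacts(res: PipelineResult, outdir: Path, cfg: PipelineConfig) -> None:
    from .io import write_matrix

    write_matrix(res.reduced, outdir / "reduced_matrix.tsv")
    res.dedup_map.to_tsv(outdir / "dedup_map.tsv")
    res.sample_partition.to_tsv(outdir / "sample_partition.tsv")
    res.feature_partition.to_tsv(outdir / "feature_partition.tsv")
    ftab = pd.DataFrame(res.frequency.values,
                        index=[f"SC{c}" for c in res.frequency.cluster_ids],
                        columns=[f"G{g}" for g in res.frequency.group_ids])
    ftab.to_csv(outdir / "frequency_table.tsv", sep="\t")
    with open(outdir / "coverage.json", "w") as fh:
        json.dump({str(k): v for k, v in res.coverage.items()}, fh, indent=2)
    with open(outdir / "report.md", "w") as fh:
        fh.write(report_to_markdown(res.report))
    pd.DataFrame(res.mds_coords, index=res.matrix.sample_ids,
                 columns=["MDS1", "MDS2"]).to_csv(outdir / "mds.tsv", sep="\t")
    write_edgelist(res.graph, outdir / "graph_edges.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, default=str)
    if cfg.make_plots:
        _make_plots(res, outdir)


def _make_plots(res: PipelineResult, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    pal = make_palette(res.sample_partition)
    colors = [pal[res.sample_partition.labels[s]] for s in res.matrix.sample_ids]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(res.mds_coords[:, 0], res.mds_coords[:, 1], c=colors, s=8)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.savefig(outdir / "mds.png", dpi=120)
    plt.close(fig)
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(res.linkage, ax=ax, no_labels=True)
    fig.savefig(outdir / "dendrogram.png", dpi=120)
    plt.close(fig)


def compare_metrics(cfg: PipelineConfig, metrics: list[str],
                    matrix: BinaryMatrix | None = None,
                    truth_labels: dict[str, int] | None = None) -> pd.DataFrame:
    """Side-by-side summary of the pipeline under several distance metrics."""
    if len(metrics) < 2:
        raise ValidationError("compare_metrics needs at least 2 metrics")
    from sklearn.metrics import adjusted_rand_score

    rows = []
    for metric in metrics:
        sub = PipelineConfig(**{**asdict(cfg), "metric": metric, "outdir": None})
        res = run_pipeline(sub, matrix=matrix)
        row: dict[str, Any] = {
            "metric": _normalize_metric(metric),
            "chosen_q": res.dimension.chosen_q,
            "K": res.sample_partition.K,
            "mean_silhouette": res.manifest["counts"].get("mean_silhouette"),
            "edges_at_tau": res.manifest["counts"]["edges_at_tau"],
        }
        if truth_labels is not None:
            ids = res.matrix.sample_ids
            row["ari_vs_truth"] = adjusted_rand_score(
                [truth_labels[s] for s in ids],
                [res.sample_partition.labels[s] for s in ids])
        rows.append(row)
    return pd.DataFrame(rows)
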