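"""Reading, validating and writing binary loss/gain/fusion (LGF) matrices.

The central container is :class:`BinaryMatrix`: a samples x features 0/1
matrix whose columns are cytoband-level events. Each column header encodes a
cytogenetic band and an event type. The canonical header dialect is
``"<band>.<L|G|F>"`` (e.g. ``"8q24.F"`` for a fusion at band 8q24); any other
upstream naming scheme can be accommodated with a user-supplied regex that
exposes named groups ``band`` and ``type``.

Two on-disk dialects are supported:

* dense TSV/CSV with a header row and one row per sample;
* sparse triplet TSV ``(sample_id, feature, value)`` carrying an explicit
  sample and feature manifest in ``#`` comment lines, so that all-zero
  karyotypes (cytogenetically normal samples) survive round trips.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

EVENT_TYPES = ("Loss", "Gain", "Fusion")
_TYPE_CODES = {"L": "Loss", "G": "Gain", "F": "Fusion",
               "Loss": "Loss", "Gain": "Gain", "Fusion": "Fusion"}

#: canonical "<band>.<L|G|F>" header dialect; band = chromosome + arm + digits
DEFAULT_FEATURE_PATTERN = re.compile(
    r"^(?:chr)?(?P<band>(?P<chrom>[0-9]{1,2}|X|Y)"
    r"(?:[pq](?:[0-9]+(?:\.[0-9]+)?)?)?)\.(?P<type>[LGF])$"
)

_CHROM_RE = re.compile(r"^(?:chr)?([0-9]{1,2}|X|Y)")

VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])


@dataclass(frozen=True)
class FeatureName:
    """A parsed LGF column header: cytoband + event type + original string."""

    band: str
    etype: str  # one of EVENT_TYPES, or "Unknown" in lenient mode
    raw: str

    @property
    def chromosome(self) -> str:
        """Chromosome token of the band (e.g. ``"8"`` for band ``"8q24"``)."""
        m = _CHROM_RE.match(self.band)
        return m.group(1) if m else self.band

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.raw


def parse_feature_name(raw: str, pattern: re.Pattern | str | None = None,
                       strict: bool = True) -> FeatureName:
    """Parse a column header into a :class:`FeatureName`.

    Parameters
    ----------
    raw:
        The original header string, e.g. ``"13q14.L"``.
    pattern:
        Optional regex (string or compiled) with named groups ``band`` and
        ``type`` overriding the canonical dialect.
    strict:
        If True, any header outside the dialect raises :class:`FormatError`;
        if False, unparseable headers pass through with ``etype="Unknown"``
        and a logged warning.
    """
    pat = DEFAULT_FEATURE_PATTERN if pattern is None else (
        re.compile(pattern) if isinstance(pattern, str) else pattern)
    m = pat.match(raw)
    if m is None:
        if strict:
            raise FormatError(f"feature name {raw!r} does not match the "
                              f"'<band>.<L|G|F>' dialect")
        logger.warning("feature name %r unparseable; etype set to Unknown", raw)
        return FeatureName(band=raw, etype="Unknown", raw=raw)
    band = m.group("band")
    code = m.group("type")
    etype = _TYPE_CODES.get(code) or _TYPE_CODES.get(code.capitalize())
    if etype is None:
        if strict:
            raise FormatError(f"feature name {raw!r}: unknown event type {code!r}")
        logger.warning("feature name %r: unknown event type %r", raw, code)
        etype = "Unknown"
    cm = _CHROM_RE.match(band)
    chrom = cm.group(1) if cm else None
    if chrom not in VALID_CHROMOSOMES:
        if strict:
            raise FormatError(f"feature name {raw!r}: invalid chromosome {chrom!r}")
        logger.warning("feature name %r: invalid chromosome %r", raw, chrom)
    return FeatureName(band=band, etype=etype, raw=raw)


@dataclass
class BinaryMatrix:
    """A validated samples x features 0/1 matrix with optional disease labels."""

    sample_ids: list[str]
    features: list[FeatureName]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValidationError("matrix must have at least one sample and one feature")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.features) != d:
            raise ValidationError(f"{len(self.features)} feature names for {d} columns")
        if len(set(self.sample_ids)) != n:
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id {dup!r}")
        raws = [f.raw for f in self.features]
        if len(set(raws)) != d:
            dup = _first_duplicate(raws)
            raise ValidationError(f"duplicate feature header {dup!r}")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-binary cell {self.values[i, j]!r} at sample "
                f"{self.sample_ids[i]!r}, feature {raws[j]!r}")
        self.values = self.values.astype(np.int8, copy=False)

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def raw_names(self) -> list[str]:
        return [f.raw for f in self.features]

    def select_features(self, index: Sequence[int]) -> "BinaryMatrix":
        """A new matrix keeping the feature columns in ``index`` (in order)."""
        index = list(index)
        return BinaryMatrix(
            sample_ids=list(self.sample_ids),
            features=[self.features[j] for j in index],
            values=self.values[:, index].copy(),
            labels=dict(self.labels) if self.labels else None,
        )

    def select_samples(self, index: Sequence[int]) -> "BinaryMatrix":
        index = list(index)
        ids = [self.sample_ids[i] for i in index]
        labels = ({s: self.labels[s] for s in ids if s in self.labels}
                  if self.labels else None)
        return BinaryMatrix(sample_ids=ids,
                            features=list(self.features),
                            values=self.values[index, :].copy(),
                            labels=labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.raw_names == other.raw_names
                and np.array_equal(self.values, other.values)
                and (self.labels or {}) == (other.labels or {}))


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


FORMATS = ("dense-tsv", "sparse-triplet")


def read_matrix(path: str | Path, format: str = "dense-tsv", *,
                sep: str = "\t", strict_names: bool = False,
                pattern: re.Pattern | str | None = None,
                transpose: bool = False) -> BinaryMatrix:
    """Read a :class:`BinaryMatrix` from disk.

    ``strict_names=False`` keeps headers that fall outside the feature-name
    dialect (flagged ``etype="Unknown"``); pass True to reject them.
    """
    path = Path(path)
    if format == "dense-tsv":
        df = pd.read_csv(path, sep=sep, dtype=str, index_col=0)
        if transpose:
            df = df.T
        sample_ids = [str(s) for s in df.index]
        raw_names = [str(c) for c in df.columns]
        values = _coerce_binary(df, sample_ids, raw_names)
    elif format == "sparse-triplet":
        sample_ids, raw_names, values = _read_sparse(path)
        if transpose:
            sample_ids, raw_names = raw_names, sample_ids
            values = values.T
    else:
        raise FormatError(f"unknown format {format!r}; valid: {FORMATS}")
    features = [parse_feature_name(r, pattern=pattern, strict=strict_names)
                for r in raw_names]
    return BinaryMatrix(sample_ids=sample_ids, features=features, values=values)


def _coerce_binary(df: pd.DataFrame, sample_ids: list[str],
                   raw_names: list[str]) -> np.ndarray:
    values = np.empty(df.shape, dtype=np.int8)
    arr = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(arr[i, j]).strip()
            if cell not in ("0", "1"):
                raise ValidationError(
                    f"non-binary cell {cell!r} at sample {sample_ids[i]!r}, "
                    f"column {raw_names[j]!r}")
            values[i, j] = int(cell)
    return values


def _read_sparse(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    sample_ids: list[str] = []
    raw_names: list[str] = []
    triplets: list[tuple[str, str, str]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#sample\t"):
                sample_ids.append(line.split("\t", 1)[1])
                continue
            if line.startswith("#feature\t"):
                raw_names.append(line.split("\t", 1)[1])
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:3] == ["sample", "feature", "value"]:
                header_seen = True
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            triplets.append((parts[0], parts[1], parts[2]))
    if not header_seen and not sample_ids:
        raise FormatError(f"{path}: missing sparse-triplet manifest/header")
    if not sample_ids or not raw_names:
        raise FormatError(f"{path}: sparse-triplet file lacks a #sample/#feature manifest")
    sidx = {s: i for i, s in enumerate(sample_ids)}
    fidx = {f: j for j, f in enumerate(raw_names)}
    values = np.zeros((len(sample_ids), len(raw_names)), dtype=np.int8)
    for s, f, v in triplets:
        if s not in sidx:
            raise ValidationError(f"sample {s!r} not in manifest")
        if f not in fidx:
            raise ValidationError(f"feature {f!r} not in manifest")
        if v not in ("0", "1"):
            raise ValidationError(f"non-binary cell {v!r} at sample {s!r}, column {f!r}")
        values[sidx[s], fidx[f]] = int(v)
    return sample_ids, raw_names, values


def write_matrix(m: BinaryMatrix, path: str | Path,
                 format: str = "dense-tsv", *, sep: str = "\t") -> Path:
    """Write ``m`` so that :func:`read_matrix` round-trips bit-exactly."""
    path = Path(path)
    if format == "dense-tsv":
        df = pd.DataFrame(m.values, index=m.sample_ids, columns=m.raw_names)
        df.to_csv(path, sep=sep, index_label="sample")
    elif format == "sparse-triplet":
        with open(path, "w") as fh:
            for s in m.sample_ids:
                fh.write(f"#sample\t{s}\n")
            for r in m.raw_names:
                fh.write(f"#feature\t{r}\n")
            fh.write("sample\tfeature\tvalue\n")
            rows, cols = np.nonzero(m.values)
            for i, j in zip(rows, cols):
                fh.write(f"{m.sample_ids[i]}\t{m.raw_names[j]}\t1\n")
    else:
        raise FormatError(f"unknown format {format!r}; valid: {FORMATS}")
    return path


def read_labels(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a two-column (sample_id, disease) table."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: labels table needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: Mapping[str, str], path: str | Path,
                 sep: str = "\t") -> Path:
    path = Path(path)
    df = pd.DataFrame({"sample_id": list(labels.keys()),
                       "disease": list(labels.values())})
    df.to_csv(path, sep=sep, index=False)
    return path


def attach_labels(m: BinaryMatrix, labels: Mapping[str, str]) -> BinaryMatrix:
    return replace(m, labels=dict(labels))
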