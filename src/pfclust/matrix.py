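"""Connectivity-matrix data model, ordinal strength encoding, and I/O.

The analysis substrate is a rectangular source-by-target table of
cortico-cortical input strengths on a semi-quantitative ordinal scale:
strong (100), medium (67), moderate (33), weak (16), absent (0).
Columns are injected (target) areas, rows are labelled source areas; rows
may include sources (e.g. temporal or insular areas) that were never
injected and therefore do not appear among the columns.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "STRENGTH_WORDS",
    "CANONICAL_LEVELS",
    "encode_strength",
    "Area",
    "AreaRegistry",
    "load_registry",
    "ConnectivityMatrix",
    "load_matrix",
    "write_matrix",
    "DistanceMatrix",
    "subset_targets",
    "column_distances",
]

#: Ordinal code for each strength word.
STRENGTH_WORDS = {
    "strong": 100,
    "medium": 67,
    "moderate": 33,
    "weak": 16,
    "absent": 0,
}

#: The canonical ordinal vocabulary.
CANONICAL_LEVELS = (0, 16, 33, 67, 100)


class MatrixError(ValueError):
    """Raised for malformed matrices, registries or lookups."""


def encode_strength(label: str) -> int:
    """Map a strength word to its ordinal code.

    Parameters
    ----------
    label:
        One of ``strong``, ``medium``, ``moderate``, ``weak``, ``absent``
        (case-insensitive, surrounding whitespace ignored).

    Returns
    -------
    int
        100, 67, 33, 16 or 0 respectively.
    """
    key = str(label).strip().lower()
    try:
        return STRENGTH_WORDS[key]
    except KeyError:
        raise MatrixError(
            f"unknown strength word {label!r}; expected one of "
            f"{sorted(STRENGTH_WORDS)}"
        ) from None


class Lobe(str, Enum):
    parietal = "parietal"
    frontal = "frontal"


@dataclass(frozen=True)
class Area:
    """A cortical area: the leaf unit of every tree in the analysis."""

    id: str
    name: str
    lobe: str
    subdivision: str
    reference_cluster: str | None = None


class AreaRegistry:
    """Parcellation registry: unique area ids with lobe/subdivision labels."""

    def __init__(self, areas: Iterable[Area]):
        self.areas: list[Area] = list(areas)
        self._by_id = {a.id: a for a in self.areas}
        if len(self._by_id) != len(self.areas):
            seen: set[str] = set()
            dup = [a.id for a in self.areas if a.id in seen or seen.add(a.id)]
            raise MatrixError(f"duplicate area ids in registry: {dup}")

    def __len__(self) -> int:
        return len(self.areas)

    def __contains__(self, area_id: str) -> bool:
        return area_id in self._by_id

    def __getitem__(self, area_id: str) -> Area:
        try:
            return self._by_id[area_id]
        except KeyError:
            raise MatrixError(f"area {area_id!r} not in registry") from None

    def ids(self, lobe: str | None = None, subdivision: str | None = None) -> list[str]:
        out = []
        for a in self.areas:
            if lobe is not None and a.lobe != lobe:
                continue
            if subdivision is not None and a.subdivision != subdivision:
                continue
            out.append(a.id)
        return out

    def reference_assignment(self, ids: Sequence[str] | None = None) -> dict[str, str]:
        """Area -> reference-cluster mapping for the given ids (default: all)."""
        ids = list(ids) if ids is not None else [a.id for a in self.areas]
        out = {}
        for i in ids:
            a = self[i]
            if a.reference_cluster:
                out[i] = a.reference_cluster
        return out

    @classmethod
    def from_csv(cls, path) -> "AreaRegistry":
        df = pd.read_csv(path, dtype=str).fillna("")
        required = {"id", "name", "lobe", "subdivision", "reference_cluster"}
        if not required.issubset(df.columns):
            raise MatrixError(f"registry must have columns {sorted(required)}")
        return cls(
            Area(r.id, r.name, r.lobe, r.subdivision, r.reference_cluster or None)
            for r in df.itertuples()
        )


def load_registry(path=None) -> AreaRegistry:
    """Load an area registry CSV; default is the packaged macaque
    parieto-frontal parcellation (37 frontal + 18 parietal target areas)."""
    if path is not None:
        return AreaRegistry.from_csv(path)
    ref = importlib.resources.files("pfclust").joinpath("data/areas.csv")
    with importlib.resources.as_file(ref) as p:
        return AreaRegistry.from_csv(p)


@dataclass
class ConnectivityMatrix:
    """Source-by-target table of ordinal input strengths.

    ``data`` is a float DataFrame whose index holds source-area ids and
    whose columns hold target-area ids.  In canonical mode every cell is
    one of the ordinal levels {0, 16, 33, 67, 100}; permissive mode allows
    any value in [0, 100] (used by synthetic generators that jitter
    strengths).
    """

    data: pd.DataFrame
    canonical: bool = True

    def __post_init__(self):
        self.data = self.data.astype(float)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def sources(self) -> list[str]:
        return list(self.data.index)

    @property
    def targets(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def is_square(self) -> bool:
        return self.sources == self.targets

    def __eq__(self, other) -> bool:
        return isinstance(other, ConnectivityMatrix) and self.data.equals(other.data)

    def validate(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            raise MatrixError(f"duplicate source ids: {sorted(idx[idx.duplicated()])}")
        if cols.has_duplicates:
            raise MatrixError(f"duplicate target ids: {sorted(cols[cols.duplicated()])}")
        vals = self.data.to_numpy()
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise MatrixError(f"missing cell at ({idx[r]}, {cols[c]})")
        if self.canonical:
            ok = np.isin(vals, CANONICAL_LEVELS)
            if not ok.all():
                r, c = np.argwhere(~ok)[0]
                raise MatrixError(
                    f"non-canonical value {vals[r, c]!r} at ({idx[r]}, {cols[c]}); "
                    f"canonical levels are {CANONICAL_LEVELS}"
                )
        else:
            if ((vals < 0) | (vals > 100)).any():
                raise MatrixError("values must lie in [0, 100]")

    def source_hash(self) -> str:
        """Order-sensitive digest of labels and values (run provenance)."""
        import hashlib

        h = hashlib.sha256()
        h.update("\x1f".join(self.sources).encode())
        h.update("\x1e".encode())
        h.update("\x1f".join(self.targets).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()


def _parse_cell(cell, row_id, col_id) -> float:
    if isinstance(cell, str):
        s = cell.strip()
        try:
            return float(s)
        except ValueError:
            pass
        try:
            return float(encode_strength(s))
        except MatrixError:
            raise MatrixError(
                f"cell ({row_id}, {col_id}): {cell!r} is neither a number "
                f"nor a strength word {sorted(STRENGTH_WORDS)}"
            ) from None
    return float(cell)


def load_matrix(path, *, sep: str | None = None, canonical: bool = True) -> ConnectivityMatrix:
    """Read a delimited connectivity table.

    Layout: first row holds target-area ids, first column source-area ids;
    cells are ordinals or strength words (mixed cells are normalised via
    :func:`encode_strength`).  The delimiter is sniffed from the extension
    (``.tsv`` -> tab, otherwise comma) unless given explicitly.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    with open(path) as fh:
        header = [h.strip() for h in fh.readline().rstrip("\n").split(sep)][1:]
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise MatrixError(f"duplicate target ids in header of {path}: {dup}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    if raw.isna().any().any():
        r, c = np.argwhere(raw.isna().to_numpy())[0]
        raise MatrixError(
            f"ragged or empty cell at ({raw.index[r]}, {raw.columns[c]}) in {path}"
        )
    parsed = pd.DataFrame(
        [
            [_parse_cell(raw.iat[i, j], raw.index[i], raw.columns[j])
             for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
    )
    return ConnectivityMatrix(parsed, canonical=canonical)


def write_matrix(matrix: ConnectivityMatrix, path, *, sep: str | None = None) -> None:
    """Write a connectivity table; cells are emitted as ordinals only."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    out = matrix.data.copy()
    if matrix.canonical:
        out = out.astype(int)
    out.to_csv(path, sep=sep)


def subset_targets(
    matrix: ConnectivityMatrix,
    keep: Sequence[str],
    *,
    restrict_sources: bool = False,
) -> ConnectivityMatrix:
    """Reduce the matrix to the given target columns (order preserved from
    ``keep``); with ``restrict_sources`` the rows are reduced to the same
    set, as in the intrinsic SPL-IPL analysis that keeps only connections
    between the superior and inferior parietal lobules."""
    keep = list(keep)
    missing = [k for k in keep if k not in matrix.data.columns]
    if missing:
        raise MatrixError(f"unknown target ids in subset: {missing}")
    data = matrix.data[keep]
    if restrict_sources:
        missing = [k for k in keep if k not in matrix.data.index]
        if missing:
            raise MatrixError(f"unknown source ids in subset: {missing}")
        data = data.loc[keep]
    return ConnectivityMatrix(data.copy(), canonical=matrix.canonical)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between target-area input profiles."""

    labels: list[str]
    d: np.ndarray  # square form

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise MatrixError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise MatrixError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise MatrixError("distance matrix must have a zero diagonal")
        if (self.d < 0).any():
            raise MatrixError("distances must be nonnegative")

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


def column_distances(
    matrix: ConnectivityMatrix, *, exclude_self: bool = False
) -> DistanceMatrix:
    """Euclidean distances between the input profiles (columns) of every
    pair of target areas, over all rows present.

    With ``exclude_self`` (square matrices only) the two rows named after
    the pair of targets being compared are dropped from that pair's
    profile vectors, so an area's self-connection convention cannot
    influence the distances.  Default keeps all rows: a target's own row
    is part of its column vector and carries 0 by convention.
    """
    if len(matrix.targets) < 2:
        raise MatrixError("need at least two target columns for distances")
    X = matrix.values.T  # targets x sources
    labels = matrix.targets
    if not exclude_self:
        d = squareform(pdist(X, metric="euclidean"))
    else:
        if not matrix.is_square:
            raise MatrixError("exclude_self requires a square matrix")
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mask = np.ones(n, dtype=bool)
                mask[[i, j]] = False
                d[i, j] = d[j, i] = float(
                    np.linalg.norm(X[i, mask] - X[j, mask])
                )
    return DistanceMatrix(labels=list(labels), d=d)
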