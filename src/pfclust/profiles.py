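"""Cluster-level input profiling: mean strengths, entropy, cluster graph.

Once areas are grouped into clusters, each cluster's inputs are summarised
by the mean connection strength it receives from every cluster (0-100
scale, absent connections counting as zeros) and by the Shannon entropy
H = -sum p_i ln p_i (in nats) of the normalised input fractions.  Entropy
is maximal (ln K) for a uniform distribution over K inputs and zero when
all input comes from a single cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ConnectivityMatrix, MatrixError

__all__ = [
    "ClusterAssignment",
    "ClusterProfile",
    "mean_cluster_input",
    "area_input_profile",
    "input_entropy",
    "profile_all",
    "cluster_graph",
]


class ClusterAssignment:
    """Mapping from area id to cluster label (every area exactly once)."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = dict(mapping)
        if not self.mapping:
            raise MatrixError("empty cluster assignment")
        # stable cluster order: first appearance
        seen: list[str] = []
        for label in self.mapping.values():
            if label not in seen:
                seen.append(label)
        self.clusters: list[str] = seen

    def __getitem__(self, area: str) -> str:
        try:
            return self.mapping[area]
        except KeyError:
            raise MatrixError(f"area {area!r} has no cluster assignment") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, ClusterAssignment) and self.mapping == other.mapping

    def members(self, label: str) -> list[str]:
        if label not in self.clusters:
            raise MatrixError(f"unknown cluster label {label!r}")
        return [a for a, l in self.mapping.items() if l == label]

    @property
    def areas(self) -> list[str]:
        return list(self.mapping)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area": list(self.mapping), "cluster": list(self.mapping.values())}
        )

    @classmethod
    def from_csv(cls, path) -> "ClusterAssignment":
        df = pd.read_csv(path, dtype=str)
        if not {"area", "cluster"}.issubset(df.columns):
            raise MatrixError("assignment CSV needs columns area,cluster")
        if df["area"].duplicated().any():
            raise MatrixError("areas assigned more than once")
        return cls(dict(zip(df["area"], df["cluster"])))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def mean_cluster_input(
    matrix: ConnectivityMatrix,
    assignment: ClusterAssignment,
    receiving: str,
    projecting: str,
) -> float:
    """Mean strength over all (source in projecting, target in receiving)
    pairs, zeros included.  Self pairs (source == target) are excluded:
    the diagonal carries a structural zero, not an observed connection.
    """
    recv = [a for a in assignment.members(receiving) if a in matrix.data.columns]
    proj = [a for a in assignment.members(projecting) if a in matrix.data.index]
    if not recv:
        raise MatrixError(f"no areas of cluster {receiving!r} among matrix targets")
    if not proj:
        raise MatrixError(f"no areas of cluster {projecting!r} among matrix sources")
    block = matrix.data.loc[proj, recv]
    vals = block.to_numpy(dtype=float)
    mask = np.ones_like(vals, dtype=bool)
    for i, s in enumerate(proj):
        for j, t in enumerate(recv):
            if s == t:
                mask[i, j] = False
    if not mask.any():
        return 0.0
    return float(vals[mask].mean())


def input_entropy(profile: Sequence[float]) -> float:
    """Shannon entropy (nats) of a nonnegative input vector.

    The vector is normalised to fractions p_i = input_i / sum(inputs);
    H = -sum p_i ln p_i with 0 ln 0 = 0.  An all-zero vector has no
    defined input distribution and is rejected.
    """
    v = np.asarray(list(profile), dtype=float)
    if (v < 0).any():
        raise MatrixError("input values must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise MatrixError("entropy undefined for an all-zero input vector")
    p = v[v > 0] / total
    p = p[p > 0]  # guard against underflow of extreme fractions
    return float(-(p * np.log(p)).sum())


def area_input_profile(
    matrix: ConnectivityMatrix,
    assignment: ClusterAssignment,
    receiving: str,
    *,
    include_self: bool = True,
) -> dict[str, float]:
    """Mean input to the receiving cluster from each individual source
    area (the area-level alternative to cluster-level input fractions).
    Self pairs are excluded cell-wise; with ``include_self=False`` sources
    belonging to the receiving cluster are dropped entirely."""
    recv = [a for a in assignment.members(receiving) if a in matrix.data.columns]
    if not recv:
        raise MatrixError(f"no areas of cluster {receiving!r} among matrix targets")
    out: dict[str, float] = {}
    for s in matrix.data.index:
        if not include_self and assignment.mapping.get(s) == receiving:
            continue
        cells = [float(matrix.data.at[s, t]) for t in recv if t != s]
        if cells:
            out[s] = float(np.mean(cells))
    return out


@dataclass
class ClusterProfile:
    """Mean inputs to one receiving cluster and their entropy (nats)."""

    receiving: str
    mean_input: dict[str, float]  # projecting cluster -> mean strength
    H: float

    @property
    def p(self) -> dict[str, float]:
        total = sum(self.mean_input.values())
        return {k: v / total for k, v in self.mean_input.items()}


def profile_all(
    matrix: ConnectivityMatrix,
    assignment: ClusterAssignment,
    *,
    include_self: bool = True,
    level: str = "cluster",
) -> list[ClusterProfile]:
    """One profile per cluster: mean input from every projecting cluster
    and the entropy of the input distribution.

    ``include_self`` keeps the receiving cluster's own (local) input in
    the entropy computation — local connectivity is part of a cluster's
    input budget; set False to profile external inputs only.  ``level``
    selects the fractions the entropy is computed over: ``cluster``
    (default, one input per projecting cluster) or ``area`` (one input
    per individual source area).
    """
    if level not in ("cluster", "area"):
        raise MatrixError("level must be 'cluster' or 'area'")
    profiles = []
    for recv in assignment.clusters:
        means = {}
        for proj in assignment.clusters:
            if not include_self and proj == recv:
                continue
            means[proj] = mean_cluster_input(matrix, assignment, recv, proj)
        if level == "cluster":
            h_inputs = list(means.values())
        else:
            h_inputs = list(
                area_input_profile(
                    matrix, assignment, recv, include_self=include_self
                ).values()
            )
        profiles.append(
            ClusterProfile(
                receiving=recv,
                mean_input=means,
                H=input_entropy(h_inputs),
            )
        )
    return profiles


def profiles_frame(profiles: Sequence[ClusterProfile]) -> pd.DataFrame:
    """Long-format table (receiving, projecting, mean_input, H)."""
    rows = []
    for p in profiles:
        for proj, v in p.mean_input.items():
            rows.append(
                {
                    "receiving": p.receiving,
                    "projecting": proj,
                    "mean_input": v,
                    "H": p.H,
                }
            )
    return pd.DataFrame(rows)


def cluster_graph(
    matrix: ConnectivityMatrix,
    assignment: ClusterAssignment,
    *,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Weighted directed edge list projecting -> receiving with weight
    ``mean_cluster_input``; edges at or below ``threshold`` are dropped.
    The frame converts directly to a graph via
    ``networkx.from_pandas_edgelist(..., create_using=nx.DiGraph)``.
    """
    rows = []
    for recv in assignment.clusters:
        for proj in assignment.clusters:
            w = mean_cluster_input(matrix, assignment, recv, proj)
            if w > threshold:
                rows.append({"projecting": proj, "receiving": recv, "weight": w})
    return pd.DataFrame(rows, columns=["projecting", "receiving", "weight"])
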