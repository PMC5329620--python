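"""Bootstrap candidate-tree search and branch-length fitting.

The tree search follows a two-stage scheme.  Agglomerative clustering of
the Euclidean distances between target input profiles yields one candidate
topology per bootstrap resample of the matrix rows (plus one from the
original data).  Each candidate topology is then refit against the
*original, unsampled* distances: branch lengths solve a nonnegative
least-squares problem matching leaf-to-leaf path lengths to the observed
distances, and the fit statistic is the Gaussian log-likelihood of the
distances given the tree.  Bootstrapping only proposes topologies; it
never enters the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.optimize import nnls as _nnls

from .matrix import ConnectivityMatrix, DistanceMatrix, MatrixError, column_distances

__all__ = [
    "TreeTopology",
    "FittedTree",
    "TreeEnsemble",
    "bootstrap_rows",
    "agglomerative_topology",
    "fit_branch_lengths",
    "candidate_search",
    "top_k",
    "enumerate_rooted_topologies",
]

LINKAGE_RULES = ("average", "complete", "single", "ward")

#: Variance floor in the plug-in Gaussian likelihood.  An exactly additive
#: fit (sse == 0) would otherwise have unbounded likelihood; below this
#: floor trees are tied and ordered by generation order.
SIGMA2_FLOOR = 1e-12


def _node_leaves(node) -> tuple:
    if isinstance(node, str):
        return (node,)
    out = []
    for child in node:
        out.extend(_node_leaves(child))
    return tuple(out)


class TreeTopology:
    """A rooted tree over target-area leaves, identified by its clades.

    ``root`` is a nested structure: a leaf is a label string, an internal
    node a tuple of child nodes (binary for agglomerative candidates;
    consensus trees may be multifurcating).  Clade identity ignores branch
    lengths and child order.
    """

    def __init__(self, root):
        self.root = root
        self.leaves: tuple[str, ...] = _node_leaves(root)
        if len(set(self.leaves)) != len(self.leaves):
            raise MatrixError("tree leaves must be unique")

    @cached_property
    def clades(self) -> frozenset[frozenset[str]]:
        """Every node's leaf set: singletons, internal clades and the root."""
        out: set[frozenset] = set()

        def walk(node) -> frozenset:
            if isinstance(node, str):
                c = frozenset((node,))
            else:
                c = frozenset().union(*(walk(ch) for ch in node))
            out.add(c)
            return c

        walk(self.root)
        return frozenset(out)

    @cached_property
    def internal_clades(self) -> frozenset[frozenset[str]]:
        return frozenset(c for c in self.clades if len(c) > 1)

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaves)

    def key(self) -> frozenset:
        """Canonical identity for duplicate detection / fit memoisation."""
        return self.internal_clades

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TreeTopology)
            and self.leaf_set == other.leaf_set
            and self.internal_clades == other.internal_clades
        )

    def __hash__(self) -> int:
        return hash((self.leaf_set, self.internal_clades))

    def contains_clade(self, areas: Iterable[str]) -> bool:
        return frozenset(areas) in self.clades

    def to_newick(
        self,
        branch_lengths: dict[frozenset, float] | None = None,
        support: dict[frozenset, object] | None = None,
    ) -> str:
        def fmt(node) -> str:
            clade = frozenset(_node_leaves(node))
            if isinstance(node, str):
                s = node
            else:
                s = "(" + ",".join(fmt(ch) for ch in node) + ")"
                if support is not None and clade in support:
                    s += str(support[clade])
            if branch_lengths is not None and clade in branch_lengths:
                s += f":{branch_lengths[clade]:.6g}"
            return s

        return fmt(self.root) + ";"


def bootstrap_rows(matrix: ConnectivityMatrix, rng: np.random.Generator) -> ConnectivityMatrix:
    """Resample the matrix rows with replacement.

    Entire rows are always kept: each output row is an exact copy of an
    input row, duplicates allowed and omissions allowed; the columns are
    untouched.  Duplicated source labels get a ``#k`` suffix so the result
    remains a valid matrix.
    """
    n = len(matrix.sources)
    if n == 0:
        raise MatrixError("cannot bootstrap an empty matrix")
    idx = rng.integers(0, n, size=n)
    data = matrix.data.iloc[idx].copy()
    counts: dict[str, int] = {}
    labels = []
    for s in data.index:
        k = counts.get(s, 0)
        counts[s] = k + 1
        labels.append(s if k == 0 else f"{s}#{k}")
    data.index = labels
    return ConnectivityMatrix(data, canonical=matrix.canonical)


def agglomerative_topology(d: DistanceMatrix, linkage: str = "average") -> TreeTopology:
    """Binary rooted topology from successive nearest-cluster merges.

    Thin wrapper over :func:`scipy.cluster.hierarchy.linkage`; only the
    merge structure is retained (cluster heights play no role downstream —
    branch lengths are refit against the original data).
    """
    if linkage not in LINKAGE_RULES:
        raise MatrixError(f"linkage must be one of {LINKAGE_RULES}")
    if len(d.labels) < 2:
        raise MatrixError("need at least two leaves")
    Z = _scipy_linkage(d.condensed, method=linkage)
    nodes: list = list(d.labels)
    for a, b, *_ in Z:
        nodes.append((nodes[int(a)], nodes[int(b)]))
    return TreeTopology(nodes[-1])


@dataclass
class FittedTree:
    """A topology with nonnegative branch lengths fitted to distance data.

    ``branch_lengths`` maps each non-root clade to the length of the edge
    above it.  ``sse`` is the residual sum of squares between tree path
    lengths and the observed distances over all leaf pairs; ``loglik`` the
    plug-in Gaussian log-likelihood, a decreasing function of ``sse``.
    """

    topology: TreeTopology
    branch_lengths: dict[frozenset, float]
    sse: float
    loglik: float
    origin: int = -1  # 0 = original-data tree, i >= 1 = bootstrap replicate i

    def path_distances(self) -> DistanceMatrix:
        labels = sorted(self.topology.leaves)
        n = len(labels)
        pos = {l: i for i, l in enumerate(labels)}
        d = np.zeros((n, n))
        for clade, length in self.branch_lengths.items():
            inside = np.zeros(n, dtype=bool)
            for l in clade:
                inside[pos[l]] = True
            sep = np.logical_xor.outer(inside, inside)
            d += sep * length
        return DistanceMatrix(labels=labels, d=d)


def _design_matrix(topology: TreeTopology, labels: Sequence[str]):
    """Leaf-pair x edge incidence: entry 1 iff the edge separates the pair."""
    pos = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    edges = sorted(
        (c for c in topology.clades if c != topology.leaf_set),
        key=lambda c: (len(c), sorted(c)),
    )
    cols = []
    for c in edges:
        inside = np.zeros(n, dtype=bool)
        for l in c:
            inside[pos[l]] = True
        cols.append(np.logical_xor.outer(inside, inside)[iu])
    A = np.column_stack(cols).astype(float)
    return A, edges, iu


def _gaussian_loglik(sse: float, m: int) -> float:
    sigma2 = max(sse / m, SIGMA2_FLOOR)
    return -(m / 2.0) * (math.log(2.0 * math.pi * sigma2) + 1.0)


def fit_branch_lengths(topology: TreeTopology, d_original: DistanceMatrix) -> FittedTree:
    """Nonnegative least-squares branch lengths for a fixed topology.

    Solves ``min ||A x - d||^2, x >= 0`` where A is the pair-by-edge path
    incidence of the topology and d the observed leaf-pair distances.  The
    log-likelihood assumes iid Gaussian residuals on the m = n(n-1)/2 leaf
    pairs with plug-in MLE variance sse/m, so tree rankings coincide with
    least-squares rankings.  Edges fitted to exactly zero are reported,
    not pruned.
    """
    if topology.leaf_set != frozenset(d_original.labels):
        raise MatrixError(
            "topology leaves do not match distance labels: "
            f"{sorted(topology.leaf_set ^ frozenset(d_original.labels))}"
        )
    labels = sorted(d_original.labels)
    order = [d_original.labels.index(l) for l in labels]
    dsq = d_original.d[np.ix_(order, order)]
    A, edges, iu = _design_matrix(topology, labels)
    y = dsq[iu]
    x, rnorm = _nnls(A, y)
    sse = float(rnorm**2)
    m = len(y)
    return FittedTree(
        topology=topology,
        branch_lengths={c: float(v) for c, v in zip(edges, x)},
        sse=sse,
        loglik=_gaussian_loglik(sse, m),
    )


@dataclass
class TreeEnsemble:
    """All fitted candidate trees from one search, best first."""

    trees: list[FittedTree]
    n_bootstrap: int
    seed: int
    source_hash: str
    linkage: str = "average"

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def best(self) -> FittedTree:
        return self.trees[0]

    def summary(self, max_trees: int | None = None) -> dict:
        """JSON-ready provenance + per-tree fit statistics (optionally
        truncated to the ``max_trees`` best)."""
        listed = self.trees if max_trees is None else self.trees[:max_trees]
        logliks = [t.loglik for t in self.trees]
        return {
            "seed": self.seed,
            "n_bootstrap": self.n_bootstrap,
            "linkage": self.linkage,
            "source_hash": self.source_hash,
            "n_trees": len(self.trees),
            "loglik_best": logliks[0],
            "loglik_worst": logliks[-1],
            "trees": [
                {"origin": t.origin, "sse": t.sse, "loglik": t.loglik}
                for t in listed
            ],
        }


def candidate_search(
    matrix: ConnectivityMatrix,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    linkage: str = "average",
    *,
    exclude_self: bool = False,
) -> TreeEnsemble:
    """Generate and fit the full candidate ensemble.

    One agglomerative topology is built from the original matrix and one
    from each of ``n_bootstrap`` row resamples; every topology's branch
    lengths are then refit against the original matrix's distances.  The
    ensemble therefore holds ``n_bootstrap + 1`` fitted trees, sorted by
    decreasing log-likelihood (ties broken by generation order, the
    original-data tree first).  Duplicate topologies are retained as
    distinct entries — they count multiply in the consensus.

    Each bootstrap replicate draws from an independent substream derived
    from ``seed``, so results do not depend on evaluation order.
    """
    if n_bootstrap < 0:
        raise MatrixError("n_bootstrap must be >= 0")
    d_orig = column_distances(matrix, exclude_self=exclude_self)
    fit_cache: dict[frozenset, FittedTree] = {}

    def fit(topology: TreeTopology, origin: int) -> FittedTree:
        key = topology.key()
        cached = fit_cache.get(key)
        if cached is None:
            cached = fit_branch_lengths(topology, d_orig)
            fit_cache[key] = cached
        return FittedTree(
            topology=cached.topology,
            branch_lengths=cached.branch_lengths,
            sse=cached.sse,
            loglik=cached.loglik,
            origin=origin,
        )

    trees = [fit(agglomerative_topology(d_orig, linkage), origin=0)]
    for i in range(1, n_bootstrap + 1):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        boot = bootstrap_rows(matrix, rng)
        d_boot = column_distances(boot, exclude_self=False)
        trees.append(fit(agglomerative_topology(d_boot, linkage), origin=i))
    trees.sort(key=lambda t: -t.loglik)  # stable: ties keep generation order
    return TreeEnsemble(
        trees=trees,
        n_bootstrap=n_bootstrap,
        seed=seed,
        source_hash=matrix.source_hash(),
        linkage=linkage,
    )


def top_k(ensemble: TreeEnsemble, k: int) -> list[FittedTree]:
    """The k highest-likelihood trees (ties resolved by generation order)."""
    if k > len(ensemble):
        raise MatrixError(f"k={k} exceeds ensemble size {len(ensemble)}")
    return ensemble.trees[:k]


def enumerate_rooted_topologies(labels: Sequence[str]) -> Iterator[TreeTopology]:
    """Exhaustively enumerate all rooted binary topologies on the labels.

    There are (2n-3)!! such trees; intended as a brute-force oracle for
    small n (<= 7 or so).
    """
    labels = list(labels)
    if len(labels) == 0:
        return
    if len(labels) == 1:
        yield TreeTopology(labels[0])
        return

    def grow(node, leaf):
        # attach `leaf` on every edge below `node`, yielding new subtrees
        yield (node, leaf)  # attach above node (new internal node)
        if not isinstance(node, str):
            left, right = node
            for g in grow(left, leaf):
                yield (g, right)
            for g in grow(right, leaf):
                yield (left, g)

    shapes = [labels[0]]
    for leaf in labels[1:]:
        shapes = [g for s in shapes for g in grow(s, leaf)]
    for s in shapes:
        yield TreeTopology(s)
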