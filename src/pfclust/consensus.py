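"""Consensus trees over the best candidate topologies.

The consensus retains the clades (clusters of areas) that occur most
often among the k best trees and annotates each with its occurrence
count.  Two rules are available: strict majority (> k/2) and greedy
extended majority, which adds clades in order of decreasing count while
they stay compatible with those already retained.  The greedy rule is the
default because observed consensus support values can fall well below
half (e.g. a cluster retained with 29 occurrences out of 100), which a
strict-majority consensus would discard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .matrix import MatrixError
from .trees import FittedTree, TreeTopology

__all__ = ["ConsensusTree", "clade_counts", "build_consensus", "occurrence_of"]

CONSENSUS_RULES = ("greedy", "majority")


def _as_topologies(trees: Sequence) -> list[TreeTopology]:
    out = []
    for t in trees:
        out.append(t.topology if isinstance(t, FittedTree) else t)
    if not out:
        raise MatrixError("need at least one tree")
    leaf_set = out[0].leaf_set
    for t in out[1:]:
        if t.leaf_set != leaf_set:
            raise MatrixError("trees do not share a leaf set")
    return out


def clade_counts(trees: Sequence) -> dict[frozenset, int]:
    """For every clade appearing in any tree, the number of trees
    containing it.  Singleton and full-leaf-set clades are present in
    every tree by construction."""
    topos = _as_topologies(trees)
    counts: dict[frozenset, int] = {}
    for t in topos:
        for c in t.clades:
            counts[c] = counts.get(c, 0) + 1
    return counts


def occurrence_of(trees: Sequence, areas: Iterable[str]) -> int:
    """Number of trees containing exactly the given leaf subset as a clade."""
    topos = _as_topologies(trees)
    clade = frozenset(areas)
    unknown = clade - topos[0].leaf_set
    if unknown:
        raise MatrixError(f"unknown leaves: {sorted(unknown)}")
    return sum(1 for t in topos if clade in t.clades)


def _compatible(c: frozenset, kept: Iterable[frozenset]) -> bool:
    return all(c <= o or o <= c or not (c & o) for o in kept)


def _nest(clades: set[frozenset], leaf_set: frozenset) -> TreeTopology:
    """Build the (possibly multifurcating) tree induced by a pairwise
    compatible clade set that contains the full leaf set."""

    def build(clade: frozenset):
        if len(clade) == 1:
            return next(iter(clade))
        children_clades: list[frozenset] = []
        for c in sorted(
            (c for c in clades if c < clade), key=lambda c: -len(c)
        ):
            if all(not (c & k) for k in children_clades):
                children_clades.append(c)
        covered = frozenset().union(*children_clades) if children_clades else frozenset()
        for leaf in sorted(clade - covered):
            children_clades.append(frozenset((leaf,)))
        children_clades.sort(key=lambda c: sorted(c)[0])
        return tuple(build(c) for c in children_clades)

    return TreeTopology(build(leaf_set))


@dataclass
class ConsensusTree:
    """Clades retained by the consensus rule, each with its occurrence count."""

    topology: TreeTopology
    counts: dict[frozenset, int]  # retained clades only
    k: int
    rule: str

    @property
    def clades(self) -> frozenset:
        return frozenset(self.counts)

    def count(self, areas: Iterable[str]) -> int:
        return self.counts.get(frozenset(areas), 0)

    def to_newick(self) -> str:
        support = {
            c: n for c, n in self.counts.items()
            if len(c) > 1 and c != self.topology.leaf_set
        }
        return self.topology.to_newick(support=support)

    def table(self):
        """Clade table as records (members sorted, count, k)."""
        rows = [
            {"clade_members": ";".join(sorted(c)), "count": n, "k": self.k}
            for c, n in sorted(self.counts.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
        ]
        return rows


def build_consensus(trees: Sequence, rule: str = "greedy") -> ConsensusTree:
    """Assemble the consensus tree of the given trees.

    ``majority`` keeps clades occurring in more than half the trees;
    ``greedy`` scans clades by decreasing count (ties: larger clades
    first, then lexicographic member order) and keeps each one compatible
    with everything already kept.  Both always retain the trivial clades.
    """
    if rule not in CONSENSUS_RULES:
        raise MatrixError(f"rule must be one of {CONSENSUS_RULES}")
    topos = _as_topologies(trees)
    k = len(topos)
    leaf_set = topos[0].leaf_set
    counts = clade_counts(topos)

    kept: dict[frozenset, int] = {}
    # trivial clades first: always compatible, always count k
    kept[leaf_set] = k
    for leaf in leaf_set:
        kept[frozenset((leaf,))] = k

    nontrivial = [
        (c, n) for c, n in counts.items() if 1 < len(c) < len(leaf_set)
    ]
    nontrivial.sort(key=lambda cn: (-cn[1], -len(cn[0]), sorted(cn[0])))
    for c, n in nontrivial:
        if rule == "majority" and n * 2 <= k:
            continue
        if _compatible(c, kept):
            kept[c] = n
    topology = _nest(set(kept), leaf_set)
    return ConsensusTree(topology=topology, counts=kept, k=k, rule=rule)
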