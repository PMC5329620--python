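"""End-to-end orchestration: subset -> distances -> bootstrap tree search
-> best-k selection -> consensus -> cluster profiling, with a serialisable
run report.  Defaults reproduce the published workflow settings: 10,000
bootstrap replicates (10,001 candidate trees) and the 100 best trees by
log-likelihood feeding the consensus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .consensus import ConsensusTree, build_consensus
from .matrix import AreaRegistry, ConnectivityMatrix, MatrixError, subset_targets
from .profiles import ClusterAssignment, cluster_graph, profile_all, profiles_frame
from .trees import TreeEnsemble, TreeTopology, candidate_search, top_k

log = logging.getLogger("pfclust")

__all__ = ["RunConfig", "RunReport", "run_analysis", "compare_partitions", "cut_tree_partition"]


@dataclass
class RunConfig:
    """Settings of one full analysis run (defaults match the published
    procedure: 10,000 bootstraps, consensus over the 100 best trees)."""

    n_bootstrap: int = 10_000
    k_best: int = 100
    linkage: str = "average"
    consensus_rule: str = "greedy"
    seed: int = 0
    targets: Sequence[str] | str | None = None  # ids, or a registry lobe name
    restrict_sources: bool = False
    exclude_self_distance: bool = False
    entropy_include_self: bool = True
    entropy_level: str = "cluster"  # or "area": fractions over source areas
    n_clusters: int | None = None  # derive a partition from the consensus
    outdir: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise MatrixError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def compare_partitions(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Adjusted Rand index between two partitions of the same areas
    (1 iff identical; ~0 for independent random partitions)."""
    if set(a.areas) != set(b.areas):
        raise MatrixError("partitions cover different area sets")
    areas = sorted(a.areas)
    return float(adjusted_rand_score([a[x] for x in areas], [b[x] for x in areas]))


def _children_map(topology: TreeTopology) -> dict[frozenset, list[frozenset]]:
    out: dict[frozenset, list[frozenset]] = {}

    def walk(node) -> frozenset:
        if isinstance(node, str):
            return frozenset((node,))
        kids = [walk(ch) for ch in node]
        clade = frozenset().union(*kids)
        out[clade] = kids
        return clade

    walk(topology.root)
    return out


def cut_tree_partition(topology: TreeTopology, k: int) -> ClusterAssignment:
    """Partition the leaves into ~k blocks by successive tree splits.

    Starting from the root, the frontier block with the most leaves is
    replaced by its children (ties: block containing the alphabetically
    first leaf) until at least k blocks exist or nothing can be split.
    Works on binary and multifurcating (consensus) trees alike.
    """
    if k < 1:
        raise MatrixError("k must be >= 1")
    children = _children_map(topology)
    frontier: list[frozenset] = [topology.leaf_set]
    while len(frontier) < k:
        splittable = [c for c in frontier if c in children]
        if not splittable:
            break
        # deterministic tie-break: largest block, then alphabetically first leaf
        maxlen = max(len(c) for c in splittable)
        pick = min(
            (c for c in splittable if len(c) == maxlen), key=lambda c: min(c)
        )
        frontier.remove(pick)
        frontier.extend(children[pick])
    blocks = sorted(frontier, key=lambda c: min(c))
    return ClusterAssignment(
        {leaf: f"C{idx + 1}" for idx, block in enumerate(blocks) for leaf in sorted(block)}
    )


@dataclass
class RunReport:
    """Everything a rerun needs plus the run's outputs."""

    config: RunConfig
    ensemble: TreeEnsemble
    best_trees: list
    consensus: ConsensusTree
    assignment: ClusterAssignment | None
    profiles: list
    graph: pd.DataFrame | None
    source_hash: str

    def payload(self) -> dict:
        """Deterministic JSON-serialisable summary (no timestamps)."""
        out = {
            "version": __version__,
            "config": {**asdict(self.config), "targets": list(self.config.targets)
                       if isinstance(self.config.targets, (list, tuple)) else self.config.targets},
            "source_hash": self.source_hash,
            "ensemble": {
                "n_trees": len(self.ensemble),
                "seed": self.ensemble.seed,
                "linkage": self.ensemble.linkage,
                "best_loglik": self.ensemble.best.loglik,
                "best_sse": self.ensemble.best.sse,
            },
            "ml_tree": self.ensemble.best.topology.to_newick(
                branch_lengths=self.ensemble.best.branch_lengths
            ),
            "consensus": self.consensus.to_newick(),
            "consensus_clades": self.consensus.table(),
        }
        if self.assignment is not None:
            out["clusters"] = {a: self.assignment[a] for a in sorted(self.assignment.areas)}
            out["profiles"] = [
                {"receiving": p.receiving, "H": p.H, "mean_input": p.mean_input}
                for p in self.profiles
            ]
        return out


def run_analysis(
    matrix: ConnectivityMatrix,
    registry: AreaRegistry | None = None,
    config: RunConfig | None = None,
    *,
    assignment: ClusterAssignment | None = None,
) -> RunReport:
    """Execute the full analysis and (optionally) write its outputs.

    The cluster assignment used for profiling is, in order of preference:
    the one passed in, or a ``config.n_clusters``-way cut of the consensus
    tree.  With neither, profiling is skipped.
    """
    config = config or RunConfig()

    targets = config.targets
    if isinstance(targets, str):
        if registry is None:
            raise MatrixError(f"targets={targets!r} needs a registry")
        targets = registry.ids(lobe=targets)
    if targets is not None:
        matrix = subset_targets(matrix, targets, restrict_sources=config.restrict_sources)
    if registry is not None:
        missing = [t for t in matrix.targets if t.split("#")[0] not in registry]
        if missing:
            raise MatrixError(f"targets not in registry: {missing}")

    log.info(
        "candidate search: %d targets, %d bootstraps, seed=%d, linkage=%s",
        len(matrix.targets), config.n_bootstrap, config.seed, config.linkage,
    )
    ensemble = candidate_search(
        matrix,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
        linkage=config.linkage,
        exclude_self=config.exclude_self_distance,
    )
    best = top_k(ensemble, min(config.k_best, len(ensemble)))
    log.info("best tree loglik=%.3f sse=%.3f", best[0].loglik, best[0].sse)
    consensus = build_consensus(best, rule=config.consensus_rule)

    if assignment is None and config.n_clusters is not None:
        assignment = cut_tree_partition(consensus.topology, config.n_clusters)

    profiles, graph = [], None
    if assignment is not None:
        prof_matrix = matrix
        profiles = profile_all(
            prof_matrix,
            assignment,
            include_self=config.entropy_include_self,
            level=config.entropy_level,
        )
        graph = cluster_graph(prof_matrix, assignment)

    report = RunReport(
        config=config,
        ensemble=ensemble,
        best_trees=best,
        consensus=consensus,
        assignment=assignment,
        profiles=profiles,
        graph=graph,
        source_hash=matrix.source_hash(),
    )
    if config.outdir:
        _write_outputs(report, Path(config.outdir))
    return report


def _write_outputs(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    best = report.ensemble.best
    (outdir / "ml_tree.nwk").write_text(
        best.topology.to_newick(branch_lengths=best.branch_lengths) + "\n"
    )
    (outdir / "consensus.nwk").write_text(report.consensus.to_newick() + "\n")
    (outdir / "ensemble.json").write_text(
        json.dumps(report.ensemble.summary(), indent=2) + "\n"
    )
    pd.DataFrame(report.consensus.table()).to_csv(outdir / "consensus_clades.csv", index=False)
    if report.assignment is not None:
        profiles_frame(report.profiles).to_csv(outdir / "profiles.csv", index=False)
        report.graph.to_csv(outdir / "cluster_graph.csv", index=False)
        report.assignment.to_csv(outdir / "clusters.csv")
    (outdir / "report.json").write_text(json.dumps(report.payload(), indent=2) + "\n")
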