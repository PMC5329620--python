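"""Planted-cluster connectivity generators.

The literature-curated macaque matrix behind the analysis is not publicly
deposited, so every pipeline stage is exercised on synthetic matrices that
emulate its statistical structure: block-structured ordinal strengths
(connectivity stronger locally, within a planted cluster, than between
clusters), reciprocal but often asymmetric long-range connections, and the
five-level ordinal vocabulary {0, 16, 33, 67, 100}.

``macaque_fixture`` reproduces the shape of the real analysis: the
packaged parcellation's target areas and named clusters, with inter-cluster
block means seeded from the published spider-plot mean-input values where
available.  All fixtures are synthetic; none contains curated data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    CANONICAL_LEVELS,
    AreaRegistry,
    ConnectivityMatrix,
    MatrixError,
    load_registry,
    write_matrix,
)
from .profiles import ClusterAssignment

__all__ = ["PlantedSpec", "generate_planted_matrix", "macaque_fixture", "write_fixture"]

#: Published mean input strengths between the 11 named clusters
#: (receiving cluster -> {projecting cluster: mean on the 0-100 scale}).
#: Within-cluster (local) input defaults to 50; pairs not listed default
#: to a weak background of 5.
PUBLISHED_BLOCK_MEANS: dict[str, dict[str, float]] = {
    "pmSPL": {"mdSPL": 50, "CING": 31.4, "pIPL": 24.8, "MI-dmPM": 23,
              "pPFC": 8.3, "aIPL": 6.6, "dmPFC": 6.3},
    "mdSPL": {"aSPL": 45.8, "pmSPL": 44.3, "MI-dmPM": 29, "CING": 22,
              "aIPL": 15.8, "pIPL": 5.1},
    "aSPL": {"mdSPL": 33.4, "CING": 16.5, "MI-dmPM": 12.4, "aIPL": 6.7},
    "aIPL": {"vPM": 44.2, "aSPL": 24.8, "pIPL": 22.5, "mdSPL": 20.6,
             "CING": 14.2, "voPFC": 9.6, "MI-dmPM": 7.1, "pmSPL": 5.5},
    "pIPL": {"pmSPL": 36.2, "aIPL": 23.3, "pPFC": 17.6, "CING": 8.3,
             "aSPL": 8.3, "vPM": 8.3, "mdSPL": 7.3},
    "MI-dmPM": {"CING": 43.4, "mdSPL": 32.6, "vPM": 30.5, "pmSPL": 23.1,
                "aSPL": 18, "pPFC": 8.7, "aIPL": 7.1},
    "vPM": {"aIPL": 45.1, "MI-dmPM": 27, "aSPL": 12.5, "voPFC": 11.1,
            "CING": 10.9, "mdSPL": 7.3},
    "CING": {"dmPFC": 34, "pmSPL": 33.1, "MI-dmPM": 28.4, "aSPL": 24.8,
             "voPFC": 24.5, "mdSPL": 20.7, "pPFC": 19.3, "aIPL": 14.3},
    "pPFC": {"pIPL": 20.7, "CING": 20.6, "pmSPL": 15.3, "voPFC": 14.8,
             "dmPFC": 13.4, "MI-dmPM": 7.6},
    "dmPFC": {"CING": 27, "voPFC": 19.0, "pPFC": 11.9},
    "voPFC": {"CING": 17.8, "pPFC": 12.4, "aIPL": 10.7, "vPM": 10.6,
              "dmPFC": 9.2},
}

DEFAULT_WITHIN_MEAN = 50.0
DEFAULT_BETWEEN_MEAN = 5.0

FIXTURE_SIDES = ("parietal", "frontal", "SPL_IPL", "full")

#: Cluster membership for the intrinsic SPL-IPL analysis; relative to the
#: parieto-frontal partition, MIP moves into pmSPL and PEa into aSPL,
#: leaving mdSPL with PEc and PEci.
SPL_IPL_REASSIGNMENT = {"MIP": "pmSPL", "PEa": "aSPL"}


@dataclass
class PlantedSpec:
    """Parameters of a planted-partition ordinal matrix.

    flip_rate is the probability that a cell's level is resampled
    uniformly from the vocabulary (noise on the ordinal scale);
    asymmetry is the probability that a reciprocal pair of cells is
    perturbed to differ by one level, emulating reciprocal connections of
    unequal strength.
    """

    clusters: list[tuple[str, int]]
    within_mean: float = DEFAULT_WITHIN_MEAN
    between_mean: float = DEFAULT_BETWEEN_MEAN
    strength_levels: tuple = CANONICAL_LEVELS
    flip_rate: float = 0.0
    asymmetry: float = 0.3
    seed: int = 0
    #: optional (receiving_label -> projecting_label -> mean) overrides
    block_means: dict[str, dict[str, float]] = field(default_factory=dict)
    #: optional explicit area ids per cluster (default: synthesised)
    areas: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if any(size < 1 for _, size in self.clusters):
            raise MatrixError("cluster sizes must be >= 1")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise MatrixError("flip_rate must lie in [0, 1]")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise MatrixError("asymmetry must lie in [0, 1]")
        self.strength_levels = tuple(sorted(self.strength_levels))

    def block_mean(self, receiving: str, projecting: str) -> float:
        override = self.block_means.get(receiving, {}).get(projecting)
        if override is not None:
            return float(override)
        return self.within_mean if receiving == projecting else self.between_mean

    def to_json(self) -> dict:
        return {
            "clusters": [[l, s] for l, s in self.clusters],
            "within_mean": self.within_mean,
            "between_mean": self.between_mean,
            "strength_levels": list(self.strength_levels),
            "flip_rate": self.flip_rate,
            "asymmetry": self.asymmetry,
            "seed": self.seed,
            "block_means": self.block_means,
        }


def _mixture_draw(mean: float, levels: tuple, u: float) -> float:
    """Two-point mixture of the adjacent vocabulary levels bracketing
    ``mean``; the expectation equals ``mean`` exactly."""
    lo, hi = levels[0], levels[-1]
    if not lo <= mean <= hi:
        raise MatrixError(
            f"block mean {mean} not representable with levels {levels}"
        )
    import bisect

    j = bisect.bisect_left(levels, mean)
    if levels[j] == mean:
        return float(levels[j])
    L, U = levels[j - 1], levels[j]
    p = (mean - L) / (U - L)
    return float(U) if u < p else float(L)


def _perturb_one_level(v: float, levels: tuple, rng: np.random.Generator) -> float:
    """Move a value one vocabulary step; the step direction is drawn so the
    perturbation is mean-preserving away from the vocabulary boundaries."""
    i = levels.index(v)
    if i == 0:
        return float(levels[1])
    if i == len(levels) - 1:
        return float(levels[-2])
    up, down = levels[i + 1] - v, v - levels[i - 1]
    q = down / (up + down)  # E[shift] = q*up - (1-q)*down = 0
    return float(levels[i + 1]) if rng.random() < q else float(levels[i - 1])


def generate_planted_matrix(spec: PlantedSpec) -> tuple[ConnectivityMatrix, ClusterAssignment]:
    """Draw a square ordinal matrix with the planted block structure.

    The premise of the cluster analysis is that areas of the same cluster
    share inputs, so the generator plants *profile coherence*: for every
    (source area, receiving cluster) pair one two-point mixture of the
    adjacent vocabulary levels bracketing the block mean is drawn and
    written into the columns of all member areas.  At ``flip_rate = 0``
    same-cluster columns therefore agree up to the asymmetry perturbation,
    while different clusters differ through their block means and through
    independent draws.  Reciprocity lives at the block level (both
    directions of a cluster pair carry positive, generally unequal,
    means); the asymmetry perturbation then moves one member of a
    reciprocal cell pair one vocabulary step (mean-preserving away from
    the boundaries), so reciprocal connections are often of different
    strength.  Flip noise finally resamples each cell uniformly from the
    vocabulary with probability ``flip_rate``.  The diagonal carries
    structural zeros.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed))
    areas: list[str] = []
    assign: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for label, size in spec.clusters:
        ids = spec.areas.get(label)
        if ids is None:
            ids = [f"{label}_{i + 1}" for i in range(size)]
        elif len(ids) != size:
            raise MatrixError(f"cluster {label!r}: {len(ids)} ids for size {size}")
        for a in ids:
            assign[a] = label
        members[label] = list(ids)
        areas.extend(ids)
    if len(set(areas)) != len(areas):
        raise MatrixError("area ids must be unique across clusters")

    n = len(areas)
    pos = {a: i for i, a in enumerate(areas)}
    levels = spec.strength_levels
    vals = np.zeros((n, n))
    # shared draw per (source, receiving cluster): plants profile coherence
    for recv_label, _ in spec.clusters:
        for s in areas:
            u = rng.random()
            mean = spec.block_mean(recv_label, assign[s])
            v = _mixture_draw(mean, levels, u)
            for t in members[recv_label]:
                if t != s:
                    vals[pos[s], pos[t]] = v
    # asymmetry: a reciprocal pair differs by one vocabulary step
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < spec.asymmetry:
                if rng.random() < 0.5:
                    vals[i, j] = _perturb_one_level(vals[i, j], levels, rng)
                else:
                    vals[j, i] = _perturb_one_level(vals[j, i], levels, rng)
    if spec.flip_rate > 0:
        off = ~np.eye(n, dtype=bool)
        flips = (rng.random((n, n)) < spec.flip_rate) & off
        vals[flips] = rng.choice(levels, size=int(flips.sum()))

    canonical = tuple(levels) == CANONICAL_LEVELS
    matrix = ConnectivityMatrix(
        pd.DataFrame(vals, index=areas, columns=areas), canonical=canonical
    )
    return matrix, ClusterAssignment(assign)


def _fixture_spec(
    side: str,
    seed: int,
    registry: AreaRegistry,
    flip_rate: float,
    asymmetry: float,
) -> PlantedSpec:
    if side not in FIXTURE_SIDES:
        raise MatrixError(f"side must be one of {FIXTURE_SIDES}")
    if side == "full":
        ids = [a.id for a in registry.areas]
        assign = registry.reference_assignment(ids)
    elif side in ("parietal", "frontal"):
        ids = registry.ids(lobe=side)
        assign = registry.reference_assignment(ids)
    else:  # SPL_IPL: intrinsic parietal partition
        ids = registry.ids(lobe="parietal")
        assign = registry.reference_assignment(ids)
        assign.update(
            {a: c for a, c in SPL_IPL_REASSIGNMENT.items() if a in assign}
        )
    order: list[str] = []
    for a in ids:
        if assign[a] not in order:
            order.append(assign[a])
    clusters = [(label, sum(1 for a in ids if assign[a] == label)) for label in order]
    areas = {label: [a for a in ids if assign[a] == label] for label in order}
    block_means = {
        r: {p: v for p, v in row.items() if r in order and p in order}
        for r, row in PUBLISHED_BLOCK_MEANS.items()
        if r in order
    }
    return PlantedSpec(
        clusters=clusters,
        areas=areas,
        block_means=block_means,
        flip_rate=flip_rate,
        asymmetry=asymmetry,
        seed=seed,
    )


def macaque_fixture(
    side: str,
    seed: int = 0,
    *,
    registry: AreaRegistry | None = None,
    flip_rate: float = 0.0,
    asymmetry: float = 0.3,
) -> tuple[ConnectivityMatrix, ClusterAssignment]:
    """Synthetic matrix shaped like the published analysis.

    Modes: ``parietal`` (18 target areas, 5 planted clusters), ``frontal``
    (37 areas, 6 clusters), ``SPL_IPL`` (18 areas, 5 clusters under the
    intrinsic-parietal membership, with MIP in pmSPL and PEa in aSPL) and
    ``full`` (all 55 areas, 11 clusters).  Block means come from the
    published inter-cluster mean-input values where printed, with local
    (within-cluster) input 50 and a weak background of 5 elsewhere.
    """
    registry = registry if registry is not None else load_registry()
    spec = _fixture_spec(side, seed, registry, flip_rate, asymmetry)
    return generate_planted_matrix(spec)


def write_fixture(
    outdir,
    name: str,
    matrix: ConnectivityMatrix,
    assignment: ClusterAssignment,
    spec: PlantedSpec | None = None,
    extra: dict | None = None,
) -> dict[str, Path]:
    """Emit a fixture as matrix CSV + assignment CSV + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{name}_matrix.csv",
        "assignment": outdir / f"{name}_clusters.csv",
        "meta": outdir / f"{name}_meta.json",
    }
    write_matrix(matrix, paths["matrix"])
    assignment.to_csv(paths["assignment"])
    meta = {"name": name, "synthetic": True}
    if spec is not None:
        meta["spec"] = spec.to_json()
    if extra:
        meta.update(extra)
    paths["meta"].write_text(json.dumps(meta, indent=2) + "\n")
    return paths
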