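#!/usr/bin/env python
"""Cluster input profiles: mean inter-cluster strengths and entropies.

For each fixture, computes every cluster's mean input from every other
cluster (the numbers a spider plot would display, 0-100 scale), the
entropy (nats) of each input distribution, and the weighted cluster graph
(the arrow-diagram edge list), under results/profiles/<side>/.
"""

from pathlib import Path

import numpy as np

from pfclust.matrix import load_matrix
from pfclust.profiles import ClusterAssignment, cluster_graph, profile_all, profiles_frame

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for side in ("parietal", "frontal", "SPL_IPL", "full"):
        matrix = load_matrix(ROOT / "fixtures" / f"{side}_matrix.csv")
        assignment = ClusterAssignment.from_csv(
            ROOT / "fixtures" / f"{side}_clusters.csv"
        )
        profiles = profile_all(matrix, assignment)
        outdir = ROOT / "profiles" / side
        outdir.mkdir(parents=True, exist_ok=True)
        profiles_frame(profiles).to_csv(outdir / "profiles.csv", index=False)
        cluster_graph(matrix, assignment).to_csv(
            outdir / "cluster_graph.csv", index=False
        )
        ents = {p.receiving: p.H for p in profiles}
        mean_h = float(np.mean(list(ents.values())))
        hi = max(ents, key=ents.get)
        lo = min(ents, key=ents.get)
        print(
            f"{side}: mean entropy {mean_h:.2f} nats; "
            f"highest {hi} ({ents[hi]:.2f}), lowest {lo} ({ents[lo]:.2f})"
        )


if __name__ == "__main__":
    main()
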