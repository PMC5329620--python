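#!/usr/bin/env python
"""Bootstrap candidate-tree search on each fixture.

For every fixture written by 01_simulate_fixtures.py, resamples the matrix
rows, builds one agglomerative topology per resample (plus the original),
refits all branch lengths against the original distances by nonnegative
least squares, and stores the ML tree and the per-tree fit statistics
under results/trees/<side>/.  A reduced bootstrap depth (2,000) keeps the
driver quick; the ensemble-size bookkeeping is identical at any depth.
"""

import json
from pathlib import Path

from pfclust.matrix import load_matrix
from pfclust.trees import candidate_search

SEED = 777
N_BOOTSTRAP = 2_000
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for side in ("parietal", "frontal", "SPL_IPL", "full"):
        matrix = load_matrix(ROOT / "fixtures" / f"{side}_matrix.csv")
        ensemble = candidate_search(matrix, n_bootstrap=N_BOOTSTRAP, seed=SEED)
        outdir = ROOT / "trees" / side
        outdir.mkdir(parents=True, exist_ok=True)
        best = ensemble.best
        (outdir / "ml_tree.nwk").write_text(
            best.topology.to_newick(branch_lengths=best.branch_lengths) + "\n"
        )
        (outdir / "ensemble.json").write_text(
            json.dumps(ensemble.summary(max_trees=100), indent=2) + "\n"
        )
        print(
            f"{side}: {len(ensemble)} candidate trees fitted; "
            f"best loglik {best.loglik:.2f} (sse {best.sse:.1f})"
        )


if __name__ == "__main__":
    main()
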