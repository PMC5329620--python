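#!/usr/bin/env python
"""Generate the synthetic planted-cluster fixtures used by the analysis.

Writes, for each mode (parietal 18 areas / frontal 37 / intrinsic SPL-IPL
18 / full 55), the connectivity matrix, the planted cluster assignment and
a JSON sidecar recording the generator settings, under results/fixtures/.
"""

from pathlib import Path

from pfclust.synthetic import FIXTURE_SIDES, macaque_fixture, write_fixture

SEED = 777  # fixture generation seed for the whole analysis
OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    for side in FIXTURE_SIDES:
        matrix, assignment = macaque_fixture(side, seed=SEED)
        paths = write_fixture(
            OUT, side, matrix, assignment,
            extra={"side": side, "seed": SEED, "flip_rate": 0.0},
        )
        print(
            f"{side}: {len(matrix.targets)} areas, "
            f"{len(assignment.clusters)} planted clusters -> {paths['matrix']}"
        )


if __name__ == "__main__":
    main()
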