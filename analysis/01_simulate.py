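#!/usr/bin/env python
"""Materialize a synthetic study workspace under the study's default
conditions (28 case families with 5 sibling pairs, 11 biobank controls,
bimodal function-score regimes, case-region variant placement).

The workspace (FASTA, score/cohort/phenotype/expression/PSI tables) is
written to scratch/workspace; downstream numbered scripts consume it and
write their result tables under results/analysis.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
WORKSPACE = ROOT / "scratch" / "workspace"
OUTDIR = ROOT / "results" / "analysis"
SEED = 1


def main() -> None:
    from rnu4kit.pipeline import Pipeline
    from rnu4kit.simulate import SimulationConfig

    pipe = Pipeline(WORKSPACE, OUTDIR, seed=SEED)
    paths = pipe.simulate(SimulationConfig(seed=SEED))["paths"]
    pipe.save_manifest()
    print(f"workspace written to {WORKSPACE} (seed {SEED}):")
    for name, p in sorted(paths.items()):
        print(f"  {name:28s} {p.stat().st_size:>8d} bytes")


if __name__ == "__main__":
    sys.exit(main())
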