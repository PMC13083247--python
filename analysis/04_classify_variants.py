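#!/usr/bin/env python
"""Run the specialized ACMG engine over every unique cohort variant
(rarity, functional-score, hotspot, in-trans, paralog-equivalence and
expression-signature evidence) and stratify individuals by their biallelic
classification status.

Writes acmg_assessments.tsv, biallelic_status.tsv and
biallelic_status_summary.tsv under results/analysis.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from rnu4kit.pipeline import Pipeline

    pipe = Pipeline(ROOT / "scratch" / "workspace", ROOT / "results" / "analysis", seed=1)
    out = pipe.classify()
    pipe.save_manifest()
    per_variant = out["per_variant"]
    counts = per_variant["classification"].value_counts()
    print("per-variant classifications:")
    for cls, n in counts.items():
        print(f"  {cls:20s} {n:3d} ({100 * n / len(per_variant):.1f}%)")
    print("per-individual biallelic status:")
    for _, row in out["summary"].iterrows():
        print(f"  {row['status']:10s} {row['n']:3d} ({row['percent']:.1f}%)")


if __name__ == "__main__":
    sys.exit(main())
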