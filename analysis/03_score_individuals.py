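#!/usr/bin/env python
"""Per-individual mean function scores, the -0.15 inclusion threshold, and
the case/control comparison of mean scores (sibling-deduplicated two-sided
Mann-Whitney U test).

Writes inclusion.tsv under results/analysis and prints group means, the
test result and the inclusion tally.
"""

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from rnu4kit.pipeline import Pipeline
    from rnu4kit.sge import compare_mean_scores, dedup_sibling_records

    pipe = Pipeline(ROOT / "scratch" / "workspace", ROOT / "results" / "analysis", seed=1)
    out = pipe.score()
    pipe.save_manifest()
    inc = out["inclusion"]
    records = dedup_sibling_records(out["records"])
    kept = {r.individual_id for r in records}
    sub = inc[inc["individual"].isin(kept)].dropna(subset=["mean_score"])
    cases = sub.loc[sub["cohort"] == "case", "mean_score"]
    controls = sub.loc[sub["cohort"] != "case", "mean_score"]
    res = compare_mean_scores(cases, controls)
    print(f"mean score, cases:    {res['mean_a']:.3f} (n={res['n_a']})")
    print(f"mean score, controls: {res['mean_b']:.3f} (n={res['n_b']})")
    print(f"two-sided Mann-Whitney U={res['U']:.0f}, p={res['p']:.2e} ({res['method']})")
    tally = inc["status"].value_counts().to_dict()
    print(f"inclusion at mean < -0.15: {tally}")


if __name__ == "__main__":
    sys.exit(main())
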