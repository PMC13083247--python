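"""Saturation-genome-editing (SGE) function scores and biallelic aggregation.

An SGE assay assigns every single-nucleotide variant of the gene a function
score measuring depletion of edited cells; scores below a significance
threshold (default -0.302) indicate the variant compromises snRNA function.
Indels are not assayed directly: a deletion's score is inferred as the mean
score of all SNVs within the deleted nucleotides, and an insertion's as the
mean over SNVs at the two positions directly flanking the insertion point.
Deletion-insertions and duplications follow the deletion rule (mean over
affected reference positions) and are flagged as inferred.

Per-individual analysis averages the two allele scores; individuals whose
mean falls below a strict inclusion threshold (default -0.15) are considered
to carry functionally relevant biallelic genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import GenotypeRecord, Variant

SIGNIFICANCE_THRESHOLD = -0.302
INCLUSION_THRESHOLD = -0.15


class SgeScoreTable:
    """Per-SNV function scores keyed by (position, ref, alt)."""

    def __init__(
        self,
        entries: Mapping[tuple[int, str, str], float],
        significance_threshold: float = SIGNIFICANCE_THRESHOLD,
    ) -> None:
        self.entries = {
            (int(p), r.upper(), a.upper()): float(s) for (p, r, a), s in entries.items()
        }
        per_pos: dict[int, int] = {}
        for (p, _, _) in self.entries:
            per_pos[p] = per_pos.get(p, 0) + 1
        too_many = [p for p, n in per_pos.items() if n > 3]
        if too_many:
            raise ValueError(f"more than 3 SNV entries at positions {sorted(too_many)}")
        self.significance_threshold = float(significance_threshold)
        self._by_pos: dict[int, list[float]] = {}
        for (p, _, _), s in self.entries.items():
            self._by_pos.setdefault(p, []).append(s)

    @classmethod
    def read_tsv(cls, path, significance_threshold: float = SIGNIFICANCE_THRESHOLD) -> "SgeScoreTable":
        df = pd.read_csv(path, sep="\t")
        required = {"position", "ref", "alt", "function_score"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        entries = {
            (int(r.position), str(r.ref), str(r.alt)): float(r.function_score)
            for r in df.itertuples()
        }
        return cls(entries, significance_threshold)

    def to_tsv(self, path) -> None:
        rows = [
            {"position": p, "ref": r, "alt": a, "function_score": s}
            for (p, r, a), s in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def lookup(self, pos: int, ref: str, alt: str) -> Optional[float]:
        return self.entries.get((pos, ref.upper(), alt.upper()))

    def scores_at(self, pos: int) -> list[float]:
        return list(self._by_pos.get(pos, []))

    def is_significant(self, score: float) -> bool:
        return score < self.significance_threshold

    def min_score_by_position(self) -> dict[int, float]:
        return {p: min(s) for p, s in self._by_pos.items()}


@dataclass(frozen=True)
class ScoredAllele:
    variant: Variant
    score: Optional[float]
    provenance: str  # measured | inferred | missing
    significant: Optional[bool]
    n_constituents: int = 1  # SNVs averaged for an inferred score

    def __post_init__(self) -> None:
        if self.provenance == "inferred" and self.variant.vtype == "SNV":
            raise ValueError("SNV scores are measured, never inferred")
        if (self.score is None) != (self.significant is None):
            raise ValueError("significance defined iff score is defined")


@dataclass(frozen=True)
class InclusionPolicy:
    mean_threshold: float = INCLUSION_THRESHOLD
    dedup_siblings: bool = True


def score_variant(v: Variant, table: SgeScoreTable) -> ScoredAllele:
    """Score one allele: exact lookup for SNVs, averaging rule for indels."""
    if v.vtype == "SNV":
        s = table.lookup(v.start, v.ref_bases, v.alt_bases)
        if s is None:
            return ScoredAllele(v, None, "missing", None, 0)
        return ScoredAllele(v, s, "measured", table.is_significant(s), 1)
    if v.vtype == "insertion":
        positions = [v.start, v.end]  # the two flanking reference positions
    else:  # deletion, delins, duplication: affected reference positions
        positions = list(range(v.start, v.end + 1))
    constituent = [s for p in positions for s in table.scores_at(p)]
    if not constituent:
        return ScoredAllele(v, None, "missing", None, 0)
    mean = float(np.mean(constituent))
    return ScoredAllele(v, mean, "inferred", table.is_significant(mean), len(constituent))


def individual_mean_score(
    rec: GenotypeRecord, table: SgeScoreTable
) -> tuple[Optional[float], str]:
    """Mean SGE score across an individual's two alleles.

    Returns ``(mean, reason)``; the mean is None with reason "unscored
    allele" when either allele has no measured or inferable score.
    """
    scored = [score_variant(a, table) for a in rec.alleles]
    if any(s.score is None for s in scored):
        return None, "unscored allele"
    return float(np.mean([s.score for s in scored])), "ok"


def dedup_sibling_records(records: Sequence[GenotypeRecord]) -> list[GenotypeRecord]:
    """Keep one individual per sibling group: the lexicographically first id.

    Individuals without a sibling group are always kept.
    """
    keep: dict[str, GenotypeRecord] = {}
    singles: list[GenotypeRecord] = []
    for rec in records:
        if rec.sibling_group is None:
            singles.append(rec)
        else:
            cur = keep.get(rec.sibling_group)
            if cur is None or rec.individual_id < cur.individual_id:
                keep[rec.sibling_group] = rec
    return singles + list(keep.values())


def inclusion_filter(
    records: Sequence[GenotypeRecord],
    table: SgeScoreTable,
    policy: InclusionPolicy = InclusionPolicy(),
) -> pd.DataFrame:
    """Per-individual mean scores with strict-threshold inclusion status.

    Individuals are ``included`` iff their mean score is strictly below the
    policy threshold, ``excluded`` otherwise; ``unscoreable`` individuals
    (an allele with no score) are reported separately.
    """
    rows = []
    for rec in records:
        mean, reason = individual_mean_score(rec, table)
        if mean is None:
            status = "unscoreable"
        elif mean < policy.mean_threshold:
            status = "included"
        else:
            status = "excluded"
        rows.append(
            {
                "individual": rec.individual_id,
                "cohort": rec.cohort,
                "sibling_group": rec.sibling_group or "",
                "mean_score": mean if mean is not None else np.nan,
                "status": status,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows).sort_values("individual", ignore_index=True)


def compare_mean_scores(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_n_cutoff: int = 25,
) -> dict:
    """Two-sided Mann-Whitney U comparison of per-individual mean scores.

    Uses the exact null distribution when the combined sample size is at
    most ``exact_n_cutoff`` and the data are tie-free; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= exact_n_cutoff and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "method": method,
    }


def validate_indel_inference(
    table: SgeScoreTable,
    measured_indels: Mapping[Variant, float],
) -> pd.DataFrame:
    """Spearman correlation of measured vs inferred indel scores, per class.

    ``measured_indels`` maps indel variants (insertions/deletions) to their
    experimentally measured scores; each is re-scored through the inference
    rule and the two score sets are rank-correlated.  Also counts threshold
    crossings: indels whose inferred and measured scores fall on opposite
    sides of the significance threshold.
    """
    by_class: dict[str, list[tuple[float, float]]] = {}
    for v, measured in measured_indels.items():
        inferred = score_variant(v, table)
        if inferred.score is None:
            continue
        key = "insertion" if v.vtype == "insertion" else "deletion"
        by_class.setdefault(key, []).append((float(measured), inferred.score))
    rows = []
    thr = table.significance_threshold
    for cls, pairs in sorted(by_class.items()):
        if len(pairs) < 3:
            raise ValueError(f"fewer than 3 scoreable {cls}s; cannot rank-correlate")
        m = np.array([p[0] for p in pairs])
        i = np.array([p[1] for p in pairs])
        rho, p = stats.spearmanr(m, i)
        crossings = int(np.sum((m < thr) != (i < thr)))
        rows.append(
            {"class": cls, "n": len(pairs), "spearman_rho": float(rho),
             "p": float(p), "threshold_crossings": crossings}
        )
    return pd.DataFrame(rows)
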