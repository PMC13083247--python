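"""Specialized ACMG/AMP evidence engine for recessive snRNA variants.

The engine evaluates six criteria tailored to a noncoding snRNA gene with a
saturation functional assay and a well-characterized paralog:

* ``PM2_supporting`` - rarity in a population biobank (allele frequency
  below 0.1% and, by default, no homozygotes).
* ``PS3_supporting`` - a significant functional-assay score; the strength is
  capped at supporting because the assay lacks benchmarked pathogenic and
  benign truth sets for the recessive disorder.
* ``PM1`` - location in a mutational hotspot (Stem II, the k-turn or the Sm
  protein binding site).
* ``PM3`` - observation in trans with pathogenic alleles, scored with the
  ClinGen SVI point system (confirmed trans with P/LP: 1.0; phase unknown:
  0.5; homozygous: 0.5, discounted to 0.25 under consanguinity; in trans
  with a VUS: 0).  Accumulated points set the criterion strength.
* ``PM5`` - an exact pathogenic/likely pathogenic equivalent at the
  structurally aligned position of the paralog.
* ``PP4`` - a carrier with the disorder's molecular signature (loss of the
  gene's expression with upregulation of its paralog) on RNA-seq.

Criteria are combined either by the points system (supporting=1, moderate=2,
strong=4, very strong=8; VUS 0-5, likely pathogenic 6-9, pathogenic >=10) or
by categorical Richards-style combination rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import EquivalenceRecord
from .sge import ScoredAllele
from .variants import GenotypeRecord, Variant

CODES = ("PM2_supporting", "PS3_supporting", "PM1", "PM3", "PM5", "PP4")
STRENGTH_POINTS = {"supporting": 1.0, "moderate": 2.0, "strong": 4.0, "very_strong": 8.0}
FIXED_STRENGTH = {
    "PM2_supporting": "supporting",
    "PS3_supporting": "supporting",
    "PP4": "supporting",
    "PM1": "moderate",
    "PM5": "moderate",
}
PLP = ("Pathogenic", "Likely pathogenic")


class NotEvaluable:
    """Marker for a criterion whose context was not supplied."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NotEvaluable"


NOT_EVALUABLE = NotEvaluable()


@dataclass(frozen=True)
class EvidenceCriterion:
    code: str
    strength: str
    met: bool
    points: float = 0.0  # PM3 observation points; 0 for other codes
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.code not in CODES:
            raise ValueError(f"unknown criterion code {self.code!r}")
        if self.code in FIXED_STRENGTH and self.strength != FIXED_STRENGTH[self.code]:
            raise ValueError(f"{self.code} must have strength {FIXED_STRENGTH[self.code]}")
        if self.strength not in STRENGTH_POINTS:
            raise ValueError(f"unknown strength {self.strength!r}")


@dataclass(frozen=True)
class TransObservation:
    """One proband's observation of the variant against its other allele."""

    proband_id: str
    partner_class: str  # classification of the in-trans allele, or of itself if homozygous
    phase: str  # trans | unknown
    homozygous: bool = False
    consanguineous: bool = False


def default_pm3_points_table() -> dict[str, float]:
    return {
        "trans_plp": 1.0,
        "unknown_plp": 0.5,
        "homozygous": 0.5,
        "homozygous_consanguineous": 0.25,
        "trans_vus": 0.0,
    }


def default_pm3_strength_cutoffs() -> list[tuple[float, str]]:
    # descending thresholds: points >= cutoff -> strength
    return [(4.0, "very_strong"), (2.0, "strong"), (1.0, "moderate"), (0.5, "supporting")]


@dataclass
class AcmgConfig:
    af_threshold: float = 0.001
    require_zero_homozygotes: bool = True
    ps3_allow_inferred: bool = True
    pm5_require_same_alt: bool = True
    pm3_points_table: dict[str, float] = field(default_factory=default_pm3_points_table)
    pm3_strength_cutoffs: list[tuple[float, str]] = field(
        default_factory=default_pm3_strength_cutoffs
    )
    combining_mode: str = "points"  # points | categorical
    points_per_strength: dict[str, float] = field(
        default_factory=lambda: dict(STRENGTH_POINTS)
    )
    class_cutoffs: dict[str, float] = field(
        default_factory=lambda: {"Pathogenic": 10.0, "Likely pathogenic": 6.0}
    )


@dataclass(frozen=True)
class AcmgAssessment:
    variant: Variant
    criteria: tuple[EvidenceCriterion, ...]
    total_points: float
    classification: str


def pm3_strength(points: float, cfg: AcmgConfig) -> Optional[str]:
    for cutoff, strength in sorted(cfg.pm3_strength_cutoffs, reverse=True):
        if points >= cutoff:
            return strength
    return None


def evaluate_criteria(
    v: Variant,
    *,
    cfg: AcmgConfig = None,
    allele_frequency: object = NOT_EVALUABLE,
    n_homozygotes: object = NOT_EVALUABLE,
    scored: object = NOT_EVALUABLE,
    pm1_positions: object = NOT_EVALUABLE,
    equivalence: object = NOT_EVALUABLE,
    trans_observations: object = NOT_EVALUABLE,
    expression_flag: object = NOT_EVALUABLE,
) -> list[EvidenceCriterion]:
    """Evaluate all six criteria for one variant.

    Context elements left as ``NOT_EVALUABLE`` yield a criterion marked
    unmet with rationale "not evaluable" rather than silently failing.

    ``pm1_positions`` is an iterable of booleans, one per affected position,
    giving hotspot eligibility; ``equivalence`` an :class:`EquivalenceRecord`;
    ``trans_observations`` an iterable of :class:`TransObservation`;
    ``expression_flag`` whether any carrier shows the expression signature.
    """
    cfg = cfg or AcmgConfig()
    out: list[EvidenceCriterion] = []

    def not_evaluable(code: str) -> EvidenceCriterion:
        return EvidenceCriterion(
            code, FIXED_STRENGTH.get(code, "supporting"), False, 0.0, "not evaluable"
        )

    # PM2_supporting: rarity
    if allele_frequency is NOT_EVALUABLE or (
        cfg.require_zero_homozygotes and n_homozygotes is NOT_EVALUABLE
    ):
        out.append(not_evaluable("PM2_supporting"))
    else:
        rare = float(allele_frequency) < cfg.af_threshold
        no_hom = (not cfg.require_zero_homozygotes) or int(n_homozygotes) == 0
        met = rare and no_hom
        out.append(
            EvidenceCriterion(
                "PM2_supporting", "supporting", met, 0.0,
                f"AF={allele_frequency}, homozygotes={n_homozygotes}",
            )
        )

    # PS3_supporting: significant functional score
    if scored is NOT_EVALUABLE:
        out.append(not_evaluable("PS3_supporting"))
    else:
        sa: ScoredAllele = scored
        met = bool(sa.significant) and (
            sa.provenance == "measured" or cfg.ps3_allow_inferred
        )
        out.append(
            EvidenceCriterion(
                "PS3_supporting", "supporting", met, 0.0,
                f"score={sa.score}, provenance={sa.provenance}",
            )
        )

    # PM1: hotspot location
    if pm1_positions is NOT_EVALUABLE:
        out.append(not_evaluable("PM1"))
    else:
        flags = list(pm1_positions)
        out.append(
            EvidenceCriterion(
                "PM1", "moderate", any(flags), 0.0,
                f"{sum(flags)}/{len(flags)} affected positions in a hotspot",
            )
        )

    # PM3: in-trans observations, SVI points
    if trans_observations is NOT_EVALUABLE:
        out.append(not_evaluable("PM3"))
    else:
        pts = 0.0
        tbl = cfg.pm3_points_table
        for obs in trans_observations:
            if obs.homozygous:
                key = "homozygous_consanguineous" if obs.consanguineous else "homozygous"
                pts += tbl[key]
            elif obs.partner_class in PLP:
                pts += tbl["trans_plp"] if obs.phase == "trans" else tbl["unknown_plp"]
            else:
                pts += tbl["trans_vus"]
        strength = pm3_strength(pts, cfg)
        out.append(
            EvidenceCriterion(
                "PM3", strength or "supporting", strength is not None, pts,
                f"{pts} observation points",
            )
        )

    # PM5: exact paralog equivalent classified P/LP
    if equivalence is NOT_EVALUABLE:
        out.append(not_evaluable("PM5"))
    else:
        eq: Optional[EquivalenceRecord] = equivalence
        met = (
            eq is not None
            and eq.equivalent
            and eq.exact_match_classification in PLP
        )
        out.append(
            EvidenceCriterion(
                "PM5", "moderate", met, 0.0,
                f"equivalence={getattr(eq, 'exact_match_classification', None)}",
            )
        )

    # PP4: carrier with the expression signature
    if expression_flag is NOT_EVALUABLE:
        out.append(not_evaluable("PP4"))
    else:
        out.append(
            EvidenceCriterion(
                "PP4", "supporting", bool(expression_flag), 0.0,
                "RNU4-2 loss with RNU4-1 gain in a carrier",
            )
        )
    return out


def _categorical_class(met: Sequence[EvidenceCriterion]) -> str:
    """Richards-style categorical combination over met criteria."""
    n = {"supporting": 0, "moderate": 0, "strong": 0, "very_strong": 0}
    for c in met:
        n[c.strength] += 1
    vs, st, mo, su = n["very_strong"], n["strong"], n["moderate"], n["supporting"]
    pathogenic = (
        (vs >= 1 and (st >= 1 or mo >= 2 or (mo == 1 and su >= 1) or su >= 2))
        or vs >= 2
        or (st >= 2)
        or (st == 1 and (mo >= 3 or (mo >= 2 and su >= 2) or (mo >= 1 and su >= 4)))
    )
    if pathogenic:
        return "Pathogenic"
    likely = (
        (vs == 1 and mo == 1)
        or (st == 1 and 1 <= mo <= 2)
        or (st == 1 and su >= 2)
        or mo >= 3
        or (mo == 2 and su >= 2)
        or (mo == 1 and su >= 4)
    )
    return "Likely pathogenic" if likely else "VUS"


def combine_criteria(
    criteria: Iterable[EvidenceCriterion], cfg: AcmgConfig = None
) -> tuple[float, str]:
    """Combine evaluated criteria into total points and a classification."""
    cfg = cfg or AcmgConfig()
    met = [c for c in criteria if c.met]
    for c in met:
        if c.code not in CODES:
            raise ValueError(f"unknown criterion code {c.code!r}")
    total = sum(cfg.points_per_strength[c.strength] for c in met)
    if cfg.combining_mode == "points":
        if total >= cfg.class_cutoffs["Pathogenic"]:
            cls = "Pathogenic"
        elif total >= cfg.class_cutoffs["Likely pathogenic"]:
            cls = "Likely pathogenic"
        else:
            cls = "VUS"
    elif cfg.combining_mode == "categorical":
        cls = _categorical_class(met)
    else:
        raise ValueError(f"unknown combining mode {cfg.combining_mode!r}")
    return total, cls


def assess_variant(
    v: Variant, criteria: Iterable[EvidenceCriterion], cfg: AcmgConfig = None
) -> AcmgAssessment:
    crit = tuple(criteria)
    total, cls = combine_criteria(crit, cfg)
    return AcmgAssessment(v, crit, total, cls)


def classify_cohort(
    records: Sequence[GenotypeRecord],
    assessments: Mapping[str, AcmgAssessment],
) -> pd.DataFrame:
    """Per-individual biallelic classification status and cohort summary.

    ``assessments`` is keyed by normalized hgvs_n.  Status is ``both-P/LP``
    when both alleles classify pathogenic or likely pathogenic, ``one-P/LP``
    when exactly one does, ``both-VUS`` otherwise.
    """
    rows = []
    for rec in records:
        classes = []
        for allele in rec.alleles:
            a = assessments.get(allele.hgvs_n)
            if a is None:
                raise ValueError(f"no assessment for allele {allele.hgvs_n}")
            classes.append(a.classification)
        n_plp = sum(c in PLP for c in classes)
        status = {2: "both-P/LP", 1: "one-P/LP", 0: "both-VUS"}[n_plp]
        rows.append(
            {
                "individual": rec.individual_id,
                "allele1_class": classes[0],
                "allele2_class": classes[1],
                "status": status,
            }
        )
    df = pd.DataFrame(rows)
    return df


def cohort_status_summary(per_individual: pd.DataFrame) -> pd.DataFrame:
    counts = per_individual["status"].value_counts()
    total = int(counts.sum())
    rows = [
        {"status": s, "n": int(counts.get(s, 0)), "percent": 100.0 * counts.get(s, 0) / total}
        for s in ("both-P/LP", "one-P/LP", "both-VUS")
    ]
    return pd.DataFrame(rows)
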