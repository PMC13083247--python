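"""ACMG criterion evaluation, combination modes and cohort stratification."""

import itertools

import pytest

from rnu4kit.acmg import (
    AcmgConfig,
    EvidenceCriterion,
    TransObservation,
    assess_variant,
    classify_cohort,
    cohort_status_summary,
    combine_criteria,
    evaluate_criteria,
    pm3_strength,
)
from rnu4kit.model import EquivalenceRecord, is_pm1_eligible
from rnu4kit.sge import ScoredAllele
from rnu4kit.variants import GenotypeRecord, parse_hgvs_loose

from oracles import acmg_class_from_counts


def snv(pos=7, ref="G", alt="C"):
    return parse_hgvs_loose(f"n.{pos}{ref}>{alt}")


def scored(value, provenance="measured", threshold=-0.302):
    v = parse_hgvs_loose("n.10_11del") if provenance == "inferred" else snv()
    sig = None if value is None else value < threshold
    return ScoredAllele(v, value, provenance if value is not None else "missing", sig,
                        0 if value is None else 1)


def full_context(model, **overrides):
    ctx = dict(
        allele_frequency=0.0005,
        n_homozygotes=0,
        scored=scored(-1.15),
        pm1_positions=[is_pm1_eligible(7, model)],
        equivalence=EquivalenceRecord(7, 10, True, True, "Pathogenic"),
        trans_observations=[],
        expression_flag=False,
    )
    ctx.update(overrides)
    return ctx


def by_code(criteria):
    return {c.code: c for c in criteria}


def test_pm2_rarity(model):
    crit = by_code(evaluate_criteria(snv(), **full_context(model)))
    assert crit["PM2_supporting"].met  # AF 0.05% with zero homozygotes
    crit = by_code(
        evaluate_criteria(snv(), **full_context(model, allele_frequency=0.002))
    )
    assert not crit["PM2_supporting"].met
    crit = by_code(evaluate_criteria(snv(), **full_context(model, n_homozygotes=2)))
    assert not crit["PM2_supporting"].met
    cfg = AcmgConfig(require_zero_homozygotes=False)
    crit = by_code(
        evaluate_criteria(snv(), cfg=cfg, **full_context(model, n_homozygotes=2))
    )
    assert crit["PM2_supporting"].met


def test_ps3_functional_score(model):
    crit = by_code(evaluate_criteria(snv(), **full_context(model)))
    assert crit["PS3_supporting"].met  # -1.15 is significantly depleted
    assert crit["PS3_supporting"].strength == "supporting"  # capped
    crit = by_code(evaluate_criteria(snv(), **full_context(model, scored=scored(-0.1))))
    assert not crit["PS3_supporting"].met
    # inferred indel scores are eligible by default but can be barred
    inf = scored(-1.0, provenance="inferred")
    crit = by_code(evaluate_criteria(snv(), **full_context(model, scored=inf)))
    assert crit["PS3_supporting"].met
    cfg = AcmgConfig(ps3_allow_inferred=False)
    crit = by_code(evaluate_criteria(snv(), cfg=cfg, **full_context(model, scored=inf)))
    assert not crit["PS3_supporting"].met


def test_pm1_hotspot(model):
    crit = by_code(evaluate_criteria(snv(7), **full_context(model)))
    assert crit["PM1"].met  # Stem II
    ctx = full_context(model, pm1_positions=[is_pm1_eligible(64, model)])
    crit = by_code(evaluate_criteria(snv(64, "A", "C"), **ctx))
    assert not crit["PM1"].met


def test_pm3_points():
    cfg = AcmgConfig()
    # in trans with a VUS scores nothing
    obs = [TransObservation("p1", "VUS", "trans")]
    crit = by_code(evaluate_criteria(snv(), trans_observations=obs))
    assert crit["PM3"].points == 0.0 and not crit["PM3"].met
    # two probands confirmed in trans with likely pathogenic alleles
    obs = [
        TransObservation("p1", "Likely pathogenic", "trans"),
        TransObservation("p2", "Likely pathogenic", "trans"),
    ]
    crit = by_code(evaluate_criteria(snv(), trans_observations=obs))
    assert crit["PM3"].points == 2.0 and crit["PM3"].strength == "strong"
    # phase-unknown halves the award; consanguineous homozygotes quarter it
    obs = [
        TransObservation("p1", "Pathogenic", "unknown"),
        TransObservation("p2", "", "trans", homozygous=True),
        TransObservation("p3", "", "trans", homozygous=True, consanguineous=True),
    ]
    crit = by_code(evaluate_criteria(snv(), trans_observations=obs))
    assert crit["PM3"].points == pytest.approx(1.25)
    assert crit["PM3"].strength == "moderate"
    assert pm3_strength(0.49, cfg) is None
    assert pm3_strength(4.0, cfg) == "very_strong"


def test_pm5_exact_paralog_match(model):
    crit = by_code(evaluate_criteria(snv(), **full_context(model)))
    assert crit["PM5"].met
    eq = EquivalenceRecord(7, 10, True, True, None)  # equivalent, unclassified
    crit = by_code(evaluate_criteria(snv(), **full_context(model, equivalence=eq)))
    assert not crit["PM5"].met
    eq = EquivalenceRecord(7, None, None, False, None)  # unmappable
    crit = by_code(evaluate_criteria(snv(), **full_context(model, equivalence=eq)))
    assert not crit["PM5"].met


def test_pp4_expression_flag(model):
    crit = by_code(evaluate_criteria(snv(), **full_context(model, expression_flag=True)))
    assert crit["PP4"].met and crit["PP4"].strength == "supporting"


def test_missing_context_is_marked_not_evaluable():
    crit = by_code(evaluate_criteria(snv()))
    for code in ("PM2_supporting", "PS3_supporting", "PM1", "PM3", "PM5", "PP4"):
        assert not crit[code].met
        assert crit[code].rationale == "not evaluable"


def crit_set(*specs):
    out = []
    for code, strength in specs:
        pts = {"supporting": 0.5, "moderate": 1.0, "strong": 2.0}.get(strength, 0.0)
        out.append(
            EvidenceCriterion(code, strength, True, pts if code == "PM3" else 0.0)
        )
    return out


def test_combine_points_mode():
    lp = crit_set(("PM1", "moderate"), ("PM5", "moderate"), ("PM3", "moderate"),
                  ("PM2_supporting", "supporting"))
    total, cls = combine_criteria(lp)
    assert (total, cls) == (7.0, "Likely pathogenic")
    assert combine_criteria([]) == (0.0, "VUS")
    p = crit_set(("PM1", "moderate"), ("PM5", "moderate"), ("PM3", "strong"),
                 ("PM2_supporting", "supporting"), ("PP4", "supporting"))
    assert combine_criteria(p) == (10.0, "Pathogenic")


def test_combine_is_permutation_invariant_and_monotone():
    base = crit_set(("PM1", "moderate"), ("PM2_supporting", "supporting"))
    import itertools as it
    results = {combine_criteria(list(perm)) for perm in it.permutations(base)}
    assert len(results) == 1
    # adding any met criterion never lowers points nor the ordinal class
    order = {"VUS": 0, "Likely pathogenic": 1, "Pathogenic": 2}
    extras = crit_set(("PM5", "moderate"), ("PP4", "supporting"), ("PM3", "strong"))
    t0, c0 = combine_criteria(base)
    for extra in extras:
        t1, c1 = combine_criteria(base + [extra])
        assert t1 >= t0 and order[c1] >= order[c0]


def test_categorical_and_points_modes_agree_on_supporting_moderate_sets():
    """Exhaustive agreement over all 64 subsets of the six codes with PM3 at
    moderate strength, checked against a hand-built truth table."""
    codes = ["PM2_supporting", "PS3_supporting", "PP4", "PM1", "PM5", "PM3"]
    strengths = dict.fromkeys(codes[:3], "supporting") | dict.fromkeys(codes[3:], "moderate")
    pts_cfg = AcmgConfig(combining_mode="points")
    cat_cfg = AcmgConfig(combining_mode="categorical")
    for mask in itertools.product([False, True], repeat=6):
        met = [
            EvidenceCriterion(c, strengths[c], True, 1.0 if c == "PM3" else 0.0)
            for c, m in zip(codes, mask)
            if m
        ]
        n_sup = sum(1 for c in met if c.strength == "supporting")
        n_mod = sum(1 for c in met if c.strength == "moderate")
        expected = acmg_class_from_counts(n_sup, n_mod)
        assert combine_criteria(met, pts_cfg)[1] == expected
        assert combine_criteria(met, cat_cfg)[1] == expected


def test_combine_rejects_unknown_mode():
    with pytest.raises(ValueError, match="combining mode"):
        combine_criteria([], AcmgConfig(combining_mode="bayesian"))


def test_classify_cohort_and_printed_percentages():
    """A 38-individual cohort with a 10 / 4 / 24 biallelic split reports
    26.3% / 10.5% / 63.2%."""
    lp = parse_hgvs_loose("n.7G>C")
    p = parse_hgvs_loose("n.120T>C")
    vus = parse_hgvs_loose("n.90A>C")
    assessments = {
        "n.7G>C": assess_variant(
            lp, crit_set(("PM1", "moderate"), ("PM5", "moderate"), ("PM3", "moderate"),
                         ("PM2_supporting", "supporting"))
        ),
        "n.120T>C": assess_variant(
            p, crit_set(("PM1", "moderate"), ("PM5", "moderate"), ("PM3", "strong"),
                        ("PM2_supporting", "supporting"), ("PP4", "supporting"))
        ),
        "n.90A>C": assess_variant(vus, []),
    }
    assert assessments["n.7G>C"].classification == "Likely pathogenic"
    assert assessments["n.120T>C"].classification == "Pathogenic"

    def rec(i, a1, a2):
        hom = a1.hgvs_n == a2.hgvs_n
        return GenotypeRecord(
            f"I{i:02d}", f"F{i:02d}", "case", a1, a2, phase="trans",
            zygosity="homozygous" if hom else "compound-het",
        )

    records = (
        [rec(i, lp, p) for i in range(10)]          # both-P/LP
        + [rec(10 + i, lp, vus) for i in range(4)]  # one-P/LP
        + [rec(14 + i, vus, vus) for i in range(24)]  # both-VUS
    )
    per_ind = classify_cohort(records, assessments)
    assert per_ind.loc[0, "status"] == "both-P/LP"
    assert per_ind.loc[10, "status"] == "one-P/LP"
    summary = cohort_status_summary(per_ind)
    pct = dict(zip(summary["status"], summary["percent"].round(1)))
    assert pct == {"both-P/LP": 26.3, "one-P/LP": 10.5, "both-VUS": 63.2}

    with pytest.raises(ValueError, match="no assessment"):
        classify_cohort(records, {"n.7G>C": assessments["n.7G>C"]})
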