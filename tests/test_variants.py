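"""HGVS n. parsing, cohort ingestion, dedup and minimal VCF conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rnu4kit.variants import (
    GenotypeRecord,
    HgvsParseError,
    ReferenceMismatchError,
    Variant,
    dedup_unique_variants,
    parse_hgvs,
    parse_hgvs_loose,
    read_cohort_table,
    read_vcf_variants,
    write_cohort_table,
)


@pytest.mark.parametrize(
    "text, vtype, start, end, ref, alt",
    [
        ("n.7G>C", "SNV", 7, 7, "G", "C"),
        ("n.7G>A", "SNV", 7, 7, "G", "A"),
        ("n.7_8insA", "insertion", 7, 8, "", "A"),
        ("n.64_65insT", "insertion", 64, 65, "", "T"),
        ("n.10_11del", "deletion", 10, 11, "", ""),
        ("n.10del", "deletion", 10, 10, "", ""),
        ("n.10_12dup", "duplication", 10, 12, "", ""),
        ("n.10_12delinsACT", "delins", 10, 12, "", "ACT"),
        ("n.120u>c", "SNV", 120, 120, "T", "C"),  # RNA alphabet, any case
    ],
)
def test_parse_hgvs_forms(text, vtype, start, end, ref, alt):
    v = parse_hgvs_loose(text)
    assert (v.vtype, v.start, v.end) == (vtype, start, end)
    if ref:
        assert v.ref_bases == ref
    if alt:
        assert v.alt_bases == alt


@pytest.mark.parametrize(
    "text",
    [
        "n.5X>Y",          # invalid bases
        "7G>C",            # missing prefix
        "n.8_7insA",       # reversed range
        "n.7_9insA",       # non-adjacent insertion flanks
        "n.7_8ins",        # insertion without bases
        "n.10_12delinsс",  # non-ACGT replacement
        "n.10_11delAGT",   # deleted bases do not span the range
        "n.7=",            # unsupported form
    ],
)
def test_parse_hgvs_rejects(text):
    with pytest.raises(HgvsParseError):
        parse_hgvs_loose(text)


def test_parse_validates_against_reference(model):
    ref7 = model.ref_base(7)
    wrong = "A" if ref7 != "A" else "C"
    with pytest.raises(ReferenceMismatchError, match=str(7)):
        parse_hgvs(f"n.7{wrong}>{'G' if wrong != 'G' else 'T'}", model)
    ok = parse_hgvs(f"n.7{ref7}>{'A' if ref7 != 'A' else 'C'}", model)
    assert ok.gene_id == model.gene_id
    with pytest.raises(ReferenceMismatchError, match="outside"):
        parse_hgvs("n.200A>C", model)
    # deletions pick up their reference bases from the model
    d = parse_hgvs("n.10_11del", model)
    assert d.ref_bases == model.sequence[9:11]


@st.composite
def hgvs_strings(draw):
    pos = draw(st.integers(1, 140))
    kind = draw(st.sampled_from(["snv", "del", "ins", "dup", "delins"]))
    bases = st.sampled_from("ACGT")
    if kind == "snv":
        ref = draw(bases)
        alt = draw(st.sampled_from([b for b in "ACGT" if b != ref]))
        return f"n.{pos}{ref}>{alt}"
    end = draw(st.integers(pos, min(pos + 3, 142)))
    if kind == "ins":
        seq = "".join(draw(st.lists(bases, min_size=1, max_size=3)))
        return f"n.{pos}_{pos + 1}ins{seq}"
    span = f"{pos}_{end}" if end > pos else f"{pos}"
    if kind == "delins":
        seq = "".join(draw(st.lists(bases, min_size=1, max_size=3)))
        return f"n.{span}delins{seq}"
    return f"n.{span}{kind}"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(hgvs_strings())
def test_parse_serialize_roundtrip(text):
    v = parse_hgvs_loose(text)
    assert v.hgvs_n == text  # generated strings are already normalized
    assert parse_hgvs_loose(v.hgvs_n) == v


def test_variant_invariants():
    with pytest.raises(ValueError):
        Variant("g", "n.5A>C", "SNV", 5, 6, "A", "C")
    with pytest.raises(ValueError):
        Variant("g", "x", "insertion", 5, 8, "", "A")
    with pytest.raises(ValueError):
        Variant("g", "x", "inversion", 5, 6)


def _mk_records(model):
    ref = model.ref_base
    def snv(pos):
        r = ref(pos)
        return f"n.{pos}{r}>{'A' if r != 'A' else 'C'}"
    rows = [
        # homozygous individual
        dict(individual="I1", family="F1", cohort="case", allele1=snv(127),
             allele2=snv(127), phase="trans", zygosity="homozygous",
             sibling_group="S1"),
        # the sibling shares the genotype
        dict(individual="I2", family="F1", cohort="case", allele1=snv(127),
             allele2=snv(127), phase="trans", zygosity="homozygous",
             sibling_group="S1"),
        # compound het carrying the same variant
        dict(individual="I3", family="F2", cohort="case", allele1=snv(127),
             allele2=snv(7), phase="trans", zygosity="compound-het",
             sibling_group=""),
        dict(individual="I4", family="F3", cohort="case", allele1=snv(30),
             allele2=snv(45), phase="unknown", zygosity="compound-het",
             sibling_group=""),
    ]
    return pd.DataFrame(rows)


def test_read_cohort_table(tmp_path, model):
    path = tmp_path / "cohort.tsv"
    _mk_records(model).to_csv(path, sep="\t", index=False)
    records = read_cohort_table(path, model)
    assert len(records) == 4
    groups = {r.sibling_group for r in records}
    assert groups == {"S1", None}
    assert records[0].zygosity == "homozygous" and records[0].phase == "trans"
    # round-trips through the writer
    out = tmp_path / "rt.tsv"
    write_cohort_table(records, out)
    assert read_cohort_table(out, model) == records


def test_cohort_table_validation(tmp_path, model):
    df = _mk_records(model)
    bad = df.copy()
    bad.loc[0, "phase"] = "cis"  # homozygous + cis is contradictory
    p = tmp_path / "bad.tsv"
    bad.to_csv(p, sep="\t", index=False)
    with pytest.raises(ValueError, match="row 2"):
        read_cohort_table(p, model)

    dup = pd.concat([df, df.iloc[[0]]])
    dup.to_csv(p, sep="\t", index=False)
    with pytest.raises(ValueError, match="duplicate individual"):
        read_cohort_table(p, model)

    df.drop(columns=["zygosity"]).to_csv(p, sep="\t", index=False)
    with pytest.raises(ValueError, match="missing columns"):
        read_cohort_table(p, model)


def test_genotype_record_invariants(model):
    a = parse_hgvs("n.10_11del", model)
    b = parse_hgvs("n.64_65insT", model)
    with pytest.raises(ValueError, match="zygosity"):
        GenotypeRecord("i", "f", "case", a, b, phase="trans", zygosity="homozygous")
    with pytest.raises(ValueError, match="trans"):
        GenotypeRecord("i", "f", "case", a, a, phase="unknown", zygosity="homozygous")


def test_dedup_unique_variants(tmp_path, model):
    records = read_cohort_table_from_df(_mk_records(model), tmp_path, model)
    unique = dedup_unique_variants(records)
    # 4 individuals carry: {127 snv} x3 genotypes, {7, 30, 45} once each
    assert len(unique) == 4
    row = unique[unique["start"] == 127].iloc[0]
    assert row["seen_homozygous"] and row["seen_compound_het"]
    assert row["n_carriers"] == 3
    assert not dedup_unique_variants([]).shape[0]


def read_cohort_table_from_df(df, tmp_path, model):
    p = tmp_path / "tmp_cohort.tsv"
    df.to_csv(p, sep="\t", index=False)
    return read_cohort_table(p, model)


def test_dedup_matches_set_oracle_and_order_invariance(tmp_path, model, rng):
    ref = model.ref_base
    rows = []
    for i in range(30):
        p1, p2 = rng.integers(1, 145, size=2)
        a1 = f"n.{p1}{ref(int(p1))}>{'A' if ref(int(p1)) != 'A' else 'C'}"
        a2 = f"n.{p2}{ref(int(p2))}>{'A' if ref(int(p2)) != 'A' else 'C'}"
        hom = a1 == a2
        rows.append(
            dict(individual=f"R{i}", family=f"RF{i}", cohort="case",
                 allele1=a1, allele2=a2 if not hom else a1,
                 phase="trans", zygosity="homozygous" if hom else "compound-het",
                 sibling_group="")
        )
    df = pd.DataFrame(rows)
    records = read_cohort_table_from_df(df, tmp_path, model)
    unique = dedup_unique_variants(records)
    expected = {h for r in records for h in (r.allele1.hgvs_n, r.allele2.hgvs_n)}
    assert set(unique["hgvs_n"]) == expected
    shuffled = dedup_unique_variants(list(reversed(records)))
    pd.testing.assert_frame_equal(unique, shuffled)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=chr12>\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def test_vcf_conversion_minus_strand(tmp_path, model):
    """A minus-strand locus maps genomic coordinates back onto n. positions
    with reverse-complemented alleles."""
    n1 = 1_000_000
    # genomic position of n.7 on the minus strand
    g7 = n1 - 7 + 1
    ref7 = model.ref_base(7)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    vcf = tmp_path / "mini.vcf"
    vcf.write_text(
        VCF_HEADER + f"chr12\t{g7}\t.\t{comp[ref7]}\t{comp['C'] if ref7 != 'C' else comp['A']}\t.\t.\t.\n"
    )
    locus = {"chrom": "chr12", "strand": "-", "n1_pos": n1}
    (v,) = read_vcf_variants(vcf, locus, model)
    assert v.start == 7 and v.ref_bases == ref7

    with pytest.raises(ValueError, match="missing 'n1_pos'"):
        read_vcf_variants(vcf, {"chrom": "chr12", "strand": "-"}, model)


def test_vcf_conversion_plus_strand(tmp_path, model):
    n1 = 500
    pos = 30
    ref = model.ref_base(pos)
    alt = "A" if ref != "A" else "C"
    vcf = tmp_path / "plus.vcf"
    vcf.write_text(VCF_HEADER.replace("chr12", "chrX") +
                   f"chrX\t{n1 + pos - 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")
    (v,) = read_vcf_variants(vcf, {"chrom": "chrX", "strand": "+", "n1_pos": n1}, model)
    assert (v.start, v.ref_bases, v.alt_bases) == (pos, ref, alt)
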