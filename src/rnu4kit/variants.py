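"""HGVS ``n.`` variant parsing and cohort genotype ingestion.

Supports the noncoding-transcript variant forms that occur in snRNA cohort
tables: substitutions (``n.7G>C``), deletions (``n.10_11del``), insertions
(``n.64_65insT``), duplications (``n.10dup``) and deletion-insertions
(``n.10_12delinsACT``).  Anything else is rejected loudly.

Cohort tables are tab-separated with one row per individual and two allele
columns; homozygous individuals carry the same allele twice so downstream
biallelic averaging needs no special case.  A minimal VCF reader converts
genomic records to ``n.`` coordinates through an explicit gene-locus config
(chromosome, strand, genomic position of n.1); conversion is refused without
one, since transcript orientation cannot be guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import SnrnaGeneModel

VALID_BASES = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

VTYPES = ("SNV", "deletion", "insertion", "duplication", "delins")


class HgvsParseError(ValueError):
    """Malformed HGVS n. description."""


class ReferenceMismatchError(ValueError):
    """Stated reference base disagrees with the gene sequence."""


@dataclass(frozen=True)
class Variant:
    """A single allele on a noncoding transcript, HGVS n. coordinates."""

    gene_id: str
    hgvs_n: str
    vtype: str
    start: int
    end: int
    ref_bases: str = ""
    alt_bases: str = ""

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.vtype == "SNV":
            if self.start != self.end or len(self.ref_bases) != 1 or len(self.alt_bases) != 1:
                raise ValueError("SNV must be a single-position substitution")
        if self.vtype == "insertion" and self.end != self.start + 1:
            raise ValueError("insertion must be flanked by two adjacent positions")


_SUB_RE = re.compile(r"^n\.(\d+)([A-Za-z])>([A-Za-z])$")
_RANGE_RE = re.compile(
    r"^n\.(\d+)(?:_(\d+))?(delins|del|dup|ins)([A-Za-z]*)$"
)


def _norm_seq(seq: str, what: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise HgvsParseError(f"invalid {what} bases {''.join(sorted(bad))!r}")
    return seq


def parse_hgvs_loose(text: str, gene_id: str = "") -> Variant:
    """Parse an HGVS n. string without reference-sequence validation."""
    text = text.strip()
    if not text.startswith("n."):
        raise HgvsParseError(f"expected 'n.' prefix in {text!r}")
    m = _SUB_RE.match(text)
    if m:
        pos = int(m.group(1))
        ref = _norm_seq(m.group(2), "reference")
        alt = _norm_seq(m.group(3), "alternate")
        return Variant(gene_id, f"n.{pos}{ref}>{alt}", "SNV", pos, pos, ref, alt)
    m = _RANGE_RE.match(text)
    if not m:
        raise HgvsParseError(f"unsupported HGVS form: {text!r}")
    start = int(m.group(1))
    end = int(m.group(2)) if m.group(2) else start
    kind, seq = m.group(3), m.group(4)
    if start > end:
        raise HgvsParseError(f"start > end in {text!r}")
    if kind == "ins":
        if end != start + 1:
            raise HgvsParseError(f"insertion flanks must be adjacent in {text!r}")
        if not seq:
            raise HgvsParseError(f"insertion requires inserted bases in {text!r}")
        alt = _norm_seq(seq, "inserted")
        return Variant(gene_id, f"n.{start}_{end}ins{alt}", "insertion", start, end, "", alt)
    if kind == "del":
        ref = _norm_seq(seq, "deleted") if seq else ""
        if ref and len(ref) != end - start + 1:
            raise HgvsParseError(f"deleted bases do not span {start}_{end} in {text!r}")
        span = f"{start}_{end}" if end > start else f"{start}"
        return Variant(gene_id, f"n.{span}del", "deletion", start, end, ref, "")
    if kind == "dup":
        ref = _norm_seq(seq, "duplicated") if seq else ""
        span = f"{start}_{end}" if end > start else f"{start}"
        return Variant(gene_id, f"n.{span}dup", "duplication", start, end, ref, ref * 2)
    if kind == "delins":
        if not seq:
            raise HgvsParseError(f"delins requires replacement bases in {text!r}")
        alt = _norm_seq(seq, "replacement")
        span = f"{start}_{end}" if end > start else f"{start}"
        return Variant(gene_id, f"n.{span}delins{alt}", "delins", start, end, "", alt)
    raise HgvsParseError(f"unsupported HGVS form: {text!r}")  # pragma: no cover


def parse_hgvs(text: str, model: Optional[SnrnaGeneModel] = None) -> Variant:
    """Parse and, when a gene model with sequence is given, validate an
    HGVS n. description against the reference."""
    v = parse_hgvs_loose(text, gene_id=model.gene_id if model else "")
    if model is None:
        return v
    if v.end > model.length or v.start < 1:
        raise ReferenceMismatchError(
            f"{v.hgvs_n}: positions outside [1, {model.length}]"
        )
    if model.sequence is not None:
        if v.vtype == "SNV":
            expected = model.ref_base(v.start)
            if v.ref_bases != expected:
                raise ReferenceMismatchError(
                    f"{v.hgvs_n}: reference base at {v.start} is {expected}, got {v.ref_bases}"
                )
        elif v.vtype in ("deletion", "duplication") and v.ref_bases:
            expected = model.sequence[v.start - 1 : v.end]
            if v.ref_bases != expected:
                raise ReferenceMismatchError(
                    f"{v.hgvs_n}: reference span {v.start}_{v.end} is {expected}, got {v.ref_bases}"
                )
        elif v.vtype in ("deletion", "duplication"):
            v = replace(v, ref_bases=model.sequence[v.start - 1 : v.end])
    return v


def serialize_hgvs(v: Variant) -> str:
    return v.hgvs_n


# -- genotype records ------------------------------------------------------

PHASES = ("trans", "cis", "unknown")
ZYGOSITIES = ("homozygous", "compound-het")


@dataclass(frozen=True)
class GenotypeRecord:
    """One individual's biallelic genotype with family and cohort context."""

    individual_id: str
    family_id: str
    cohort: str
    allele1: Variant
    allele2: Variant
    phase: str = "unknown"
    zygosity: str = "compound-het"
    inheritance1: str = "unknown"
    inheritance2: str = "unknown"
    consanguinity: bool = False
    sibling_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"invalid phase {self.phase!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        same = self.allele1.hgvs_n == self.allele2.hgvs_n
        if (self.zygosity == "homozygous") != same:
            raise ValueError(
                f"{self.individual_id}: zygosity {self.zygosity} contradicts alleles"
            )
        if self.zygosity == "homozygous" and self.phase != "trans":
            raise ValueError(
                f"{self.individual_id}: homozygous genotypes are trans by definition"
            )

    @property
    def alleles(self) -> tuple[Variant, Variant]:
        return (self.allele1, self.allele2)


REQUIRED_COHORT_COLUMNS = (
    "individual",
    "family",
    "cohort",
    "allele1",
    "allele2",
    "phase",
    "zygosity",
)


def read_cohort_table(path, model: Optional[SnrnaGeneModel] = None) -> list[GenotypeRecord]:
    """Read a per-individual genotype TSV into validated records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    records: list[GenotypeRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        ind = row["individual"]
        if ind in seen:
            raise ValueError(f"row {rownum}: duplicate individual id {ind!r}")
        seen.add(ind)
        try:
            rec = GenotypeRecord(
                individual_id=ind,
                family_id=row["family"],
                cohort=row["cohort"],
                allele1=parse_hgvs(row["allele1"], model),
                allele2=parse_hgvs(row["allele2"], model),
                phase=row["phase"],
                zygosity=row["zygosity"],
                inheritance1=row.get("inheritance1", "unknown") or "unknown",
                inheritance2=row.get("inheritance2", "unknown") or "unknown",
                consanguinity=str(row.get("consanguinity", "")).lower()
                in ("1", "true", "yes"),
                sibling_group=row.get("sibling_group") or None,
            )
        except ValueError as e:
            raise ValueError(f"row {rownum}: {e}") from e
        records.append(rec)
    return records


def write_cohort_table(records: Iterable[GenotypeRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "individual": r.individual_id,
                "family": r.family_id,
                "cohort": r.cohort,
                "allele1": r.allele1.hgvs_n,
                "allele2": r.allele2.hgvs_n,
                "phase": r.phase,
                "zygosity": r.zygosity,
                "inheritance1": r.inheritance1,
                "inheritance2": r.inheritance2,
                "consanguinity": str(r.consanguinity).lower(),
                "sibling_group": r.sibling_group or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def dedup_unique_variants(records: Iterable[GenotypeRecord]) -> pd.DataFrame:
    """Unique variants across a cohort with their genotype contexts.

    Uniqueness is by normalized ``hgvs_n`` within gene.  Each variant is
    tagged with whether it was ever seen in a homozygous genotype, ever in a
    compound-heterozygous genotype, and its carrier count.
    """
    seen: dict[tuple[str, str], dict] = {}
    for rec in records:
        for allele in rec.alleles:
            key = (allele.gene_id, allele.hgvs_n)
            entry = seen.setdefault(
                key,
                {
                    "gene": allele.gene_id,
                    "hgvs_n": allele.hgvs_n,
                    "vtype": allele.vtype,
                    "start": allele.start,
                    "seen_homozygous": False,
                    "seen_compound_het": False,
                    "carriers": set(),
                },
            )
            entry["seen_homozygous"] |= rec.zygosity == "homozygous"
            entry["seen_compound_het"] |= rec.zygosity == "compound-het"
            entry["carriers"].add(rec.individual_id)
    rows = []
    for entry in seen.values():
        entry = dict(entry)
        entry["n_carriers"] = len(entry.pop("carriers"))
        rows.append(entry)
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "hgvs_n",
            "vtype",
            "start",
            "seen_homozygous",
            "seen_compound_het",
            "n_carriers",
        ],
    )
    return df.sort_values(["gene", "start", "hgvs_n"], ignore_index=True)


# -- minimal VCF ingestion -------------------------------------------------


def read_vcf_variants(path, locus: Mapping, model: Optional[SnrnaGeneModel] = None) -> list[Variant]:
    """Convert a minimal VCF (CHROM/POS/REF/ALT) to n.-coordinate variants.

    ``locus`` must provide ``chrom``, ``strand`` ('+' or '-') and ``n1_pos``,
    the genomic coordinate of transcript position n.1.  On the minus strand
    alleles are reverse-complemented.  Only SNVs and simple indels sharing a
    leading anchor base are supported.
    """
    import pysam

    for key in ("chrom", "strand", "n1_pos"):
        if key not in locus:
            raise ValueError(f"gene-locus config missing {key!r}")
    strand = locus["strand"]
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    n1 = int(locus["n1_pos"])

    def to_n(gpos: int) -> int:
        return gpos - n1 + 1 if strand == "+" else n1 - gpos + 1

    def rc(seq: str) -> str:
        return seq.translate(_COMPLEMENT)[::-1]

    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if str(rec.chrom) != str(locus["chrom"]):
                continue
            ref = rec.ref.upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) == 1 and len(alt) == 1:
                    npos = to_n(rec.pos)
                    r, a = (ref, alt) if strand == "+" else (rc(ref), rc(alt))
                    hgvs = f"n.{npos}{r}>{a}"
                elif len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
                    # deletion of ref[1:]
                    g0, g1 = rec.pos + 1, rec.pos + len(ref) - 1
                    s, e = sorted((to_n(g0), to_n(g1)))
                    hgvs = f"n.{s}_{e}del" if e > s else f"n.{s}del"
                elif len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
                    ins = alt[1:] if strand == "+" else rc(alt[1:])
                    npos = to_n(rec.pos)
                    s = npos if strand == "+" else npos - 1
                    hgvs = f"n.{s}_{s + 1}ins{ins}"
                else:
                    raise HgvsParseError(
                        f"unsupported VCF allele {rec.chrom}:{rec.pos} {ref}>{alt}"
                    )
                out.append(parse_hgvs(hgvs, model))
    return out
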