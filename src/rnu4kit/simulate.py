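"""Seeded synthetic data with the statistical structure of the study cohort.

Everything the pipeline consumes can be generated here: a gene model with a
random reference sequence honoring the packaged region layout, a paralog
with identical bases inside the structural alignment blocks, an SGE score
table with region-dependent score regimes, a case/control cohort (sibling
pairs, consanguineous homozygous families, compound heterozygotes), a
population allele-frequency reference, phenotype matrices for the case
cohort and a dominant-disorder comparison cohort, expression TPM tables and
a PSI splice-signature table.

Default parameters are the study conditions: per-individual mean function
scores centered at -0.525 (cases) and -0.076 (biobank controls), case
variants concentrated in Stem II / the k-turn and 5' stem loop / the Sm
site, control variants concentrated in the 3' stem loop, clinical term
frequencies at the case-cohort rates, and expression group means at the
observed TPM values (e.g. control 1645/346, biallelic 314/1952 for
RNU4-2/RNU4-1).  Because the case and control score regimes genuinely
overlap in their tails, separation of the two regimes is distributional,
not pointwise; see the methods note.

All randomness flows from one integer seed through ``numpy``'s Generator;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionTable, SpliceSignature
from .model import (
    ParalogAlignment,
    SnrnaGeneModel,
    default_alignment,
    default_model,
    load_default_config,
)
from .phenotypes import PhenotypeMatrix
from .sge import SgeScoreTable, individual_mean_score
from .variants import GenotypeRecord, Variant, parse_hgvs, write_cohort_table

BASES = np.array(list("ACGT"))

# Case-cohort clinical term frequencies (fraction of individuals with known
# status in whom the term is present).
DEFAULT_PHENOTYPE_FREQUENCIES: dict[str, float] = {
    "GDD": 1.00,
    "ID": 1.00,
    "impaired_language": 1.00,
    "gross_motor_delay": 0.933,
    "brain_mri_abnormality": 0.889,
    "white_matter_abnormality": 0.778,
    "dilated_perivascular_spaces": 0.783,
    "corpus_callosum_abnormality": 0.524,
    "cerebellar_atrophy": 0.500,
    "hypotonia": 0.839,
    "dysmorphic_facial_features": 0.800,
    "eye_abnormality": 0.774,
    "strabismus": 0.536,
    "seizure": 0.613,
    "behavioral_abnormality": 0.609,
    "spasticity": 0.467,
    "integument_abnormality": 0.607,
    "microcephaly": 0.433,
    "feeding_difficulties": 0.480,
    "short_stature": 0.433,
    "movement_abnormality": 0.433,
    "dental_anomalies": 0.423,
    "genitalia_abnormality": 0.310,
    "skeletal_abnormality": 0.300,
    "endocrine_anomalies": 0.310,
    "autism_spectrum_disorder": 0.286,
    "failure_to_thrive": 0.269,
}

# Dominant-disorder comparison cohort: similar neurodevelopmental core but
# without the recessive disorder's white-matter/cerebellar signature.
DEFAULT_RENU_FREQUENCIES: dict[str, float] = {
    **DEFAULT_PHENOTYPE_FREQUENCIES,
    "dilated_perivascular_spaces": 0.08,
    "cerebellar_atrophy": 0.05,
    "white_matter_abnormality": 0.500,
    "eye_abnormality": 0.625,
    "skeletal_abnormality": 0.438,
    "seizure": 0.644,
}

DEFAULT_EXPRESSION_MEANS: dict[str, dict[str, float]] = {
    "control": {"RNU4-2": 1645.0, "RNU4-1": 346.0},
    "biallelic": {"RNU4-2": 314.0, "RNU4-1": 1952.0},
    "ReNU": {"RNU4-2": 2699.0, "RNU4-1": 346.0},
    "het-SGE-significant": {"RNU4-2": 420.0, "RNU4-1": 346.0},
}

DEFAULT_CASE_REGION_WEIGHTS = {
    "Stem II": 0.25,
    "5' stem loop": 0.45,
    "Sm protein": 0.20,
    "terminal stem loop": 0.10,
}

DEFAULT_CONTROL_REGION_WEIGHTS = {
    "3' stem loop": 0.50,
    "Stem I": 0.20,
    "t-loop": 0.15,
    "Stem III": 0.15,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_case_families: int = 28
    n_sibling_pairs: int = 5
    n_controls: int = 11
    consanguinity_rate: float = 5 / 28
    homozygous_rate: float = 0.25  # non-consanguineous families
    control_homozygous_rate: float = 5 / 11
    indel_rate: float = 0.10  # case alleles that are short indels
    case_score_mean: float = -0.525
    case_score_sd: float = 0.30
    control_score_mean: float = -0.076
    control_score_sd: float = 0.10
    score_bounds: tuple[float, float] = (-3.0, 1.0)
    case_region_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CASE_REGION_WEIGHTS)
    )
    control_region_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_REGION_WEIGHTS)
    )
    phenotype_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_FREQUENCIES)
    )
    renu_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RENU_FREQUENCIES)
    )
    n_renu: int = 178
    missingness_rate: float = 0.15
    expression_group_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_EXPRESSION_MEANS.items()}
    )
    expression_group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "biallelic": 3,
            "ReNU": 11,
            "het-SGE-significant": 3,
            "control": 20,
        }
    )
    expression_log_sd: float = 0.25  # natural-log sd of TPM draws
    psi_shift: float = 0.10
    psi_noise_sd: float = 0.03
    n_events: int = 101
    n_psi_controls: int = 20
    n_psi_renu: int = 19
    paralog_plp_rate: float = 0.3  # mapped positions with a classified paralog variant

    def __post_init__(self) -> None:
        for name in ("case_region_weights", "control_region_weights"):
            w = getattr(self, name)
            if any(x < 0 for x in w.values()) or sum(w.values()) <= 0:
                raise ValueError(f"{name} must be nonnegative and normalizable")
        for name in ("consanguinity_rate", "missingness_rate", "indel_rate"):
            x = getattr(self, name)
            if not 0 <= x <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticGene:
    model: SnrnaGeneModel
    paralog_model: SnrnaGeneModel
    alignment: ParalogAlignment
    scores: SgeScoreTable
    paralog_table: pd.DataFrame  # classified paralog variants (ClinVar-style)
    functional_positions: set[int]


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are loose, so cheap)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _region_positions(model: SnrnaGeneModel, names: Sequence[str]) -> dict[str, list[int]]:
    spans = {r.name: list(range(r.start, r.end + 1)) for r in model.regions}
    missing = [n for n in names if n not in spans]
    if missing:
        raise ValueError(f"unknown region names {missing}")
    return {n: spans[n] for n in names}


def generate_gene_and_scores(
    cfg: SimulationConfig, sequence: Optional[str] = None
) -> SyntheticGene:
    """Gene + paralog models, SGE score table and classified paralog variants.

    The reference sequence is random unless supplied; the paralog carries
    identical bases inside the alignment blocks so position equivalence is
    exercisable.  Every position gets 3 SNV scores, drawn from the case
    regime in the functional (case-weighted) regions and from the control
    regime elsewhere.
    """
    rng = np.random.default_rng(cfg.seed)
    base_cfg = load_default_config()
    length = int(base_cfg["length"])
    if sequence is None:
        sequence = "".join(rng.choice(BASES, size=length))
    model = default_model(sequence=sequence)
    aln_cfg = base_cfg["paralog_alignment"]
    target_len = int(aln_cfg.get("target_length", 130))
    target = list(rng.choice(BASES, size=target_len))
    for s0, s1, d0, d1 in aln_cfg["blocks"]:
        for off in range(s1 - s0 + 1):
            target[d0 - 1 + off] = sequence[s0 - 1 + off]
    target_seq = "".join(target)
    paralog_model = SnrnaGeneModel(
        gene_id=aln_cfg["target_gene"],
        length=target_len,
        regions=[],
        sequence=target_seq,
    )
    alignment = default_alignment(source_sequence=sequence, target_sequence=target_seq)

    functional = set()
    for positions in _region_positions(model, cfg.case_region_weights).values():
        functional.update(positions)
    lo, hi = cfg.score_bounds
    entries: dict[tuple[int, str, str], float] = {}
    for pos in range(1, length + 1):
        ref = sequence[pos - 1]
        mean, sd = (
            (cfg.case_score_mean, cfg.case_score_sd)
            if pos in functional
            else (cfg.control_score_mean, cfg.control_score_sd)
        )
        alts = [b for b in "ACGT" if b != ref]
        draws = _truncnorm(rng, mean, sd, lo, hi, len(alts))
        for alt, s in zip(alts, draws):
            entries[(pos, ref, alt)] = float(s)
    scores = SgeScoreTable(entries, base_cfg["thresholds"]["sge_significance"])

    # classified paralog variants at a subset of mapped functional positions
    rows = []
    for s0, s1, d0, d1 in alignment.blocks:
        for pos in range(s0, s1 + 1):
            if pos not in functional or rng.random() > cfg.paralog_plp_rate:
                continue
            mapped = d0 + (pos - s0)
            ref = target_seq[mapped - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            cls = rng.choice(["Pathogenic", "Likely pathogenic"], p=[0.4, 0.6])
            rows.append(
                {
                    "gene": alignment.target_gene,
                    "hgvs_n": f"n.{mapped}{ref}>{alt}",
                    "classification": cls,
                }
            )
    paralog_table = pd.DataFrame(rows, columns=["gene", "hgvs_n", "classification"])
    return SyntheticGene(model, paralog_model, alignment, scores, paralog_table, functional)


def _draw_position(rng, model, weights: dict[str, float]) -> int:
    names = list(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    w /= w.sum()
    region = names[rng.choice(len(names), p=w)]
    positions = _region_positions(model, [region])[region]
    return int(positions[rng.integers(len(positions))])


def _draw_snv(rng, model: SnrnaGeneModel, weights) -> Variant:
    pos = _draw_position(rng, model, weights)
    ref = model.ref_base(pos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return parse_hgvs(f"n.{pos}{ref}>{alt}", model)


def _draw_case_allele(rng, model, cfg) -> Variant:
    if rng.random() < cfg.indel_rate:
        pos = _draw_position(rng, model, cfg.case_region_weights)
        pos = min(pos, model.length - 1)
        if rng.random() < 0.5:
            return parse_hgvs(f"n.{pos}_{pos + 1}del", model)
        ins = str(rng.choice(BASES))
        return parse_hgvs(f"n.{pos}_{pos + 1}ins{ins}", model)
    return _draw_snv(rng, model, cfg.case_region_weights)


def generate_cohort(
    cfg: SimulationConfig, gene: SyntheticGene
) -> tuple[list[GenotypeRecord], pd.DataFrame]:
    """Case families (with sibling pairs and consanguineous homozygotes) and
    biobank-style controls, plus a truth table for recovery experiments."""
    rng = np.random.default_rng(cfg.seed + 1)
    model = gene.model
    records: list[GenotypeRecord] = []
    truth_rows = []
    counter = 0

    def add(rec: GenotypeRecord, group: str) -> None:
        mean, _ = individual_mean_score(rec, gene.scores)
        records.append(rec)
        truth_rows.append(
            {
                "individual": rec.individual_id,
                "true_group": group,
                "true_mean_score": mean if mean is not None else np.nan,
                "sibling_group": rec.sibling_group or "",
            }
        )

    for fam in range(cfg.n_case_families):
        family_id = f"F{fam + 1:03d}"
        consang = rng.random() < cfg.consanguinity_rate
        homozygous = consang or rng.random() < cfg.homozygous_rate
        if homozygous:
            a = _draw_case_allele(rng, model, cfg)
            alleles = (a, a)
        else:
            a1 = _draw_case_allele(rng, model, cfg)
            a2 = _draw_case_allele(rng, model, cfg)
            while a2.hgvs_n == a1.hgvs_n:
                a2 = _draw_case_allele(rng, model, cfg)
            alleles = (a1, a2)
        n_sibs = 2 if fam < cfg.n_sibling_pairs else 1
        sib_group = f"S{fam + 1:03d}" if n_sibs == 2 else None
        for s in range(n_sibs):
            counter += 1
            rec = GenotypeRecord(
                individual_id=f"IND{counter:04d}",
                family_id=family_id,
                cohort="case",
                allele1=alleles[0],
                allele2=alleles[1],
                phase="trans",
                zygosity="homozygous" if homozygous else "compound-het",
                inheritance1="maternal",
                inheritance2="maternal" if homozygous else "paternal",
                consanguinity=consang,
                sibling_group=sib_group,
            )
            add(rec, "case")

    for i in range(cfg.n_controls):
        counter += 1
        homozygous = rng.random() < cfg.control_homozygous_rate
        if homozygous:
            a = _draw_snv(rng, model, cfg.control_region_weights)
            alleles = (a, a)
        else:
            a1 = _draw_snv(rng, model, cfg.control_region_weights)
            a2 = _draw_snv(rng, model, cfg.control_region_weights)
            while a2.hgvs_n == a1.hgvs_n:
                a2 = _draw_snv(rng, model, cfg.control_region_weights)
            alleles = (a1, a2)
        rec = GenotypeRecord(
            individual_id=f"UKB{counter:04d}",
            family_id=f"UF{i + 1:03d}",
            cohort="UKB-control",
            allele1=alleles[0],
            allele2=alleles[1],
            phase="trans",
            zygosity="homozygous" if homozygous else "compound-het",
        )
        add(rec, "control")

    truth = pd.DataFrame(truth_rows)
    return records, truth


def generate_population_reference(
    cfg: SimulationConfig, records: Sequence[GenotypeRecord]
) -> pd.DataFrame:
    """Biobank-style allele frequencies: every cohort variant is rare, with
    homozygote counts only for variants carried by control homozygotes."""
    rng = np.random.default_rng(cfg.seed + 2)
    rows = {}
    for rec in records:
        for allele in rec.alleles:
            if allele.hgvs_n in rows:
                continue
            af = float(10 ** rng.uniform(-6, -3.2))  # always below 0.1%
            n_hom = 0
            if rec.cohort != "case" and rec.zygosity == "homozygous":
                n_hom = 1
            rows[allele.hgvs_n] = {
                "hgvs_n": allele.hgvs_n,
                "allele_frequency": af,
                "n_homozygotes": n_hom,
            }
    return pd.DataFrame(list(rows.values()))


def _bernoulli_matrix(rng, ids, freqs: dict[str, float], missingness: float) -> pd.DataFrame:
    terms = list(freqs)
    data = {}
    for term in terms:
        present = (rng.random(len(ids)) < freqs[term]).astype(float)
        mask = rng.random(len(ids)) < missingness
        present[mask] = np.nan
        data[term] = present
    return pd.DataFrame(data, index=ids)


def generate_phenotypes_and_expression(
    cfg: SimulationConfig, records: Sequence[GenotypeRecord]
) -> dict:
    """Phenotype matrices (cases + a dominant-disorder comparison cohort),
    the expression TPM table and the PSI splice-signature table."""
    rng = np.random.default_rng(cfg.seed + 3)
    case_ids = [r.individual_id for r in records if r.cohort == "case"]
    sib = pd.Series(
        {r.individual_id: (r.sibling_group or np.nan) for r in records if r.cohort == "case"}
    )
    values = _bernoulli_matrix(rng, case_ids, cfg.phenotype_frequencies, cfg.missingness_rate)
    severity = pd.Series(np.nan, index=values.index)
    if "ID" in values.columns:
        with_id = values.index[values["ID"] == 1]
        severity.loc[with_id] = rng.choice(
            [1.0, 2.0, 3.0], size=len(with_id), p=[0.1, 0.5, 0.4]
        )
    cases = PhenotypeMatrix(
        values=values,
        cohorts=pd.Series("case", index=values.index),
        sibling_groups=sib.reindex(values.index),
        id_severity=severity,
    )
    renu_ids = [f"RENU{i + 1:04d}" for i in range(cfg.n_renu)]
    renu_values = _bernoulli_matrix(rng, renu_ids, cfg.renu_frequencies, cfg.missingness_rate)
    renu = PhenotypeMatrix(
        values=renu_values,
        cohorts=pd.Series("ReNU", index=renu_values.index),
        sibling_groups=pd.Series(np.nan, index=renu_values.index),
    )

    # expression: log-normal TPM with E[TPM] equal to the group mean
    sd = cfg.expression_log_sd
    samples, groups, tpm_rows = [], [], []
    for group, n in cfg.expression_group_sizes.items():
        means = cfg.expression_group_means[group]
        for i in range(n):
            sid = f"{group}-{i + 1:03d}"
            samples.append(sid)
            groups.append(group)
            row = {}
            for gene_name, m in means.items():
                mu = np.log(m) - sd**2 / 2
                row[gene_name] = float(np.exp(rng.normal(mu, sd)))
            tpm_rows.append(row)
    expression = ExpressionTable(
        tpm=pd.DataFrame(tpm_rows, index=samples),
        groups=pd.Series(groups, index=samples),
    )

    # splice signature: dominant-disorder samples shift PSI on half the events
    events = [f"A5SS_{i + 1:04d}" for i in range(cfg.n_events)]
    base = rng.uniform(0.2, 0.8, size=cfg.n_events)
    shifted = np.zeros(cfg.n_events, dtype=bool)
    shifted[: cfg.n_events // 2] = True
    psi_rows, psi_ids, psi_groups = [], [], []

    def psi_sample(sid: str, group: str, shift: bool) -> None:
        mu = base + (cfg.psi_shift * shifted if shift else 0.0)
        psi = np.clip(rng.normal(mu, cfg.psi_noise_sd), 0.0, 1.0)
        psi_rows.append(psi)
        psi_ids.append(sid)
        psi_groups.append(group)

    for i in range(cfg.n_psi_controls):
        psi_sample(f"psi-control-{i + 1:03d}", "control", False)
    for i in range(cfg.n_psi_renu):
        psi_sample(f"psi-ReNU-{i + 1:03d}", "ReNU", True)
    for i in range(cfg.expression_group_sizes.get("biallelic", 3)):
        psi_sample(f"psi-biallelic-{i + 1:03d}", "biallelic", False)
    signature = SpliceSignature(
        psi=pd.DataFrame(psi_rows, index=psi_ids, columns=events),
        groups=pd.Series(psi_groups, index=psi_ids),
        reference_groups=("control", "ReNU"),
    )
    return {
        "cases": cases,
        "renu": renu,
        "expression": expression,
        "signature": signature,
    }


def simulate_workspace(cfg: SimulationConfig, outdir) -> dict[str, Path]:
    """Materialize a complete input workspace on disk; returns file paths."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gene = generate_gene_and_scores(cfg)
    records, truth = generate_cohort(cfg, gene)
    pop = generate_population_reference(cfg, records)
    phen = generate_phenotypes_and_expression(cfg, records)

    paths: dict[str, Path] = {}

    def _p(name: str) -> Path:
        paths[name] = out / name
        return paths[name]

    seqs = [
        SeqRecord(Seq(gene.model.sequence), id=gene.model.gene_id, description="synthetic"),
        SeqRecord(
            Seq(gene.paralog_model.sequence),
            id=gene.paralog_model.gene_id,
            description="synthetic",
        ),
    ]
    SeqIO.write(seqs, _p("reference.fasta"), "fasta")
    gene.scores.to_tsv(_p("sge_scores.tsv"))
    gene.paralog_table.to_csv(_p("paralog_classified.tsv"), sep="\t", index=False)
    write_cohort_table(records, _p("cohort.tsv"))
    truth.to_csv(_p("truth.tsv"), sep="\t", index=False)
    pop.to_csv(_p("population_af.tsv"), sep="\t", index=False)
    phen["cases"].to_tsv(_p("phenotypes_cases.tsv"))
    phen["renu"].to_tsv(_p("phenotypes_renu.tsv"))
    phen["expression"].to_tsv(_p("expression_tpm.tsv"))
    psi_long = (
        phen["signature"]
        .psi.reset_index(names="sample")
        .melt(id_vars="sample", var_name="event_id", value_name="psi")
    )
    psi_long.insert(
        1, "group", phen["signature"].groups.reindex(psi_long["sample"]).to_numpy()
    )
    psi_long.to_csv(_p("psi_events.tsv"), sep="\t", index=False)
    # expression-signature flags: the notionally RNA-sequenced case individuals,
    # flagged when their sample shows RNU4-2 loss with RNU4-1 gain (ratio < 1)
    expr = phen["expression"]
    bial = expr.tpm[expr.groups == "biallelic"]
    ratios = (bial["RNU4-2"] / bial["RNU4-1"]).to_numpy()
    case_ids = [r.individual_id for r in records if r.cohort == "case"]
    flag_rows = [
        {"individual": ind, "expression_flag": bool(r < 1.0)}
        for ind, r in zip(case_ids, ratios)
    ]
    pd.DataFrame(flag_rows).to_csv(_p("expression_flags.tsv"), sep="\t", index=False)
    with open(_p("simulation_config.yaml"), "w") as fh:
        def _plain(v):
            if isinstance(v, dict):
                return {k: _plain(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return [_plain(x) for x in v]
            return v

        yaml.safe_dump(
            {k: _plain(v) for k, v in vars(cfg).items() if not k.startswith("_")},
            fh,
            default_flow_style=False,
        )
    return paths
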