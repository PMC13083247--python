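"""End-to-end orchestration of the analysis stages with a run manifest.

Stages (each reads TSV/FASTA inputs from a workspace directory and writes
TSV outputs plus a JSON manifest):

* ``simulate``  - materialize a complete synthetic workspace
* ``annotate``  - region + paralog annotation of the cohort's unique variants
* ``score``     - per-individual mean function scores and inclusion status
* ``classify``  - ACMG criteria per variant and biallelic status per individual
* ``enrich``    - case-cohort vs comparison-cohort phenotype enrichment
* ``biomarker`` - expression ratio, group tests, log-log regression, PSI PCA
* ``report``    - aggregate counts from all prior stage outputs

The manifest records the config snapshot, input digests, seed and per-stage
row counts; identical config and inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .acmg import (
    AcmgConfig,
    TransObservation,
    assess_variant,
    classify_cohort,
    cohort_status_summary,
    evaluate_criteria,
)
from .expression import (
    ExpressionTable,
    SpliceSignature,
    compare_expression_groups,
    compute_ratio_table,
    loglog_regression,
    project_splice_signature,
)
from .model import (
    annotate_region,
    default_alignment,
    default_model,
    find_equivalent_variant,
    is_pm1_eligible,
    load_default_config,
    region_distribution,
)
from .phenotypes import EnrichConfig, PhenotypeMatrix, build_frequency_table, enrich_phenotypes
from .sge import InclusionPolicy, SgeScoreTable, inclusion_filter, score_variant
from .simulate import SimulationConfig, simulate_workspace
from .variants import dedup_unique_variants, parse_hgvs, read_cohort_table


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        raise StageError(stage, f"required input {path} is missing")
    return path


def _load_models(stage: str, workspace: Path):
    fasta = _require(stage, workspace / "reference.fasta")
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
    base = load_default_config()
    gene_id = base["gene_id"]
    if gene_id not in seqs:
        raise StageError(stage, f"{gene_id} missing from {fasta}")
    model = default_model(sequence=seqs[gene_id])
    target_id = base["paralog_alignment"]["target_gene"]
    aln = default_alignment(
        source_sequence=seqs[gene_id], target_sequence=seqs.get(target_id)
    )
    return model, aln


class Pipeline:
    def __init__(self, workspace, outdir, seed: int = 0) -> None:
        self.workspace = Path(workspace)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(seed)
        self.manifest: dict = {
            "package_version": __version__,
            "seed": self.seed,
            "workspace": str(self.workspace),
            "stages": {},
            "inputs": {},
            "outputs": {},
        }

    # -- helpers ----------------------------------------------------------

    def _write(self, stage: str, name: str, df: pd.DataFrame) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=False)
        self.manifest["outputs"][name] = {
            "rows": int(len(df)),
            "sha256": _digest(path),
        }
        self.manifest["stages"].setdefault(stage, {"outputs": []})
        self.manifest["stages"][stage]["outputs"].append(name)
        return path

    def _note_input(self, path: Path) -> None:
        self.manifest["inputs"][path.name] = _digest(path)

    def save_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return path

    # -- stages -----------------------------------------------------------

    def simulate(self, sim_cfg: Optional[SimulationConfig] = None) -> dict:
        cfg = sim_cfg or SimulationConfig(seed=self.seed)
        paths = simulate_workspace(cfg, self.workspace)
        for p in paths.values():
            self._note_input(p)
        self.manifest["stages"]["simulate"] = {
            "outputs": [p.name for p in paths.values()]
        }
        return {"paths": paths}

    def annotate(self) -> dict:
        stage = "annotate"
        model, aln = _load_models(stage, self.workspace)
        cohort_path = _require(stage, self.workspace / "cohort.tsv")
        self._note_input(cohort_path)
        records = read_cohort_table(cohort_path, model)
        unique = dedup_unique_variants(records)
        paralog_path = self.workspace / "paralog_classified.tsv"
        paralog = (
            pd.read_csv(paralog_path, sep="\t") if paralog_path.exists() else None
        )
        rows = []
        for _, row in unique.iterrows():
            v = parse_hgvs(row["hgvs_n"], model)
            region, kturn = annotate_region(v.start, model)
            eq = find_equivalent_variant(v, aln, paralog)
            rows.append(
                {
                    **row.to_dict(),
                    "region": region,
                    "kturn": kturn,
                    "pm1_eligible": is_pm1_eligible(v.start, model),
                    "paralog_position": eq.aligned_position,
                    "paralog_equivalent": eq.equivalent,
                    "paralog_classification": eq.exact_match_classification or "",
                }
            )
        annotated = pd.DataFrame(rows)
        self._write(stage, "variants_annotated.tsv", annotated)
        dist = region_distribution(
            [parse_hgvs(h, model) for h in unique["hgvs_n"]], model
        )
        self._write(stage, "region_distribution.tsv", dist)
        return {"records": records, "annotated": annotated, "distribution": dist}

    def score(self) -> dict:
        stage = "score"
        model, _ = _load_models(stage, self.workspace)
        scores_path = _require(stage, self.workspace / "sge_scores.tsv")
        cohort_path = _require(stage, self.workspace / "cohort.tsv")
        self._note_input(scores_path)
        table = SgeScoreTable.read_tsv(scores_path)
        records = read_cohort_table(cohort_path, model)
        result = inclusion_filter(records, table, InclusionPolicy())
        self._write(stage, "inclusion.tsv", result)
        return {"inclusion": result, "records": records, "table": table}

    def classify(self, acmg_cfg: Optional[AcmgConfig] = None) -> dict:
        stage = "classify"
        cfg = acmg_cfg or AcmgConfig()
        model, aln = _load_models(stage, self.workspace)
        table = SgeScoreTable.read_tsv(_require(stage, self.workspace / "sge_scores.tsv"))
        records = read_cohort_table(_require(stage, self.workspace / "cohort.tsv"), model)
        pop_path = _require(stage, self.workspace / "population_af.tsv")
        pop = pd.read_csv(pop_path, sep="\t").set_index("hgvs_n")
        paralog_path = self.workspace / "paralog_classified.tsv"
        paralog = pd.read_csv(paralog_path, sep="\t") if paralog_path.exists() else None
        flags_path = self.workspace / "expression_flags.tsv"
        flags = (
            pd.read_csv(flags_path, sep="\t").set_index("individual")["expression_flag"]
            if flags_path.exists()
            else pd.Series(dtype=bool)
        )

        unique = dedup_unique_variants(records)
        variants = {h: parse_hgvs(h, model) for h in unique["hgvs_n"]}
        carriers: dict[str, list] = {h: [] for h in variants}
        for rec in records:
            if rec.cohort != "case":
                continue
            for allele in rec.alleles:
                if rec.individual_id not in [
                    c.individual_id for c in carriers[allele.hgvs_n]
                ]:
                    carriers[allele.hgvs_n].append(rec)

        def base_context(h: str) -> dict:
            v = variants[h]
            af = pop.loc[h, "allele_frequency"] if h in pop.index else 0.0
            n_hom = int(pop.loc[h, "n_homozygotes"]) if h in pop.index else 0
            positions = (
                [v.start, v.end] if v.vtype == "insertion" else range(v.start, v.end + 1)
            )
            return {
                "allele_frequency": af,
                "n_homozygotes": n_hom,
                "scored": score_variant(v, table),
                "pm1_positions": [is_pm1_eligible(p, model) for p in positions],
                "equivalence": find_equivalent_variant(
                    v, aln, paralog, require_same_alt=cfg.pm5_require_same_alt
                ),
                "expression_flag": any(
                    bool(flags.get(r.individual_id, False)) for r in carriers[h]
                ),
            }

        # pass 1: classify without in-trans evidence
        first_pass: dict[str, str] = {}
        for h, v in variants.items():
            crit = evaluate_criteria(v, cfg=cfg, trans_observations=[], **base_context(h))
            first_pass[h] = assess_variant(v, crit, cfg).classification

        # pass 2: PM3 from partner classifications of pass 1
        assessments = {}
        for h, v in variants.items():
            obs = []
            for rec in carriers[h]:
                if rec.zygosity == "homozygous":
                    obs.append(
                        TransObservation(
                            rec.individual_id, first_pass[h], "trans",
                            homozygous=True, consanguineous=rec.consanguinity,
                        )
                    )
                else:
                    partner = (
                        rec.allele2 if rec.allele1.hgvs_n == h else rec.allele1
                    )
                    obs.append(
                        TransObservation(
                            rec.individual_id,
                            first_pass[partner.hgvs_n],
                            "trans" if rec.phase == "trans" else "unknown",
                        )
                    )
            crit = evaluate_criteria(v, cfg=cfg, trans_observations=obs, **base_context(h))
            assessments[h] = assess_variant(v, crit, cfg)

        rows = []
        for h, a in assessments.items():
            rows.append(
                {
                    "hgvs_n": h,
                    "classification": a.classification,
                    "total_points": a.total_points,
                    "criteria_met": ";".join(c.code for c in a.criteria if c.met),
                }
            )
        per_variant = pd.DataFrame(rows).sort_values("hgvs_n", ignore_index=True)
        self._write(stage, "acmg_assessments.tsv", per_variant)
        case_records = [r for r in records if r.cohort == "case"]
        per_individual = classify_cohort(case_records, assessments)
        summary = cohort_status_summary(per_individual)
        self._write(stage, "biallelic_status.tsv", per_individual)
        self._write(stage, "biallelic_status_summary.tsv", summary)
        return {
            "assessments": assessments,
            "per_variant": per_variant,
            "per_individual": per_individual,
            "summary": summary,
        }

    def enrich(self, cfg: EnrichConfig = EnrichConfig()) -> dict:
        stage = "enrich"
        cases = PhenotypeMatrix.read_tsv(
            _require(stage, self.workspace / "phenotypes_cases.tsv")
        )
        renu = PhenotypeMatrix.read_tsv(
            _require(stage, self.workspace / "phenotypes_renu.tsv")
        )
        freq = build_frequency_table(cases)["terms"]
        self._write(stage, "phenotype_frequencies.tsv", freq)
        enr = enrich_phenotypes(cases.dedup_siblings(), renu, cfg)
        self._write(stage, "phenotype_enrichment.tsv", enr)
        return {"frequency": freq, "enrichment": enr}

    def biomarker(self) -> dict:
        stage = "biomarker"
        expr = ExpressionTable.read_tsv(
            _require(stage, self.workspace / "expression_tpm.tsv")
        )
        ratio = compute_ratio_table(expr, "RNU4-2", "RNU4-1")
        per_sample = ratio["per_sample"].reset_index(names="sample")
        self._write(stage, "expression_ratio.tsv", per_sample)
        self._write(stage, "expression_ratio_groups.tsv", ratio["group_means"])
        pairs = [(g, "control") for g in ("biallelic", "ReNU", "het-SGE-significant")]
        tests = pd.concat(
            [
                compare_expression_groups(expr, "RNU4-2", pairs).assign(quantity="RNU4-2"),
                compare_expression_groups(expr, "RNU4-1", pairs).assign(quantity="RNU4-1"),
                compare_expression_groups(
                    expr, ratio["per_sample"]["ratio"], pairs
                ).assign(quantity="ratio"),
            ],
            ignore_index=True,
        )
        self._write(stage, "expression_tests.tsv", tests)
        reg = loglog_regression(expr, "RNU4-1", "RNU4-2")
        self._write(stage, "expression_regression.tsv", pd.DataFrame([reg]))

        psi_path = self.workspace / "psi_events.tsv"
        projection = None
        if psi_path.exists():
            long = pd.read_csv(psi_path, sep="\t")
            psi = long.pivot(index="sample", columns="event_id", values="psi")
            groups = long.drop_duplicates("sample").set_index("sample")["group"]
            sig = SpliceSignature(
                psi=psi,
                groups=groups.reindex(psi.index),
                reference_groups=("control", "ReNU"),
            )
            query = [s for s in psi.index if groups[s] == "biallelic"]
            proj = project_splice_signature(sig, query)
            coords = pd.concat(
                [
                    proj["reference_coordinates"].assign(role="reference"),
                    proj["query_coordinates"].assign(role="query"),
                ]
            ).reset_index(names="sample")
            coords["group"] = groups.reindex(coords["sample"]).to_numpy()
            self._write(stage, "psi_projection.tsv", coords)
            projection = proj
        return {"ratio": ratio, "tests": tests, "regression": reg, "projection": projection}

    def report(self) -> dict:
        stage = "report"
        summary: dict = {"seed": self.seed}
        for name in (
            "variants_annotated.tsv",
            "inclusion.tsv",
            "acmg_assessments.tsv",
            "biallelic_status_summary.tsv",
            "phenotype_enrichment.tsv",
            "expression_ratio_groups.tsv",
        ):
            path = self.outdir / name
            if not path.exists():
                continue
            df = pd.read_csv(path, sep="\t")
            summary[name] = int(len(df))
            if name == "inclusion.tsv":
                summary["n_included"] = int((df["status"] == "included").sum())
                summary["n_excluded"] = int((df["status"] == "excluded").sum())
        path = self.outdir / "report.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        self.manifest["stages"][stage] = {"outputs": ["report.json"]}
        return summary


STAGES = ("simulate", "annotate", "score", "classify", "enrich", "biomarker", "report")


def run_pipeline(workspace, outdir, stages: Sequence[str] = STAGES, seed: int = 0) -> Pipeline:
    pipe = Pipeline(workspace, outdir, seed=seed)
    for stage in stages:
        if stage not in STAGES:
            raise StageError(stage, "unknown stage")
        getattr(pipe, stage)()
    pipe.save_manifest()
    return pipe
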