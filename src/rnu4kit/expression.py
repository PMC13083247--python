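"""Expression-ratio biomarker and splice-signature projection.

In blood transcriptomes generated with ribodepletion protocols, snRNA
expression is quantifiable in TPM.  Individuals with biallelic loss of
*RNU4-2* show a strong reduction of *RNU4-2* with compensatory upregulation
of its paralog *RNU4-1*; the per-sample *RNU4-2*/*RNU4-1* TPM ratio therefore
separates such cases from controls and is the candidate diagnostic
biomarker computed here.  Group summaries average per-sample ratios (never
the ratio of group means).

The splice-signature check projects new samples into a principal-component
space fitted on reference cohorts' PSI (percent spliced in) values for a
pre-selected set of alternative 5' splice-site events, to ask whether query
samples cluster with a disease signature or with controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class ExpressionTable:
    """Samples x genes TPM values with per-sample group labels."""

    tpm: pd.DataFrame  # index: sample ids; columns: genes
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy(dtype=float) < 0).any():
            raise ValueError("TPM values must be nonnegative")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionTable":
        """Long-format TSV: sample, group, gene, tpm."""
        df = pd.read_csv(path, sep="\t")
        wide = df.pivot(index="sample", columns="gene", values="tpm")
        groups = df.drop_duplicates("sample").set_index("sample")["group"]
        return cls(tpm=wide, groups=groups.reindex(wide.index))

    def to_tsv(self, path) -> None:
        long = self.tpm.reset_index(names="sample").melt(
            id_vars="sample", var_name="gene", value_name="tpm"
        )
        long.insert(1, "group", self.groups.reindex(long["sample"]).to_numpy())
        long.to_csv(path, sep="\t", index=False)


def compute_ratio_table(
    t: ExpressionTable, numerator_gene: str, denominator_gene: str
) -> dict:
    """Per-sample expression ratio plus per-group mean ratios.

    Samples with zero denominator TPM get an undefined ratio and are
    excluded from group means (their count is reported).
    """
    for g in (numerator_gene, denominator_gene):
        if g not in t.tpm.columns:
            raise ValueError(f"gene {g!r} missing from expression table")
    num = t.tpm[numerator_gene].astype(float)
    den = t.tpm[denominator_gene].astype(float)
    ratio = num / den.replace(0.0, np.nan)
    per_sample = pd.DataFrame(
        {
            "group": t.groups,
            numerator_gene: num,
            denominator_gene: den,
            "ratio": ratio,
        }
    )
    group_means = (
        per_sample.dropna(subset=["ratio"])
        .groupby("group")["ratio"]
        .agg(mean_ratio="mean", n="size")
        .reset_index()
    )
    return {
        "per_sample": per_sample,
        "group_means": group_means,
        "n_undefined": int(ratio.isna().sum()),
    }


def compare_expression_groups(
    t: ExpressionTable,
    quantity,  # gene name, or a per-sample Series (e.g. the ratio)
    group_pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests between groups on TPM or a ratio."""
    if isinstance(quantity, str):
        values = t.tpm[quantity].astype(float)
    else:
        values = pd.Series(quantity, index=t.tpm.index, dtype=float)
    rows = []
    for ga, gb in group_pairs:
        xa = values[t.groups == ga].dropna()
        xb = values[t.groups == gb].dropna()
        if xa.empty or xb.empty:
            raise ValueError(f"empty group in pair ({ga}, {gb})")
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": int(xa.size),
                "n_b": int(xb.size),
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "U": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SpliceSignature:
    """PSI values (samples x events) for pre-selected splice events, with the
    reference group labels that define the component space."""

    psi: pd.DataFrame  # index: sample ids; columns: event ids
    groups: pd.Series  # sample -> group label
    reference_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = self.psi.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("PSI values must lie in [0, 1]")


def project_splice_signature(
    sig: SpliceSignature, query_samples: Sequence[str], n_components: int = 2
) -> dict:
    """Fit a PCA space on reference samples' PSI values and project queries.

    Centering uses reference means only, so query samples do not influence
    the space.  Missing PSI values are imputed with the reference mean of
    their event.  Signs follow the largest-magnitude-loading-positive
    convention.
    """
    ref_ids = [
        s for s in sig.psi.index if sig.groups.get(s) in sig.reference_groups
    ]
    if len(ref_ids) < 2:
        raise ValueError("need at least 2 reference samples")
    missing_q = [s for s in query_samples if s not in sig.psi.index]
    if missing_q:
        raise ValueError(f"query samples missing from PSI table: {missing_q}")
    ref = sig.psi.loc[ref_ids].to_numpy(dtype=float)
    ref_mean = np.nanmean(ref, axis=0)
    ref_mean = np.where(np.isnan(ref_mean), 0.0, ref_mean)

    def _prep(x: np.ndarray) -> np.ndarray:
        x = np.where(np.isnan(x), ref_mean, x)
        return x - ref_mean

    centered = _prep(ref)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, int(np.sum(s > 1e-12)))
    if k == 0:
        raise ValueError("reference PSI matrix has zero variance")
    vt = vt[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    ref_coords = pd.DataFrame(centered @ vt.T, index=ref_ids, columns=cols)
    qry = _prep(sig.psi.loc[list(query_samples)].to_numpy(dtype=float))
    qry_coords = pd.DataFrame(qry @ vt.T, index=list(query_samples), columns=cols)
    return {
        "reference_coordinates": ref_coords,
        "query_coordinates": qry_coords,
        "loadings": pd.DataFrame(vt.T, index=sig.psi.columns, columns=cols),
    }


def loglog_regression(t: ExpressionTable, gene_x: str, gene_y: str) -> dict:
    """OLS of log10(gene_y) on log10(gene_x); zero-TPM samples excluded."""
    for g in (gene_x, gene_y):
        if g not in t.tpm.columns:
            raise ValueError(f"gene {g!r} missing from expression table")
    x = t.tpm[gene_x].astype(float)
    y = t.tpm[gene_y].astype(float)
    usable = (x > 0) & (y > 0)
    n_excluded = int((~usable).sum())
    if usable.sum() < 3:
        raise ValueError("need at least 3 samples with positive TPM for both genes")
    lx = np.log10(x[usable].to_numpy())
    ly = np.log10(y[usable].to_numpy())
    fit = sm.OLS(ly, sm.add_constant(lx)).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "p": float(fit.pvalues[1]),
        "n": int(usable.sum()),
        "n_excluded": n_excluded,
    }
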