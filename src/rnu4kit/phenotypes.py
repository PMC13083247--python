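"""Phenotype frequency tables, case-case enrichment and clustering.

Phenotype data are per-individual matrices of clinical terms coded present
(1), absent (0) or unknown (NA).  Frequencies always use the *known*
denominator (present + absent); unknowns never inflate denominators.

The enrichment comparison between two cohorts follows a select-test-correct
order: terms present in at least 25% of either cohort are selected, each is
tested with a two-sided Fisher exact test on present/absent counts, odds
ratios use the Haldane-Anscombe correction (0.5 added to every cell), and
Benjamini-Hochberg FDR is applied across the selected terms only.

Clustering encodes terms as 0/1 (unknown treated as absent), optionally
appends an ordinal intellectual-disability severity column, and runs PCA on
the centered encoding with one individual kept per sibling pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PhenotypeMatrix:
    """Individuals x terms matrix with values 1 (present), 0 (absent), NaN
    (unknown), plus cohort labels, sibling groups and optional ID severity."""

    values: pd.DataFrame  # index: individual ids; columns: terms
    cohorts: pd.Series  # individual -> cohort label
    sibling_groups: pd.Series  # individual -> group id or NaN
    id_severity: Optional[pd.Series] = None  # 1=mild, 2=moderate, 3=severe

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("phenotype values must be 0, 1 or NA")
        if self.id_severity is not None and "ID" in self.values.columns:
            has_sev = self.id_severity.dropna().index
            not_present = [
                i for i in has_sev if self.values.loc[i, "ID"] != 1
            ]
            if not_present:
                raise ValueError(
                    f"ID severity given for individuals without the ID term: {not_present}"
                )

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    @property
    def terms(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path) -> "PhenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="individual")
        meta_cols = [c for c in ("cohort", "sibling_group", "id_severity") if c in df.columns]
        terms = df.drop(columns=meta_cols)
        return cls(
            values=terms.astype(float),
            cohorts=df["cohort"] if "cohort" in df else pd.Series("", index=df.index),
            sibling_groups=df["sibling_group"]
            if "sibling_group" in df
            else pd.Series(np.nan, index=df.index),
            id_severity=df["id_severity"].astype(float) if "id_severity" in df else None,
        )

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "cohort", self.cohorts)
        out.insert(1, "sibling_group", self.sibling_groups)
        if self.id_severity is not None:
            out["id_severity"] = self.id_severity
        out.to_csv(path, sep="\t", index_label="individual")

    def dedup_siblings(self) -> "PhenotypeMatrix":
        keep: list[str] = []
        seen: dict[str, str] = {}
        for ind in sorted(self.individuals):
            g = self.sibling_groups.get(ind)
            if pd.isna(g) or g == "":
                keep.append(ind)
            elif g not in seen:
                seen[g] = ind
                keep.append(ind)
        keep = [i for i in self.individuals if i in set(keep)]
        return PhenotypeMatrix(
            values=self.values.loc[keep],
            cohorts=self.cohorts.loc[keep],
            sibling_groups=self.sibling_groups.loc[keep],
            id_severity=None if self.id_severity is None else self.id_severity.loc[keep],
        )


@dataclass
class EnrichConfig:
    prevalence_threshold: float = 0.25
    ha_mode: str = "always"  # always | only_zero_cells
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_threshold < 1:
            raise ValueError("prevalence threshold must be in (0, 1)")
        if self.ha_mode not in ("always", "only_zero_cells"):
            raise ValueError(f"unknown HA mode {self.ha_mode!r}")


def build_frequency_table(
    m: PhenotypeMatrix,
    numeric_fields: Optional[pd.DataFrame] = None,
    stratify_by: Optional[pd.Series] = None,
) -> dict:
    """Table-1-style summary: per-term present/known counts and percentages,
    plus median and range for optional per-individual numeric fields.

    ``known`` counts individuals coded present or absent; unknowns are
    excluded from the denominator.  With ``stratify_by`` (individual ->
    stratum), per-stratum columns are added alongside the totals.
    """

    def _summarize(values: pd.DataFrame) -> pd.DataFrame:
        present = (values == 1).sum(axis=0)
        absent = (values == 0).sum(axis=0)
        known = present + absent
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * present / known.replace(0, np.nan)
        return pd.DataFrame(
            {"present": present.astype(int), "known": known.astype(int), "percent": pct}
        ).rename_axis("term").reset_index()

    terms = _summarize(m.values)
    if stratify_by is not None:
        for stratum in sorted(stratify_by.dropna().unique()):
            ids = stratify_by[stratify_by == stratum].index
            sub = _summarize(m.values.loc[m.values.index.intersection(ids)])
            terms = terms.merge(
                sub.rename(
                    columns={
                        "present": f"present_{stratum}",
                        "known": f"known_{stratum}",
                        "percent": f"percent_{stratum}",
                    }
                ),
                on="term",
            )
    numerics = None
    if numeric_fields is not None:
        rows = []
        for col in numeric_fields.columns:
            x = numeric_fields[col].dropna()
            rows.append(
                {
                    "field": col,
                    "n": int(x.size),
                    "median": float(x.median()) if x.size else np.nan,
                    "min": float(x.min()) if x.size else np.nan,
                    "max": float(x.max()) if x.size else np.nan,
                }
            )
        numerics = pd.DataFrame(rows)
    return {"terms": terms, "numerics": numerics}


def fisher_exact_test(table: Sequence[Sequence[int]], sided: str = "two") -> float:
    """Fisher exact p-value on a 2x2 count table.

    Two-sided p sums hypergeometric point probabilities at most the observed
    one (with the conventional 1+1e-7 relative tolerance); one-sided tests
    enrichment of the top-left cell.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    alternative = {"two": "two-sided", "one": "greater"}[sided]
    return float(stats.fisher_exact(t, alternative=alternative)[1])


def ha_odds_ratio(
    table: Sequence[Sequence[int]], cfg: EnrichConfig = EnrichConfig()
) -> dict:
    """Odds ratio with Haldane-Anscombe correction and 95% Wald CI.

    In ``always`` mode 0.5 is added to every cell of every table; in
    ``only_zero_cells`` mode the correction is applied only when some cell
    is zero.  The CI is exp(log OR +/- 1.96 * SE) with SE from the corrected
    cells.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if cfg.ha_mode == "always" or (t == 0).any():
        t = t + 0.5
    (a, b), (c, d) = t
    orr = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    log_or = float(np.log(orr))
    return {
        "odds_ratio": float(orr),
        "ci_low": float(np.exp(log_or - 1.96 * se)),
        "ci_high": float(np.exp(log_or + 1.96 * se)),
        "se_log_or": se,
    }


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, in input order.

    q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def _present_known(m) -> pd.DataFrame:
    """Accept a PhenotypeMatrix or a pre-aggregated present/known table."""
    if isinstance(m, PhenotypeMatrix):
        present = (m.values == 1).sum(axis=0).astype(int)
        known = ((m.values == 1) | (m.values == 0)).sum(axis=0).astype(int)
        return pd.DataFrame({"present": present, "known": known}).rename_axis("term")
    df = pd.DataFrame(m)
    if "term" in df.columns:
        df = df.set_index("term")
    if not {"present", "known"}.issubset(df.columns):
        raise ValueError("aggregated counts need 'present' and 'known' columns")
    return df[["present", "known"]].astype(int)


def enrich_phenotypes(
    cohort_a,
    cohort_b,
    cfg: EnrichConfig = EnrichConfig(),
    term_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-term enrichment of cohort A versus cohort B.

    Inputs may be :class:`PhenotypeMatrix` objects or aggregated
    present/known tables (e.g. for a published comparison cohort).  An
    optional explicit ``term_map`` renames cohort-B terms onto cohort-A
    vocabulary before matching; no fuzzy matching is attempted.
    """
    a = _present_known(cohort_a)
    b = _present_known(cohort_b)
    if term_map:
        b = b.rename(index=dict(term_map))
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("no shared phenotype terms between cohorts")
    rows = []
    for term in shared:
        pa, ka = int(a.loc[term, "present"]), int(a.loc[term, "known"])
        pb, kb = int(b.loc[term, "present"]), int(b.loc[term, "known"])
        if ka == 0 or kb == 0:
            continue
        prev_a, prev_b = pa / ka, pb / kb
        if max(prev_a, prev_b) < cfg.prevalence_threshold:
            continue
        table = [[pa, ka - pa], [pb, kb - pb]]
        orr = ha_odds_ratio(table, cfg)
        rows.append(
            {
                "term": term,
                "present_a": pa,
                "known_a": ka,
                "present_b": pb,
                "known_b": kb,
                "prevalence_a": prev_a,
                "prevalence_b": prev_b,
                "odds_ratio": orr["odds_ratio"],
                "ci_low": orr["ci_low"],
                "ci_high": orr["ci_high"],
                "p": fisher_exact_test(table, "two"),
                "direction": "enriched" if orr["odds_ratio"] > 1 else "depleted",
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no terms passed the prevalence threshold")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < cfg.alpha
    return out.sort_values("q", ignore_index=True)


def encode_for_pca(m: PhenotypeMatrix) -> pd.DataFrame:
    """Binary encoding for clustering: present=1, absent/unknown=0, plus an
    ordinal ID-severity column when available (unknown severity = 0)."""
    enc = m.values.fillna(0.0).astype(float)
    if m.id_severity is not None:
        enc = enc.copy()
        enc["id_severity"] = m.id_severity.reindex(enc.index).fillna(0.0)
    return enc


def phenotype_pca(m: PhenotypeMatrix, n_components: Optional[int] = None) -> dict:
    """PCA of encoded phenotype profiles, one individual per sibling pair.

    Columns are centered but not scaled; components come from the SVD with a
    fixed sign convention (the largest-magnitude loading of each component is
    positive), so results are fully deterministic.
    """
    deduped = m.dedup_siblings()
    if len(deduped.individuals) < 2:
        raise ValueError("need at least 2 individuals after sibling dedup")
    enc = encode_for_pca(deduped)
    x = enc.to_numpy(dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("phenotype matrix has zero variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = n_components or int(np.sum(s > 1e-12))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    coords = pd.DataFrame(
        scores, index=enc.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    loadings = pd.DataFrame(
        vt.T, index=enc.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    var = s**2 / max(len(enc) - 1, 1)
    return {"coordinates": coords, "loadings": loadings, "explained_variance": var}
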