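"""Frequency tables, Fisher/OR/FDR machinery, enrichment and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rnu4kit.phenotypes import (
    EnrichConfig,
    PhenotypeMatrix,
    bh_fdr,
    build_frequency_table,
    enrich_phenotypes,
    fisher_exact_test,
    ha_odds_ratio,
    phenotype_pca,
)

from oracles import bh_stepwise, fisher_two_sided_enum


def matrix_from(values: dict, cohort="case", sibs=None) -> PhenotypeMatrix:
    df = pd.DataFrame(values, dtype=float)
    df.index = [f"I{i}" for i in range(len(df))]
    return PhenotypeMatrix(
        values=df,
        cohorts=pd.Series(cohort, index=df.index),
        sibling_groups=pd.Series(sibs if sibs is not None else np.nan, index=df.index),
    )


def test_frequency_table_known_denominators():
    col = [1.0] * 18 + [0.0] * 5 + [np.nan] * 8
    m = matrix_from({"dilated_pvs": col})
    t = build_frequency_table(m)["terms"]
    row = t.iloc[0]
    assert (row["present"], row["known"]) == (18, 23)
    assert row["percent"] == pytest.approx(100 * 18 / 23, abs=0.05)  # 78.3%


def test_frequency_table_seizure_and_all_unknown():
    m = matrix_from({
        "seizure": [1.0] * 19 + [0.0] * 12,
        "ghost": [np.nan] * 31,
    })
    t = build_frequency_table(m)["terms"].set_index("term")
    assert t.loc["seizure", "percent"] == pytest.approx(61.3, abs=0.05)
    assert t.loc["ghost", "known"] == 0
    assert np.isnan(t.loc["ghost", "percent"])


def test_frequency_table_numerics_and_strata():
    m = matrix_from({"seizure": [1.0, 0.0, 1.0, np.nan]})
    ages = pd.DataFrame({"age": [10.0, 0.12, 32.0, np.nan]}, index=m.values.index)
    strata = pd.Series(["plp", "plp", "other", "other"], index=m.values.index)
    out = build_frequency_table(m, numeric_fields=ages, stratify_by=strata)
    num = out["numerics"].iloc[0]
    assert (num["median"], num["min"], num["max"]) == (10.0, 0.12, 32.0)
    row = out["terms"].iloc[0]
    assert row["present_plp"] == 1 and row["known_plp"] == 2


@pytest.mark.parametrize(
    "table, expected",
    [
        ([[5, 5], [5, 5]], 1.0),
        ([[2, 0], [0, 2]], 1 / 3),
        ([[7, 14], [0, 35]], 5.0139e-4),
    ],
)
def test_fisher_two_sided_values(table, expected):
    assert fisher_exact_test(table, "two") == pytest.approx(expected, rel=1e-3)
    assert fisher_two_sided_enum(table) == pytest.approx(expected, rel=1e-3)


def test_fisher_rejects_bad_input():
    with pytest.raises(ValueError):
        fisher_exact_test([[1, -2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact_test([[1, 2, 3], [4, 5, 6]])


def test_fisher_matches_enumeration_on_random_tables(rng):
    for _ in range(150):
        t = rng.integers(0, 16, size=(2, 2))
        p = fisher_exact_test(t, "two")
        assert p == pytest.approx(fisher_two_sided_enum(t), rel=1e-12)
        assert 0 < p <= 1


def test_ha_odds_ratio():
    assert ha_odds_ratio([[1, 1], [1, 1]])["odds_ratio"] == pytest.approx(1.0)
    out = ha_odds_ratio([[3, 0], [0, 3]])
    assert out["odds_ratio"] == pytest.approx(49.0)  # (3.5 * 3.5) / (0.5 * 0.5)
    assert out["ci_low"] < 49.0 < out["ci_high"]
    # swapping rows inverts the odds ratio exactly
    a = ha_odds_ratio([[12, 12], [3, 21]])["odds_ratio"]
    b = ha_odds_ratio([[3, 21], [12, 12]])["odds_ratio"]
    assert a == pytest.approx(1 / b)


def test_ha_only_zero_cells_mode():
    cfg = EnrichConfig(ha_mode="only_zero_cells")
    # no zero cell: uncorrected OR
    assert ha_odds_ratio([[2, 4], [1, 8]], cfg)["odds_ratio"] == pytest.approx(4.0)
    # zero cell: correction kicks in
    assert ha_odds_ratio([[3, 0], [0, 3]], cfg)["odds_ratio"] == pytest.approx(49.0)


def test_bh_fdr_stepwise_example():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_fdr_properties(pvals):
    q = bh_fdr(pvals)
    assert np.all(q >= np.asarray(pvals) - 1e-15)
    assert np.all(q <= 1.0)
    assert q == pytest.approx(bh_stepwise(pvals), abs=1e-12)
    # invariant under permutation (after restoring order)
    perm = np.random.RandomState(0).permutation(len(pvals))
    q2 = bh_fdr(np.asarray(pvals)[perm])
    assert q2 == pytest.approx(q[perm], abs=1e-12)


def test_bh_fdr_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=40)
    expected = multipletests(p, method="fdr_bh")[1]
    assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)


def test_enrichment_selection_correction_and_finiteness():
    a = matrix_from({
        "hallmark": [1.0] * 12 + [0.0] * 12,   # 50% in cohort A
        "rare": [1.0] * 2 + [0.0] * 22,        # 8% everywhere -> dropped
        "common": [1.0] * 20 + [0.0] * 4,
    })
    b = matrix_from({
        "hallmark": [0.0] * 10,                # absent in cohort B
        "rare": [1.0] * 1 + [0.0] * 9,
        "common": [1.0] * 8 + [0.0] * 2,
    })
    out = enrich_phenotypes(a, b)
    assert set(out["term"]) == {"hallmark", "common"}  # 25% rule in either cohort
    hall = out.set_index("term").loc["hallmark"]
    assert np.isfinite(hall["odds_ratio"]) and hall["odds_ratio"] > 1
    assert hall["direction"] == "enriched"
    # BH applied across selected terms only (m = 2)
    assert out["q"].max() <= 1.0
    with pytest.raises(ValueError, match="no shared"):
        enrich_phenotypes(a, matrix_from({"other": [1.0] * 4}))


def test_enrichment_accepts_aggregated_counts():
    a = matrix_from({"hallmark": [1.0] * 12 + [0.0] * 12})
    b = pd.DataFrame({"term": ["hallmark"], "present": [2], "known": [40]})
    out = enrich_phenotypes(a, b)
    assert out.loc[0, "present_b"] == 2 and out.loc[0, "known_b"] == 40


def test_pca_identical_profiles_and_rank_bound():
    m = matrix_from({
        "a": [1.0, 1.0, 0.0, 0.0],
        "b": [1.0, 1.0, 0.0, 1.0],
        "c": [0.0, 0.0, 1.0, 0.0],
    })
    out = phenotype_pca(m)
    coords = out["coordinates"]
    assert np.allclose(coords.iloc[0], coords.iloc[1])  # identical encodings
    assert coords.shape[1] <= min(3, 3)  # rank bound: min(n-1, n_terms)
    with pytest.raises(ValueError, match="zero variance"):
        phenotype_pca(matrix_from({"a": [1.0, 1.0], "b": [0.0, 0.0]}))


def test_pca_matches_sklearn_up_to_sign():
    rng = np.random.default_rng(7)
    vals = (rng.random((12, 6)) < 0.4).astype(float)
    m = matrix_from({f"t{j}": vals[:, j] for j in range(6)})
    out = phenotype_pca(m, n_components=3)
    from sklearn.decomposition import PCA

    ref = PCA(n_components=3).fit_transform(vals - 0)  # sklearn centers internally
    assert np.allclose(np.abs(out["coordinates"].to_numpy()), np.abs(ref), atol=1e-9)


def test_pca_unknowns_encoded_absent_and_siblings_deduped():
    m = PhenotypeMatrix(
        values=pd.DataFrame(
            {"a": [1.0, 1.0, np.nan, 0.0], "b": [0.0, 0.0, 1.0, 1.0]},
            index=["s1", "s2", "x", "y"],
        ),
        cohorts=pd.Series("case", index=["s1", "s2", "x", "y"]),
        sibling_groups=pd.Series(["G1", "G1", np.nan, np.nan],
                                 index=["s1", "s2", "x", "y"]),
    )
    out = phenotype_pca(m)
    assert list(out["coordinates"].index) == ["s1", "x", "y"]


def test_pca_separates_disjoint_term_groups():
    """Two groups with disjoint high-frequency term sets split on PC1 in
    nearly every replicate."""
    hits = 0
    n_rep = 40
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        g1 = np.hstack([(rng.random((10, 5)) < 0.9), (rng.random((10, 5)) < 0.05)])
        g2 = np.hstack([(rng.random((10, 5)) < 0.05), (rng.random((10, 5)) < 0.9)])
        vals = np.vstack([g1, g2]).astype(float)
        m = matrix_from({f"t{j}": vals[:, j] for j in range(10)})
        pc1 = phenotype_pca(m)["coordinates"]["PC1"].to_numpy()
        lo, hi = pc1[:10], pc1[10:]
        hits += int(lo.max() < hi.min() or hi.max() < lo.min())
    assert hits >= int(0.95 * n_rep)


def test_severity_column_requires_id_term():
    df = pd.DataFrame({"ID": [1.0, 0.0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="severity"):
        PhenotypeMatrix(
            values=df,
            cohorts=pd.Series("case", index=df.index),
            sibling_groups=pd.Series(np.nan, index=df.index),
            id_severity=pd.Series([3.0, 2.0], index=df.index),
        )
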