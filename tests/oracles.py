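"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: the Fisher oracle
enumerates the hypergeometric support directly, the BH oracle applies the
stepwise definition, the rank-correlation oracle uses the rank formula, and
the classification oracle is a hand-built truth table over criterion counts.
"""

from __future__ import annotations

import math

import numpy as np


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric support.

    Sums point probabilities at most (1 + 1e-7) times the observed one.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    r, k = a + b, a + c  # row-1 and column-1 margins

    def point_prob(x: int) -> float:
        return (
            math.comb(r, x)
            * math.comb(n - r, k - x)
            / math.comb(n, k)
        )

    lo, hi = max(0, r + k - n), min(r, k)
    p_obs = point_prob(a)
    total = sum(
        p for x in range(lo, hi + 1) if (p := point_prob(x)) <= p_obs * (1 + 1e-7)
    )
    return min(total, 1.0)


def bh_stepwise(pvalues) -> np.ndarray:
    """Benjamini-Hochberg by the literal stepwise definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_idx, idx in enumerate(order):
        j0 = rank_idx + 1
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(j0, m + 1)),
            1.0,
        )
    return q


def spearman_rho(x, y) -> float:
    """Spearman rank correlation via the Pearson-of-ranks formula."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def acmg_class_from_counts(n_supporting: int, n_moderate: int) -> str:
    """Hand-built truth table for criterion sets containing only supporting
    and moderate strengths (the regime where points and categorical
    combination rules must agree)."""
    if n_moderate >= 3:
        return "Likely pathogenic"
    if n_moderate == 2 and n_supporting >= 2:
        return "Likely pathogenic"
    if n_moderate == 1 and n_supporting >= 4:
        return "Likely pathogenic"
    return "VUS"


def region_tally(positions, spans) -> dict:
    """Brute-force per-region tally: spans is {name: (start, end)}."""
    counts: dict[str, int] = {}
    for pos in positions:
        label = "unassigned"
        for name, (s, e) in spans.items():
            if s <= pos <= e:
                label = name
                break
        counts[label] = counts.get(label, 0) + 1
    return counts


def auroc(scores_pos, scores_neg) -> float:
    """Area under the ROC curve by pairwise comparison."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))
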