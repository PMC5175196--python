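"""Wilcoxon signed-rank outlier detection for per-miRNA scores.

A miRNA's score (NOD, TFP or AGP) is declared "significantly high" by a
one-sample Wilcoxon signed-rank test on the paired differences between the
focal miRNA's score and every other scored miRNA's score, one-sided in the
"greater" direction. This construction gives per-miRNA p-values with two
structural guarantees: miRNAs with equal scores receive identical p-values,
and a larger score never receives a larger p-value (for a fixed
background). It is an interpretation of the outlier filter, documented as
such in the methods note.

Conventions: zero differences are dropped (Wilcoxon's original treatment);
tied absolute differences receive mid-ranks; the null distribution of the
positive-rank sum W+ is enumerated exactly for n_eff <= 25 tie-free
differences and otherwise approximated by a tie-corrected normal with
continuity correction. All differences zero gives p = 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutlierTestResult",
    "signed_rank_p",
    "outlier_pvalue",
    "outlier_pvalues",
    "select_significant",
]

EXACT_LIMIT = 25


@dataclass(frozen=True)
class OutlierTestResult:
    statistic: float  # signed-rank sum W+
    n_eff: int  # nonzero paired differences
    p_value: float  # one-sided, P(W+ >= observed)
    method: str  # "exact" or "normal_approx"
    mirna_id: str | None = None
    metric: str | None = None


def _exact_tail_p(w_plus: int, n: int) -> float:
    """P(W+ >= w_plus) under the exact tie-free null, by subset-sum counting.

    The null distribution of W+ over the 2^n equiprobable sign assignments
    is the number of subsets of {1..n} summing to each value, built by
    dynamic programming (polynomial product of (1 + x^r)).
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=np.uint64)
    counts[0] = 1
    for r in range(1, n + 1):
        counts[r:] += counts[: total + 1 - r]
    tail = int(counts[w_plus:].sum())
    return tail / 2.0**n


def signed_rank_p(differences, alternative: str = "greater") -> OutlierTestResult:
    """One-sided Wilcoxon signed-rank test on a vector of paired differences.

    Returns the positive-rank sum W+, the effective sample size after
    dropping zeros, the one-sided p-value P(W+ >= observed), and which
    null ("exact" enumeration or tie-corrected "normal_approx") was used.
    """
    if alternative != "greater":
        raise ValueError("only the 'greater' alternative is supported")
    d = np.asarray(differences, dtype=float)
    if d.size and not np.isfinite(d).all():
        raise ValueError("non-finite differences")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return OutlierTestResult(statistic=0.0, n_eff=0, p_value=1.0, method="exact")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n

    if n <= EXACT_LIMIT and not has_ties:
        p = _exact_tail_p(int(round(w_plus)), n)
        return OutlierTestResult(w_plus, n, p, "exact")

    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    sigma2 -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    sigma = np.sqrt(sigma2)
    if sigma == 0.0:  # only possible for pathological inputs
        p = 1.0 if w_plus <= mu else 0.5
    else:
        z = (w_plus - 0.5 - mu) / sigma  # continuity-corrected
        p = float(stats.norm.sf(z))
    return OutlierTestResult(w_plus, n, min(max(p, np.nextafter(0, 1)), 1.0), "normal_approx")


def outlier_pvalue(scores: pd.Series, focal: str, metric: str | None = None) -> OutlierTestResult:
    """Signed-rank outlier test of one miRNA's score against the background.

    ``scores`` maps every miRNA in the scoring network to its score; the
    paired differences are focal-minus-other over all other miRNAs.
    """
    if focal not in scores.index:
        raise KeyError(f"miRNA '{focal}' not in the score background")
    others = scores.drop(index=focal)
    if len(others) < 1:
        raise ValueError("outlier test needs at least 2 scored miRNAs")
    d = float(scores[focal]) - others.to_numpy(dtype=float)
    res = signed_rank_p(d)
    return OutlierTestResult(res.statistic, res.n_eff, res.p_value, res.method, focal, metric)


def outlier_pvalues(scores: pd.Series, metric: str | None = None) -> pd.Series:
    """Per-miRNA outlier p-values against the full background.

    Equal scores yield identical difference multisets, so p-values are
    computed once per distinct score value.
    """
    cache: dict[float, float] = {}
    out = {}
    for m in scores.index:
        v = float(scores[m])
        if v not in cache:
            cache[v] = outlier_pvalue(scores, m, metric).p_value
        out[m] = cache[v]
    return pd.Series(out, name=f"{metric or 'score'}_p")


def select_significant(
    table: pd.DataFrame, metric: str, alpha: float = 0.05, within: list[str] | None = None
) -> list[str]:
    """miRNAs whose ``metric`` outlier p is below ``alpha`` (strict).

    ``table`` is indexed by miRNA with columns ``<metric>`` and
    ``<metric>_p``. The result is ordered by descending score (ties by
    miRNA ID); ``within`` restricts the candidates without changing the
    p-values, which were computed against the full background.
    """
    pcol = f"{metric}_p"
    if pcol not in table.columns or table[pcol].isna().any():
        raise ValueError(f"outlier p-values for '{metric}' not computed")
    sub = table if within is None else table.loc[[m for m in within if m in table.index]]
    kept = sub[sub[pcol] < alpha]
    order = kept.sort_values(
        by=[metric], ascending=False, kind="mergesort"
    )  # mergesort: stable, ties keep index order
    return list(order.index)
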