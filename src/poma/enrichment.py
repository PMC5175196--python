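"""Over-representation analysis of gene sets with Bonferroni correction.

For a query gene set (typically the pooled targets of the candidate
miRNAs) and a catalog of named gene sets (GMT), each set is tested for
over-representation with the one-sided hypergeometric tail (Fisher exact,
"greater") within a declared universe — by default all genes of the
reference network. Raw p-values are Bonferroni-adjusted by the number of
sets actually tested (those with at least one member in the universe) and
sets with adjusted p < 0.05 are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from scipy import stats

from .io import GeneSet, ValidationError

__all__ = ["EnrichmentResult", "hypergeom_tail", "enrich", "write_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    universe_size: int  # N
    set_size: int  # K (members in the universe)
    query_size: int  # n (query members in the universe)
    overlap: int  # k
    raw_p: float
    adj_p: float
    significant: bool


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and max(K, n) <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: GeneSet, collection: list[GeneSet], universe: GeneSet, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Test every catalog set for over-representation of ``query`` genes.

    Query members outside the universe are dropped (they cannot be drawn);
    the Bonferroni multiplier is the number of sets with >= 1 universe
    member. Results are sorted by ascending adjusted p, ties by set name.
    """
    uni = universe.members
    if not uni:
        raise ValidationError("empty universe")
    q = query.members & uni
    if not q:
        raise ValidationError("query has no members inside the universe")
    N, n = len(uni), len(q)
    testable = [(s, s.members & uni) for s in collection]
    testable = [(s, mem) for s, mem in testable if mem]
    m = len(testable)
    results = []
    for s, mem in testable:
        K, k = len(mem), len(mem & q)
        raw_p = hypergeom_tail(N, K, n, k)
        adj_p = min(1.0, raw_p * m)
        results.append(
            EnrichmentResult(s.name, N, K, n, k, raw_p, adj_p, adj_p < alpha)
        )
    results.sort(key=lambda r: (r.adj_p, r.raw_p, r.set_name))
    return results


def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    """Write an enrichment report TSV (set, N, K, n, k, raw_p, adj_p, significant)."""
    with open(Path(path), "w") as fh:
        fh.write("set\tN\tK\tn\tk\traw_p\tadj_p\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.universe_size}\t{r.set_size}\t{r.query_size}\t"
                f"{r.overlap}\t{r.raw_p:.10g}\t{r.adj_p:.10g}\t{r.significant}\n"
            )
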