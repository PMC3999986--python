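"""Statistical tests shared across the pipeline.

Exact 2x2 Fisher test, hypergeometric over-representation, exact binomial
test, Wilcoxon rank-sum with tie handling, Benjamini-Hochberg adjustment,
and a generic gene-set enrichment engine over term -> gene maps.

Distribution tails are delegated to scipy; this module fixes the
conventions (sidedness, tie handling, BH step-up) used everywhere else in
the package so that every caller agrees on them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "fisher_exact_2x2",
    "hypergeom_enrichment",
    "binomial_test",
    "wilcoxon_ranksum",
    "bh_adjust",
    "term_enrichment",
    "read_gmt",
    "read_gene_term_tsv",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 table; ``a`` is the in-set AND in-condition cell."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table cells must be non-negative")

    @property
    def odds_ratio(self) -> float:
        if self.b == 0 or self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes annotated to the term
    K: int  # universe genes annotated to the term
    n: int  # query size
    N: int  # universe size
    p_value: float
    adj_p: float = float("nan")


def fisher_exact_2x2(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Exact Fisher test on a 2x2 table.

    The two-sided p-value uses the probability-mass convention: the sum of
    hypergeometric point probabilities no larger than that of the observed
    table. Returns ``(p_value, odds_ratio)`` with the sample odds ratio
    a*d / (b*c).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(
        alternative
    )
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    res = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alt
    )
    return float(res.pvalue), table.odds_ratio


def hypergeom_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Over-representation tail P[X >= k], X ~ Hypergeom(N, K, n).

    ``k`` of ``n`` query genes hit a term covering ``K`` of ``N`` universe
    genes.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError("term size and query size cannot exceed the universe")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def binomial_test(
    k: int, n: int, p0: float = 0.5, alternative: str = "two_sided"
) -> float:
    """Exact binomial tail probability.

    Two-sided: sum of outcome probabilities no larger than the observed
    point probability (the scipy/R convention).
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n; got k={k}, n={n}")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    return float(stats.binomtest(k, n, p0, alternative=alt).pvalue)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration of group labelings.

    Only intended for small samples (|x| + |y| <= ~12); mid-ranks are used
    so ties are handled consistently with the asymptotic path.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    observed = ranks[:nx].sum()
    total = 0
    as_extreme = 0
    idx = range(len(pooled))
    mean_sum = ranks.sum() * nx / len(pooled)
    obs_dev = abs(observed - mean_sum)
    for combo in itertools.combinations(idx, nx):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean_sum) >= obs_dev - 1e-12:
            as_extreme += 1
    return as_extreme / total


def wilcoxon_ranksum(
    x: Sequence[float],
    y: Sequence[float],
    continuity: bool = True,
    exact: bool | None = None,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Ties get mid-ranks with a tie-corrected variance; the default path is
    the normal approximation with continuity correction. For tiny samples
    (``len(x) + len(y) <= 12``, or ``exact=True``) the p-value is computed
    by full permutation enumeration instead.

    Returns ``(p_value, U_statistic)`` where U counts (x > y) pairs plus
    half the ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_stat = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0, float(u_stat)
    if exact is None:
        exact = len(x) + len(y) <= 12
    if exact:
        return _exact_ranksum_p(x, y), float(u_stat)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", use_continuity=continuity, method="asymptotic"
    )
    return float(res.pvalue), float(u_stat)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def term_enrichment(
    query_genes: Iterable[str],
    universe_genes: Iterable[str],
    term_map: Mapping[str, set[str]] | Mapping[str, tuple[str, set[str]]],
    method: str = "hypergeom",
) -> list[EnrichmentResult]:
    """Test each term for over-representation in the query gene set.

    ``term_map`` maps a term id either to its gene set or to a
    ``(description, gene set)`` pair (GMT style). Genes outside the
    universe are ignored; terms with no universe gene are skipped. BH
    adjustment is applied across all tested terms and results come back
    sorted by adjusted p.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query_genes) & universe
    if set(query_genes) - universe:
        missing = len(set(query_genes) - universe)
        raise ValueError(f"{missing} query genes are not in the universe")
    if method not in {"hypergeom", "fisher"}:
        raise ValueError(f"unknown method {method!r}")

    n, N = len(query), len(universe)
    results: list[EnrichmentResult] = []
    for term_id, value in term_map.items():
        if isinstance(value, tuple):
            name, genes = value
        else:
            name, genes = term_id, value
        term_genes = set(genes) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        if method == "hypergeom":
            p = hypergeom_enrichment(k, K, n, N)
        else:
            p, _ = fisher_exact_2x2(
                ContingencyTable2x2(k, n - k, K - k, N - n - K + k),
                alternative="greater",
            )
        results.append(EnrichmentResult(term_id, name, k, K, n, N, p))

    adj = bh_adjust([r.p_value for r in results])
    results = [
        EnrichmentResult(r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p_value, a)
        for r, a in zip(results, adj)
    ]
    results.sort(key=lambda r: (r.adj_p, r.p_value, r.term_id))
    return results


def read_gmt(path: str) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    out: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            out[fields[0]] = (fields[1], set(fields[2:]))
    return out


def read_gene_term_tsv(path: str) -> dict[str, set[str]]:
    """Read a 2-column gene<TAB>term file into a term -> gene-set map."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(term, set()).add(gene)
    return out
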