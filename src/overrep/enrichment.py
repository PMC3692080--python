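"""Over-representation tests on 2x2 overlap tables.

For each gene set the overlap with the query is summarized by four counts:
N (background size), n (query genes in the background), K (set genes in the
background), and k (query/set overlap within the background).  The default
test is the one-sided Fisher exact test, whose upper tail equals the
hypergeometric survival function

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n),

i.e. the probability of drawing at least k set genes when n genes are
sampled from the background without replacement.  A chi-square test (with
optional Yates continuity correction) is offered as the large-sample
alternative.  Genes outside the background are dropped from both the query
and the sets before counting, and the drops are reported in a QueryAudit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .geneset_io import Background, Category, GeneSet, GeneSetCollection

__all__ = [
    "ContingencyTable",
    "QueryAudit",
    "EnrichmentResult",
    "TestMethod",
    "build_table",
    "hypergeom_test",
    "fisher_exact_test",
    "chisq_test",
    "run_enrichment",
]


class TestMethod(str, Enum):
    fisher = "fisher"
    hypergeom = "hypergeom"
    chisq = "chisq"


@dataclass(frozen=True)
class ContingencyTable:
    """Overlap counts N, n, K, k for one gene set against one query.

    N: background size; n: query genes in background; K: set genes in
    background; k: overlap of query and set within the background.
    """

    N: int
    n: int
    K: int
    k: int

    def __post_init__(self) -> None:
        for fname in ("N", "n", "K", "k"):
            v = getattr(self, fname)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{fname} must be a non-negative integer, got {v!r}")
        if self.n > self.N or self.K > self.N:
            raise ValueError(f"margins exceed background: n={self.n}, K={self.K}, N={self.N}")
        if self.k > min(self.n, self.K):
            raise ValueError(f"k={self.k} exceeds min(n, K)={min(self.n, self.K)}")
        if self.k < max(0, self.n + self.K - self.N):
            raise ValueError(f"k={self.k} below the table's support")

    def as_2x2(self) -> np.ndarray:
        """Cells: [[k, n-k], [K-k, N-n-K+k]] (query x set membership)."""
        return np.array(
            [[self.k, self.n - self.k],
             [self.K - self.k, self.N - self.n - self.K + self.k]]
        )

    @property
    def fold_enrichment(self) -> float:
        """(k/n) / (K/N); NaN when a margin is zero."""
        if self.n == 0 or self.K == 0:
            return float("nan")
        return (self.k / self.n) / (self.K / self.N)


@dataclass
class QueryAudit:
    """Bookkeeping for submitted query IDs: redundancy and background drops."""

    raw_count: int
    nonredundant: list[str]
    dropped_not_in_background: list[str]

    @property
    def redundancy(self) -> int:
        return self.raw_count - len(self.nonredundant)

    @property
    def in_background_count(self) -> int:
        return len(self.nonredundant) - len(self.dropped_not_in_background)


@dataclass
class EnrichmentResult:
    """Per-set outcome: the table, overlap members, raw (and adjusted) p."""

    set_name: str
    category: Category
    description: str
    table: ContingencyTable
    overlap_members: frozenset[str]
    p_raw: float
    test: TestMethod
    p_adjusted: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError(f"p_raw={self.p_raw} outside [0, 1]")
        if len(self.overlap_members) != self.table.k:
            raise ValueError("overlap member count disagrees with k")

    @property
    def fold_enrichment(self) -> float:
        return self.table.fold_enrichment


def build_table(
    query: Iterable[str], geneset: GeneSet, background: Background
) -> tuple[ContingencyTable, frozenset[str]]:
    """Intersect query and set with the background and count N, n, K, k.

    Raises ``ValueError`` when the query has no gene in the background
    (usually a wrong ID type or the wrong background).
    """
    bg = background.genes
    q = frozenset(query) & bg
    if not q:
        raise ValueError(
            "no query gene found in the background; check that the query ID "
            "type matches the background/gene-set ID space"
        )
    s = geneset.members & bg
    overlap = q & s
    table = ContingencyTable(N=len(bg), n=len(q), K=len(s), k=len(overlap))
    return table, overlap


def hypergeom_test(table: ContingencyTable) -> float:
    """One-sided over-representation p: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(table.k - 1, table.N, table.K, table.n))


def _hypergeom_sf_vec(k: np.ndarray, N: int, K: np.ndarray, n: int) -> np.ndarray:
    return stats.hypergeom.sf(k - 1, N, K, n)


def fisher_exact_test(table: ContingencyTable, sided: str = "greater") -> float:
    """Fisher exact test on the 2x2 table.

    ``sided='greater'`` (the default, over-representation) is exactly the
    hypergeometric upper tail.  ``'two_sided'`` sums all tables with the
    observed margins whose point probability does not exceed the observed
    one.
    """
    if sided == "greater":
        return hypergeom_test(table)
    if sided == "two_sided":
        return float(stats.fisher_exact(table.as_2x2(), alternative="two-sided")[1])
    raise ValueError(f"sided must be 'greater' or 'two_sided', got {sided!r}")


def chisq_test(table: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square on the 2x2 table, 1 df, optional Yates correction.

    Emits a ``UserWarning`` when any expected cell count is below 5 (the
    exact tests should be preferred there).  Raises on a zero margin, where
    the statistic is undefined.
    """
    obs = table.as_2x2()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square statistic undefined: a table margin is zero")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (expected < 5).any():
        warnings.warn(
            "chi-square approximation unreliable: expected cell count < 5; "
            "prefer the exact tests", UserWarning, stacklevel=2)
    stat, p, _, _ = stats.chi2_contingency(obs, correction=yates)
    return float(p)


_CATEGORY_ORDER = {c: i for i, c in enumerate(Category)}


def run_enrichment(
    query: Sequence[str],
    collection: GeneSetCollection,
    background: Background,
    test: TestMethod | str = TestMethod.fisher,
    categories: Optional[Iterable[Category | str]] = None,
    min_set_size: int = 2,
    max_set_size: Optional[int] = None,
    sided: str = "greater",
    yates: bool = True,
) -> tuple[list[EnrichmentResult], QueryAudit]:
    """Test every gene set of the selected categories against the query.

    Sets are pre-filtered to ``min_set_size <= |set & background| <=
    max_set_size`` (defaults 2 and |background|).  k=0 sets are retained
    with p=1 so the annotation table stays complete; the significance
    cut-off is applied downstream.  Results are ordered by (category, name)
    and carry raw p only — adjustment is a separate stage.
    """
    test = TestMethod(test)
    if max_set_size is None:
        max_set_size = len(background)
    raw = list(query)
    nonredundant = list(dict.fromkeys(raw))
    dropped = [g for g in nonredundant if g not in background.genes]
    audit = QueryAudit(raw_count=len(raw), nonredundant=nonredundant,
                       dropped_not_in_background=dropped)
    if categories is not None:
        collection = collection.filter_categories(categories)
    kept: list[tuple[GeneSet, ContingencyTable, frozenset[str]]] = []
    for s in collection:
        table, overlap = build_table(nonredundant, s, background)
        if not min_set_size <= table.K <= max_set_size:
            continue
        kept.append((s, table, overlap))
    if test in (TestMethod.fisher, TestMethod.hypergeom) and sided == "greater" and kept:
        # vectorized hypergeometric tail over all kept sets
        ks = np.array([t.k for _, t, _ in kept])
        Ks = np.array([t.K for _, t, _ in kept])
        N = len(background.genes)
        n = kept[0][1].n
        pvals = _hypergeom_sf_vec(ks, N, Ks, n)
    else:
        pvals = np.array([
            fisher_exact_test(t, sided=sided) if test == TestMethod.fisher
            else hypergeom_test(t) if test == TestMethod.hypergeom
            else chisq_test(t, yates=yates)
            for _, t, _ in kept
        ])
    results = [
        EnrichmentResult(
            set_name=s.name, category=s.category, description=s.description,
            table=t, overlap_members=overlap,
            p_raw=min(1.0, max(0.0, float(p))), test=test,
        )
        for (s, t, overlap), p in zip(kept, pvals)
    ]
    results.sort(key=lambda r: (_CATEGORY_ORDER[r.category], r.set_name))
    return results, audit
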