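"""Result-page artifacts: summary table, gene-annotation table, basic
summary text, annotation-coverage statistics, and bar-chart data.

Everything is emitted as TSV (plus one plain-text block); the tables are
plain pandas DataFrames so downstream tooling can consume them directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .enrichment import EnrichmentResult, QueryAudit
from .geneset_io import Background, Category, GeneSetCollection
from .multiple_testing import select_significant

__all__ = [
    "CoverageReport",
    "build_summary",
    "build_annotation",
    "basic_summary",
    "coverage",
    "bar_chart_data",
    "write_tsv",
]

SUMMARY_COLUMNS = ["set_name", "description", "category", "overlap",
                   "p_raw", "p_adjusted"]

#: floor applied to p_adjusted == 0 before taking -log10 (keeps charts finite)
LOG_FLOOR = 1e-300


def build_summary(
    results: Sequence[EnrichmentResult], cutoff: float = 0.05
) -> pd.DataFrame:
    """Significant sets as a six-column table, most significant first."""
    rows = [
        (r.set_name, r.description, r.category.value, r.table.k,
         r.p_raw, r.p_adjusted)
        for r in select_significant(results, cutoff)
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def build_annotation(
    query: Sequence[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Gene-set membership of each query gene, against the full collection.

    One row per non-redundant query gene; genes in no set keep empty
    membership columns.  Set names within a row are sorted, and the
    ``categories`` column is aligned with ``gene_sets``.
    """
    rows = []
    for gene in dict.fromkeys(query):
        hits = sorted(
            (s.name, s.category.value) for s in collection if gene in s.members
        )
        rows.append((
            gene,
            ";".join(name for name, _ in hits),
            ";".join(cat for _, cat in hits),
            len(hits),
        ))
    return pd.DataFrame(rows, columns=["gene", "gene_sets", "categories", "n_sets"])


def basic_summary(
    audit: QueryAudit, categories: Sequence[Category | str]
) -> str:
    """Plain-text run summary: redundancy, background drops, categories."""
    cats = ", ".join(Category(c).value for c in categories)
    lines = [
        f"Submitted IDs: {audit.raw_count}",
        f"Non-redundant IDs: {len(audit.nonredundant)}",
        f"Redundant IDs removed: {audit.redundancy}",
        f"IDs not in background (dropped): {len(audit.dropped_not_in_background)}",
    ]
    if audit.dropped_not_in_background:
        lines.append("Dropped IDs: " + ", ".join(audit.dropped_not_in_background))
    lines.append(f"IDs used for enrichment: {audit.in_background_count}")
    lines.append(f"Categories analyzed: {cats}")
    return "\n".join(lines) + "\n"


@dataclass
class CoverageReport:
    """Fraction of background genes annotated by >=1 set, per category and overall."""

    background_size: int
    per_category: dict[str, int]  # category -> annotated gene count
    overall: int                  # |union across categories|

    def percentage(self, category: Optional[str] = None) -> float:
        count = self.overall if category is None else self.per_category.get(category, 0)
        return 100.0 * count / self.background_size

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (cat, count, self.background_size,
             round(100.0 * count / self.background_size, 1))
            for cat, count in sorted(self.per_category.items())
        ]
        rows.append(("overall", self.overall, self.background_size,
                     round(self.percentage(), 1)))
        return pd.DataFrame(
            rows, columns=["category", "annotated", "background", "percent"])


def coverage(
    collection: GeneSetCollection,
    background: Background,
    categories: Optional[Iterable[Category | str]] = None,
) -> CoverageReport:
    """Count background genes covered by each category's sets and by their union."""
    if categories is None:
        categories = list(Category)
    cats = [Category(c) for c in categories]
    per_cat: dict[str, int] = {}
    union: set[str] = set()
    for cat in cats:
        covered: set[str] = set()
        for s in collection:
            if s.category == cat:
                covered |= s.members & background.genes
        per_cat[cat.value] = len(covered)
        union |= covered
    return CoverageReport(
        background_size=len(background.genes),
        per_category=per_cat,
        overall=len(union),
    )


def bar_chart_data(
    results: Sequence[EnrichmentResult],
    cutoff: float = 0.05,
    top_k: int = 10,
) -> pd.DataFrame:
    """Top-k significant sets per category with -log10 adjusted p.

    Adjusted p-values of exactly zero (possible only through underflow)
    are floored at 1e-300 so the chart values stay finite.
    """
    rows = []
    per_cat_count: dict[str, int] = {}
    for r in select_significant(results, cutoff):
        cat = r.category.value
        if per_cat_count.get(cat, 0) >= top_k:
            continue
        per_cat_count[cat] = per_cat_count.get(cat, 0) + 1
        p = max(r.p_adjusted, LOG_FLOOR)
        rows.append((r.set_name, cat, -math.log10(p)))
    return pd.DataFrame(rows, columns=["set_name", "category", "neg_log10_p_adjusted"])


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV writer (Unix newlines, no index, repr floats)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
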