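"""Multiple-testing corrections across the tested gene-set family.

Six procedures are provided: Bonferroni, Holm (step-down), Hochberg
(step-up), Hommel (Simes-based closed testing), Benjamini-Hochberg (FDR
under independence/PRDS) and Benjamini-Yekutieli (FDR under arbitrary
dependence; BH inflated by c(m) = sum_{i=1}^m 1/i).  BY is the default
because the gene-set family is large and heavily overlapping, so arbitrary
dependence is the honest assumption.  All procedures return adjusted
p-values in the input order, each >= the raw p and capped at 1.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .enrichment import EnrichmentResult

__all__ = ["AdjustMethod", "adjust", "adjust_results", "select_significant"]


class AdjustMethod(str, Enum):
    bonferroni = "bonferroni"
    holm = "holm"
    hochberg = "hochberg"
    hommel = "hommel"
    bh = "bh"
    by = "by"


def _validate(p_raw: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be one-dimensional")
    if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _holm(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.maximum.accumulate((m - np.arange(m)) * p[order])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(-p, kind="stable")  # descending
    adj = np.minimum.accumulate(np.arange(1, m + 1) * p[order])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _hommel(p: np.ndarray) -> np.ndarray:
    # closed-testing shortcut over Simes local tests (Wright 1992)
    m = p.size
    if m == 1:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q = np.full(m, np.min(m * ps / np.arange(1, m + 1)))
    pa = q.copy()
    for j in range(m - 1, 1, -1):
        lo = np.arange(m - j + 1)          # smallest m-j+1 p-values
        hi = np.arange(m - j + 1, m)       # largest j-1 p-values
        q1 = np.min(j * ps[hi] / np.arange(2, j + 1))
        q[lo] = np.minimum(j * ps[lo], q1)
        q[hi] = q[m - j]
        pa = np.maximum(pa, q)
    out = np.empty(m)
    out[order] = np.maximum(pa, ps)
    return out


def _step_up_fdr(p: np.ndarray, scale: float) -> np.ndarray:
    m = p.size
    order = np.argsort(-p, kind="stable")  # descending
    mult = scale * m / np.arange(m, 0, -1)
    adj = np.minimum.accumulate(mult * p[order])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def adjust(p_raw: Sequence[float], method: AdjustMethod | str = AdjustMethod.by) -> np.ndarray:
    """Adjust raw p-values; output positions match input positions."""
    method = AdjustMethod(method)
    p = _validate(p_raw)
    m = p.size
    if m == 0:
        return p
    if method == AdjustMethod.bonferroni:
        return np.minimum(m * p, 1.0)
    if method == AdjustMethod.holm:
        return _holm(p)
    if method == AdjustMethod.hochberg:
        return _hochberg(p)
    if method == AdjustMethod.hommel:
        return _hommel(p)
    if method == AdjustMethod.bh:
        return _step_up_fdr(p, 1.0)
    if method == AdjustMethod.by:
        c_m = float(np.sum(1.0 / np.arange(1, m + 1)))
        return _step_up_fdr(p, c_m)
    raise AssertionError(f"unhandled method {method}")


def adjust_results(
    results: Sequence[EnrichmentResult],
    method: AdjustMethod | str = AdjustMethod.by,
    per_category: bool = False,
) -> list[EnrichmentResult]:
    """Fill ``p_adjusted`` on enrichment results, in place, and return them.

    The family is all tested sets pooled across categories (default), or
    one family per category with ``per_category=True``.
    """
    results = list(results)
    if per_category:
        groups: dict[str, list[int]] = {}
        for i, r in enumerate(results):
            groups.setdefault(r.category.value, []).append(i)
        families = list(groups.values())
    else:
        families = [list(range(len(results)))]
    for idx in families:
        if not idx:
            continue
        p_adj = adjust([results[i].p_raw for i in idx], method)
        for i, pa in zip(idx, p_adj):
            results[i].p_adjusted = float(pa)
    return results


def select_significant(
    results: Iterable[EnrichmentResult], cutoff: float = 0.05
) -> list[EnrichmentResult]:
    """Keep results with p_adjusted < cutoff, most significant first.

    Ties on p_adjusted break by larger overlap k, then set name.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    picked = []
    for r in results:
        if r.p_adjusted is None:
            raise ValueError(f"result {r.set_name!r} has no adjusted p-value")
        if r.p_adjusted < cutoff:
            picked.append(r)
    picked.sort(key=lambda r: (r.p_adjusted, -r.table.k, r.set_name))
    return picked
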