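"""Hypergeometric over-representation analysis of the major hubs.

For a query set of n genes drawn from a universe of N genes, a pathway
with K annotated members and k of them in the query has upper-tail
p-value  P(X >= k)  under  X ~ Hypergeometric(N, K, n)  — the classic
over-representation test.  Benjamini–Hochberg step-up q-values are
reported alongside raw p, and the significance filter can use either
(the original screen used raw p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PathwayAnnotation


@dataclass(frozen=True)
class PathwayResult:
    """One pathway's over-representation outcome."""

    name: str
    K: int          # pathway size in universe
    n: int          # query size in universe
    k: int          # overlap
    N: int          # universe size
    p_value: float
    q_value: float
    overlap_ids: tuple[str, ...]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); exactly 1 when k == 0."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, original order restored."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    query_ids: Iterable[str],
    annotation: PathwayAnnotation,
    universe: Iterable[str] | None = None,
) -> list[PathwayResult]:
    """Over-representation of a query set against every annotated pathway.

    ``universe`` defaults to the annotation's own universe; passing the
    profiled network's node set restricts both pathways and query to genes
    the analysis could actually have selected.  Pathways empty after
    restriction are skipped.
    """
    uni = frozenset(universe) if universe is not None else annotation.universe
    if not uni:
        raise ValueError("empty universe")
    query = frozenset(query_ids) & uni
    if not query:
        raise ValueError("query does not intersect the universe")
    N, n = len(uni), len(query)
    rows = []
    for name in sorted(annotation.pathways):
        members = annotation.pathways[name] & uni
        K = len(members)
        if K == 0:
            continue
        overlap = members & query
        k = len(overlap)
        rows.append((name, K, k, tuple(sorted(overlap)), hypergeom_upper_tail(k, N, K, n)))
    q_values = adjust_bh([r[4] for r in rows])
    return [
        PathwayResult(name=name, K=K, n=n, k=k, N=N, p_value=p, q_value=float(q), overlap_ids=overlap)
        for (name, K, k, overlap, p), q in zip(rows, q_values)
    ]


def significant_pathways(
    results: Sequence[PathwayResult],
    alpha: float = 0.05,
    use_q: bool = False,
) -> list[PathwayResult]:
    """Pathways with p < alpha (or q < alpha), sorted by ascending p."""
    keep = [r for r in results if (r.q_value if use_q else r.p_value) < alpha]
    return sorted(keep, key=lambda r: (r.p_value, -r.k, r.name))


def top_pathways(
    results: Sequence[PathwayResult],
    k: int = 10,
    alpha: float = 0.05,
    use_q: bool = False,
) -> list[PathwayResult]:
    """The k most significant pathways (smallest p; ties -> larger overlap, then name)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return significant_pathways(results, alpha=alpha, use_q=use_q)[:k]


def assign_modules(
    significant: Sequence[PathwayResult],
    category_map: Mapping[str, str],
) -> dict[str, dict]:
    """Group significant pathways (and their overlapping hubs) by category.

    Pathways absent from ``category_map`` land in ``uncategorized``.  A gene
    appearing in pathways of several categories is listed in each; the
    returned record carries both member lists and multi-membership counts.
    """
    modules: dict[str, dict] = {}
    for result in significant:
        category = category_map.get(result.name, "uncategorized")
        module = modules.setdefault(category, {"pathways": [], "members": set()})
        module["pathways"].append(result.name)
        module["members"].update(result.overlap_ids)
    membership: dict[str, int] = {}
    for module in modules.values():
        for member in module["members"]:
            membership[member] = membership.get(member, 0) + 1
    return {
        category: {
            "pathways": sorted(module["pathways"]),
            "members": sorted(module["members"]),
            "n_pathways": len(module["pathways"]),
            "n_members": len(module["members"]),
            "n_multi_category_members": sum(
                1 for member in module["members"] if membership[member] > 1
            ),
        }
        for category, module in modules.items()
    }


def results_frame(results: Sequence[PathwayResult]) -> pd.DataFrame:
    rows = [
        {
            "pathway": r.name, "K": r.K, "n": r.n, "k": r.k, "N": r.N,
            "p_value": r.p_value, "q_value": r.q_value,
            "overlap": ";".join(r.overlap_ids),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["pathway", "K", "n", "k", "N", "p_value", "q_value", "overlap"])
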