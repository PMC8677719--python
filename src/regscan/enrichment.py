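"""Category overrepresentation by the one-sided hypergeometric test.

For a selected gene set of size n drawn from a universe of size N, a category
with K members in the universe and k among the selected genes gets

    p = P(X >= k),  X ~ Hypergeom(N, K, n)
    fold enrichment = (k/n) / (K/N)

with Benjamini-Hochberg adjustment across categories.  This is a generic
replacement for web-service GO analysis; no ontology structure is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    category_id: str
    k: int          # selected genes in the category
    K: int          # category size in the universe
    n: int          # selected set size
    N: int          # universe size
    p_value: float
    bh_adjusted_p: float
    fold_enrichment: float

    def __post_init__(self):
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


def categories_from_map(category_map: pd.DataFrame) -> dict[str, set[str]]:
    """category_id -> set of gene ids, from the two-column map table."""
    return {cat: set(group["gene_id"])
            for cat, group in category_map.groupby("category_id")}


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    categories: Mapping[str, set[str]] | pd.DataFrame,
) -> list[EnrichmentResult]:
    """Per-category overrepresentation of ``selected`` within ``universe``.

    Category members outside the universe are ignored for counting; selected
    genes outside the universe are an error.
    """
    selected = set(selected)
    universe = set(universe)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)[:5]}")
    if isinstance(categories, pd.DataFrame):
        categories = categories_from_map(categories)
    N, n = len(universe), len(selected)
    results = []
    for cat_id in sorted(categories):
        members = categories[cat_id] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        p = hypergeometric_p(k, K, n, N)
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        results.append(EnrichmentResult(cat_id, k, K, n, N, p, bh_adjusted_p=p,
                                        fold_enrichment=fold))
    adjusted = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adjusted):
        r.bh_adjusted_p = q
    return results


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = list(p_values)
    if not p:
        return []
    if any(x < 0 or x > 1 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    return df.sort_values(["bh_adjusted_p", "p_value", "category_id"]).reset_index(drop=True)


def write_results(results: list[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
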