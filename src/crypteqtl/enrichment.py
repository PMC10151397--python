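"""Generic hypergeometric category enrichment with size/overlap filters.

Categories (gene classes, GO terms, pathway memberships, TF-binding
target sets, ...) are supplied as plain tables; categories are tested
only when the category has more than 3 members and shares more than 2
genes with the query, and p-values are Bonferroni-corrected over the
number of categories actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .exceptions import ParameterError, ValidationError


@dataclass(frozen=True)
class CategoryTable:
    """Long-format category membership: one row per (category, gene)."""

    frame: pd.DataFrame  # columns category_id, source, gene_id

    def __post_init__(self):
        missing = {"category_id", "gene_id"} - set(self.frame.columns)
        if missing:
            raise ValidationError(f"category table lacks columns {sorted(missing)}")

    def members(self) -> dict[str, set]:
        return {
            str(cat): set(grp["gene_id"].astype(str))
            for cat, grp in self.frame.groupby("category_id")
        }


@dataclass
class EnrichmentResult:
    category_id: str
    category_size: int
    query_size: int
    overlap: int
    p_value: float
    p_adj: float  # Bonferroni over tested categories


def read_categories(path) -> CategoryTable:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return CategoryTable(frame=frame)


def enrich(
    query: set,
    categories: CategoryTable,
    universe: set | None = None,
    min_category_size_exclusive: int = 3,
    min_overlap_exclusive: int = 2,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a gene set per category.

    Filters precede testing: only categories with size strictly above
    ``min_category_size_exclusive`` and query overlap strictly above
    ``min_overlap_exclusive`` are tested; Bonferroni multiplicity is the
    number of categories that pass both filters. When no universe is
    given it defaults to the union of all category members plus the query.
    """
    if not query:
        raise ParameterError("empty query gene set")
    members = categories.members()
    if universe is None:
        universe = set().union(*members.values(), query) if members else set(query)
    if not query <= universe:
        raise ValidationError("query genes outside the declared universe")

    query = query & universe
    candidates = []
    for cat in sorted(members):
        mem = members[cat] & universe
        k = len(mem & query)
        if len(mem) > min_category_size_exclusive and k > min_overlap_exclusive:
            candidates.append((cat, mem, k))
    n_tested = len(candidates)
    results = []
    for cat, mem, k in candidates:
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(mem), len(query)))
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(
                category_id=cat,
                category_size=len(mem),
                query_size=len(query),
                overlap=k,
                p_value=p,
                p_adj=min(1.0, p * n_tested),
            )
        )
    return results
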