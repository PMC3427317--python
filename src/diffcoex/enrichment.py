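"""Gene-set overlap statistics: hypergeometric P and enrichment level R.

For a universe of N genes and two sets of sizes m and n sharing k genes,
over-representation is measured by the upper-tail hypergeometric probability

    P = Σ_{i=k}^{min(m,n)} C(m, i) · C(N−m, n−i) / C(N, n)

and the enrichment level R = kN/(mn), the observed overlap relative to its
expectation mn/N under independent draws. The same machinery drives
Fisher-style gene-set enrichment with BH correction and pairwise
co-targeting matrices between transcription-factor target sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd
from scipy import stats

from .expression import benjamini_hochberg

#: Overlaps with P below this are flagged significant.
SIGNIFICANCE_LEVEL = 0.05

#: Tiers used when reporting co-targeting matrices.
COTARGET_TIERS = (1e-3, 1e-10)


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two gene sets in a common universe."""

    N: int
    m: int
    n: int
    k: int
    p_value: float
    enrichment_R: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def hypergeom_overlap(N: int, m: int, n: int, k: int) -> OverlapResult:
    """Upper-tail hypergeometric overlap probability and enrichment level.

    Computed via the survival function of the hypergeometric distribution
    (log-gamma arithmetic internally, stable for genome-scale counts).
    R = kN/(mn); R is 0 when either set is empty.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"set sizes exceed universe: N={N}, m={m}, n={n}")
    if not 0 <= k <= min(m, n):
        raise ValueError(f"overlap k={k} inconsistent with m={m}, n={n}")
    if k == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
    r = k * N / (m * n) if m and n else 0.0
    return OverlapResult(N=N, m=m, n=n, k=k, p_value=min(p, 1.0), enrichment_R=r)


def overlap_of_sets(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapResult:
    """Hypergeometric overlap of two explicit gene sets within a universe."""
    a = set_a & universe
    b = set_b & universe
    return hypergeom_overlap(len(universe), len(a), len(b), len(a & b))


def enrich_gene_sets(
    query: set[str],
    collections: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Test a query gene list against every set of a collection.

    Sets are intersected with the universe before testing; BH correction is
    applied across all sets of the collection. Returns one row per set with
    N, m, n, k, R, p and q, ordered as the collection iterates (results are
    order-invariant).
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, genes in collections.items():
        res = overlap_of_sets(set(query), set(genes), set(universe))
        rows.append(
            {
                "set": name,
                "N": res.N,
                "m": res.m,
                "n": res.n,
                "k": res.k,
                "enrichment_R": res.enrichment_R,
                "p": res.p_value,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = benjamini_hochberg(table["p"].to_numpy()) if len(table) else []
    return table


def cotarget_matrix(
    target_sets: Mapping[str, set[str]],
    universe: set[str],
    tiers: tuple[float, ...] = COTARGET_TIERS,
) -> pd.DataFrame:
    """Pairwise overlap statistics between factors' target sets.

    One row per unordered factor pair (and each factor against itself) with
    k, p, R and the significance tier reached (the smallest listed tier
    whose cutoff the p-value beats; empty string if none).
    """
    factors = list(target_sets)
    if len(factors) < 2:
        raise ValueError("need at least two factors")
    rows = []
    for fa, fb in combinations(factors, 2):
        res = overlap_of_sets(target_sets[fa], target_sets[fb], universe)
        tier = ""
        for cutoff in sorted(tiers, reverse=True):
            if res.p_value < cutoff:
                tier = f"p<{cutoff:g}"
        rows.append(
            {
                "factor_a": fa,
                "factor_b": fb,
                "N": res.N,
                "m": res.m,
                "n": res.n,
                "k": res.k,
                "enrichment_R": res.enrichment_R,
                "p": res.p_value,
                "tier": tier,
            }
        )
    return pd.DataFrame(rows)


def multi_factor_classes(
    primary_targets: set[str],
    other_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Partition a primary factor's targets by which other factors co-bind.

    Each primary target falls in exactly one class — the exact subset of
    the other factors that also bind it; classes are exclusive and their
    counts sum to the primary set size. The all-factors intersection is the
    class naming every other factor.
    """
    names = list(other_sets)
    classes: dict[tuple[str, ...], int] = {}
    for g in primary_targets:
        combo = tuple(f for f in names if g in other_sets[f])
        classes[combo] = classes.get(combo, 0) + 1
    rows = [
        {
            "cobinding": "+".join(combo) if combo else "(none)",
            "n_factors": len(combo),
            "count": count,
        }
        for combo, count in sorted(classes.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows)


def bound_by_at_least(
    primary_targets: set[str], other_sets: Mapping[str, set[str]], t: int
) -> set[str]:
    """Primary targets co-bound by at least ``t`` of the other factors."""
    return {
        g
        for g in primary_targets
        if sum(g in s for s in other_sets.values()) >= t
    }
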