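"""Cross-phenotype DEG/miRNA set overlaps.

Overlap significance is the upper-tail hypergeometric probability of seeing
at least the observed intersection when two sets of the given sizes are
drawn without replacement from a common universe of tested features.
Three-way comparisons are summarized as exact Venn region counts, and
"unique to A vs B" fractions follow the convention of reporting the
percentage relative to |A|.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Collection, Mapping

from scipy import stats


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap test between two feature sets."""

    set_a_name: str
    set_b_name: str
    size_a: int
    size_b: int
    overlap_count: int
    universe_n: int
    percent_of_smaller: float | None
    p_value: float


def overlap_test(set_a: Collection[str], set_b: Collection[str],
                 universe_n: int, name_a: str = "A", name_b: str = "B",
                 universe: Collection[str] | None = None) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two sets.

    ``p = P(X >= |A ∩ B|)`` with ``X ~ Hypergeom(universe_n, |A|, |B|)``.
    When an explicit ``universe`` is given, both sets must be contained in
    it; ``universe_n`` must always be at least ``|A ∪ B|``.
    """
    a, b = set(set_a), set(set_b)
    if universe is not None:
        uni = set(universe)
        stray = (a | b) - uni
        if stray:
            raise ValueError(f"set members outside universe: "
                             f"{sorted(stray)[:5]}")
        if universe_n != len(uni):
            raise ValueError("universe_n disagrees with explicit universe")
    if universe_n < len(a | b):
        raise ValueError(f"universe_n={universe_n} smaller than "
                         f"|A ∪ B|={len(a | b)}")
    k = len(a & b)
    # survival function at k-1 gives P(X >= k); exact summation inside scipy
    p = float(stats.hypergeom.sf(k - 1, universe_n, len(a), len(b)))
    smaller = min(len(a), len(b))
    percent = 100.0 * k / smaller if smaller else None
    return OverlapResult(set_a_name=name_a, set_b_name=name_b,
                         size_a=len(a), size_b=len(b), overlap_count=k,
                         universe_n=universe_n,
                         percent_of_smaller=percent, p_value=min(p, 1.0))


def all_pairwise_overlaps(sets: Mapping[str, Collection[str]],
                          universe_n: int) -> list[OverlapResult]:
    """Overlap tests for every unordered pair of named sets."""
    return [overlap_test(sets[na], sets[nb], universe_n, na, nb)
            for na, nb in combinations(sets, 2)]


def venn_partition(sets: Mapping[str, Collection[str]]) -> dict[str, int]:
    """Exact disjoint-region counts for two or three named sets.

    Region keys join the member set names with ``&`` (e.g. ``"ADU&ADT"``
    for elements in exactly those two sets).  Counts sum to the union size.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_partition supports 2 or 3 sets")
    names = list(sets)
    as_sets = {n: set(sets[n]) for n in names}
    universe = set().union(*as_sets.values())
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts["&".join(combo)] = 0
    for element in universe:
        members = [n for n in names if element in as_sets[n]]
        counts["&".join(members)] += 1
    return counts


def unique_fraction(set_a: Collection[str], set_b: Collection[str]
                    ) -> tuple[int, float | None]:
    """Count and percentage of A's members absent from B.

    The percentage denominator is |A|; for an empty A it is undefined and
    reported as None.
    """
    a, b = set(set_a), set(set_b)
    unique = len(a - b)
    percent = 100.0 * unique / len(a) if a else None
    return unique, percent
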