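"""Direction-pattern (dynamic) clustering of the DEG union.

Every gene differentially expressed in at least one patient phenotype gets
a three-letter pattern over (ADU, ADT, ID): letter i is U when the gene's
log2 fold change vs HC in that phenotype is positive, else D (an exact zero
counts as U; see below).  The 8 possible patterns split into three dynamic
groups:

* group 1 — same direction throughout (UUU, DDD): persistent changes;
* group 2 — flipped only in inactive disease (UUD, DDU): late response;
* group 3 — flipped in treated-active disease (UDD, DUU, UDU, DUD): early
  response.

UUU/DDD genes whose absolute fold change in ID is strictly smaller than in
ADU attenuate toward normal and are refined into sub-clusters written with
a lower-case third letter (UUu, DDd).

Significance in a given phenotype is not required for its letter — the
union gene carries a full triple of fold-change signs regardless of which
contrasts called it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import CASE_PHENOTYPES

logger = logging.getLogger(__name__)

#: All 8 possible direction patterns, canonical order.
ALL_PATTERNS = ("UUU", "UUD", "UDU", "UDD", "DUU", "DUD", "DDU", "DDD")

_GROUP_OF = {"UUU": 1, "DDD": 1, "UUD": 2, "DDU": 2,
             "UDD": 3, "DUU": 3, "UDU": 3, "DUD": 3}


@dataclass(frozen=True)
class PatternAssignment:
    """One gene's direction pattern across (ADU, ADT, ID)."""

    gene_id: str
    pattern: str
    subpattern: str
    log2fc: tuple[float, float, float]
    group: int


def union_degs(deg_lists: Iterable[Iterable[str]]) -> list[str]:
    """Sorted union of per-contrast DEG lists."""
    out: set[str] = set()
    for lst in deg_lists:
        out.update(lst)
    return sorted(out)


def assign_pattern(gene_id: str,
                   log2fc_triple: Sequence[float]) -> PatternAssignment:
    """Pattern, sub-pattern and dynamic group from a fold-change triple
    ordered (ADU, ADT, ID)."""
    if len(log2fc_triple) != 3:
        raise ValueError("need a log2fc triple over (ADU, ADT, ID)")
    fc = tuple(float(x) for x in log2fc_triple)
    if any(x != x or x in (float("inf"), float("-inf")) for x in fc):
        raise ValueError(f"non-finite log2fc for {gene_id!r}")
    letters = []
    for x in fc:
        if x == 0:
            logger.warning("gene %s has log2fc exactly 0; letter U by "
                           "convention", gene_id)
        letters.append("U" if x >= 0 else "D")
    pattern = "".join(letters)
    subpattern = pattern
    if pattern in ("UUU", "DDD") and abs(fc[2]) < abs(fc[0]):
        subpattern = pattern[:2] + pattern[2].lower()
    return PatternAssignment(gene_id=gene_id, pattern=pattern,
                             subpattern=subpattern, log2fc=fc,
                             group=_GROUP_OF[pattern])


def assign_patterns(de_results: Mapping[str, pd.DataFrame],
                    genes: Iterable[str]) -> pd.DataFrame:
    """Pattern assignments for ``genes`` from per-contrast DE tables.

    ``de_results`` maps each patient phenotype to its DE table (indexed by
    feature with a ``log2fc`` column); every gene must appear in all three.
    Returns a DataFrame indexed by gene with columns ``pattern``,
    ``subpattern``, ``group`` and the three fold changes.
    """
    missing_contrasts = [c for c in CASE_PHENOTYPES if c not in de_results]
    if missing_contrasts:
        raise ValueError(f"missing contrasts: {missing_contrasts}")
    rows = []
    for gene in genes:
        triple = []
        for phe in CASE_PHENOTYPES:
            table = de_results[phe]
            if gene not in table.index:
                raise KeyError(f"gene {gene!r} absent from {phe} contrast")
            triple.append(float(table.loc[gene, "log2fc"]))
        pa = assign_pattern(gene, triple)
        rows.append({"gene": gene, "pattern": pa.pattern,
                     "subpattern": pa.subpattern, "group": pa.group,
                     "log2fc_ADU": triple[0], "log2fc_ADT": triple[1],
                     "log2fc_ID": triple[2]})
    df = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["pattern", "subpattern", "group",
                 "log2fc_ADU", "log2fc_ADT", "log2fc_ID"])
    return df


def cluster_census(assignments: pd.DataFrame,
                   by: str = "pattern") -> pd.DataFrame:
    """Per-cluster counts and percentages of the union total.

    ``by`` selects ``"pattern"`` (8 clusters) or ``"subpattern"`` (UUU/DDD
    split into attenuated and non-attenuated).  Percentages are of the
    union size, rounded to 2 decimals in the returned table.
    """
    if by not in ("pattern", "subpattern"):
        raise ValueError("by must be 'pattern' or 'subpattern'")
    total = len(assignments)
    counts = assignments[by].value_counts()
    rows = []
    for cluster, count in counts.items():
        rows.append({"cluster": cluster, "count": int(count),
                     "percent": round(100.0 * count / total, 2)})
    df = pd.DataFrame(rows, columns=["cluster", "count", "percent"])
    return df.sort_values(["count", "cluster"],
                          ascending=[False, True],
                          kind="stable").set_index("cluster")


def cluster_members(assignments: pd.DataFrame,
                    by: str = "subpattern") -> dict[str, list[str]]:
    """Mapping cluster label -> sorted gene list."""
    if by not in ("pattern", "subpattern"):
        raise ValueError("by must be 'pattern' or 'subpattern'")
    out: dict[str, list[str]] = {}
    for label, sub in assignments.groupby(by):
        out[str(label)] = sorted(sub.index)
    return out


def complement_pattern(pattern: str) -> str:
    """Letter-wise complement (U <-> D), preserving case of the third
    letter's attenuation marker."""
    flip = {"U": "D", "D": "U", "u": "d", "d": "u"}
    return "".join(flip[c] for c in pattern)
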