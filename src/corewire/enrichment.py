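"""Fisher's exact target-set enrichment of miRNAs and TFs per dynamic
cluster.

For a cluster of m genes and a regulator with K annotated targets inside a
universe of N tested genes, with k targets inside the cluster, the one-sided
(greater) Fisher exact p-value on the table [[k, m-k], [K-k, N-m-K+k]] is
the upper hypergeometric tail P(X >= k).  Following the low-stringency
screening design, no multiple-testing correction is applied at this stage;
results below the p threshold (default 0.01) are flagged significant.
Target-set members absent from the universe are dropped (and logged) before
testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Collection, Mapping

import pandas as pd
from scipy import stats

from .io import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

#: Default enrichment screening threshold (uncorrected).
P_THRESHOLD = 0.01


@dataclass(frozen=True)
class EnrichmentResult:
    """One regulator-vs-cluster 2x2 Fisher outcome."""

    cluster_id: str
    regulator: str
    kind: str
    family: str | None
    k: int           # cluster ∩ targets
    m: int           # cluster size within universe
    big_k: int       # target-set size within universe
    n_universe: int
    odds_ratio: float
    p_value: float


def fisher_enrichment(cluster_genes: Collection[str], gene_set: GeneSet,
                      universe: Collection[str],
                      cluster_id: str = "cluster") -> EnrichmentResult:
    """One-sided (greater) Fisher exact test of a target set against a
    cluster, both restricted to the universe."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    cluster = set(cluster_genes) & uni
    if not cluster:
        raise ValueError(f"cluster {cluster_id!r} empty within universe")
    stray = set(cluster_genes) - uni
    if stray:
        raise ValueError(f"cluster genes outside universe: "
                         f"{sorted(stray)[:5]}")
    targets = set(gene_set.members) & uni
    dropped = len(set(gene_set.members)) - len(targets)
    if dropped:
        logger.debug("%s: %d target(s) outside universe dropped",
                     gene_set.name, dropped)
    n = len(uni)
    m = len(cluster)
    big_k = len(targets)
    k = len(cluster & targets)
    # upper tail of Hypergeom(N, K, m) at k == one-sided Fisher "greater"
    p = float(stats.hypergeom.sf(k - 1, n, big_k, m))
    denom = (m - k) * (big_k - k)
    odds = (k * (n - m - big_k + k) / denom) if denom else float("inf")
    return EnrichmentResult(cluster_id=cluster_id, regulator=gene_set.name,
                            kind=gene_set.kind, family=gene_set.family,
                            k=k, m=m, big_k=big_k, n_universe=n,
                            odds_ratio=odds, p_value=min(p, 1.0))


def enrich_all(clusters: Mapping[str, Collection[str]],
               collection: GeneSetCollection,
               universe: Collection[str],
               p_threshold: float = P_THRESHOLD) -> pd.DataFrame:
    """Every (cluster, regulator) Fisher test as one tidy table.

    All tests are reported, flagged ``significant`` when p < threshold
    (strict, uncorrected), ordered by (cluster, p, regulator).  Clusters
    that are empty within the universe are skipped with a warning.
    """
    rows = []
    for cluster_id, genes in clusters.items():
        cluster_in_uni = set(genes) & set(universe)
        if not cluster_in_uni:
            logger.warning("cluster %s empty within universe; skipped",
                           cluster_id)
            continue
        for gs in collection:
            res = fisher_enrichment(genes, gs, universe,
                                    cluster_id=cluster_id)
            rows.append({
                "cluster": res.cluster_id, "regulator": res.regulator,
                "kind": res.kind, "family": res.family, "k": res.k,
                "m": res.m, "K": res.big_k, "N": res.n_universe,
                "odds_ratio": res.odds_ratio, "p": res.p_value,
                "significant": res.p_value < p_threshold})
    df = pd.DataFrame(rows, columns=["cluster", "regulator", "kind",
                                     "family", "k", "m", "K", "N",
                                     "odds_ratio", "p", "significant"])
    return df.sort_values(["cluster", "p", "regulator"],
                          kind="stable").reset_index(drop=True)


def significant_enrichments(table: pd.DataFrame) -> pd.DataFrame:
    """The flagged subset of an :func:`enrich_all` table."""
    return table[table["significant"]].reset_index(drop=True)
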