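"""Synthetic multi-phenotype expression data with fully recorded planted
truth.

The generator emulates the statistical structure of a four-phenotype
(HC, ADU, ADT, ID) microarray study on the log2 scale: each gene's value is

    baseline + phenotype effect + Normal(0, noise_sd)

where the phenotype effect is zero for healthy controls and for null genes,
and otherwise follows the gene's planted direction pattern — a triple of
log2 shifts over (ADU, ADT, ID) whose signs spell the pattern letters.
Planted anti-correlated miRNA regulators receive the letter-wise opposite
direction triple of their target cluster.  Target-set collections (with
uniform decoy sets), PPI edges among cluster genes, and qPCR Ct tables are
derived from the same truth so that every downstream stage of the pipeline
has a recoverable ground truth.

All randomness flows from the explicit ``seed`` in the config; identical
configs give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, GeneSet, GeneSetCollection, SampleDesign,
                 CASE_PHENOTYPES, PHENOTYPES)
from .patterns import ALL_PATTERNS, complement_pattern


class ConfigError(ValueError):
    """Invalid simulation configuration (message names the violated
    invariant)."""


def _default_samples() -> dict[str, int]:
    # group sizes of the mRNA-profiling cohort the pipeline is designed for
    return {"HC": 35, "ADU": 35, "ADT": 26, "ID": 14}


def _default_effects() -> dict[str, tuple[float, float, float]]:
    """|delta| = 1.5 log2 units, signs per pattern letter; same-direction
    patterns attenuate in ID (|delta_ID| = half) so that the planted truth
    contains the UUu/DDd sub-clusters."""
    out: dict[str, tuple[float, float, float]] = {}
    for pattern in ALL_PATTERNS:
        triple = tuple((1.5 if c == "U" else -1.5) for c in pattern)
        if pattern in ("UUU", "DDD"):
            triple = (triple[0], triple[1], triple[2] / 2)
        out[pattern] = triple
    return out


def _default_proportions() -> dict[str, float]:
    """20% of genes differentially expressed, split across the 8 patterns
    in the proportions observed for the DEG union of the treated-arthritis
    cohort; 80% exact nulls."""
    census = {"UUU": 45.2, "DDD": 44.96, "UUD": 5.2, "DDU": 2.87,
              "UDD": 0.77, "DUU": 0.5, "UDU": 0.45, "DUD": 0.15}
    total = sum(census.values())
    de_fraction = 0.2
    out = {p: de_fraction * v / total for p, v in census.items()}
    out["null"] = 1.0 - sum(out.values())
    return out


@dataclass
class SimulationConfig:
    """All knobs of the generator; every field has a recorded default."""

    n_genes: int = 2000
    n_mirnas: int = 200
    n_samples_per_phenotype: dict[str, int] = \
        field(default_factory=_default_samples)
    baseline_mean: float = 8.0
    noise_sd: float = 0.5
    effect_sizes: dict[str, tuple[float, float, float]] = \
        field(default_factory=_default_effects)
    pattern_proportions: dict[str, float] = \
        field(default_factory=_default_proportions)
    n_regulators_per_kind: int = 5
    n_decoys_per_kind: int = 20
    targets_per_regulator: int = 50
    regulator_cluster_bias: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_regulators_per_kind",
                     "targets_per_regulator"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_decoys_per_kind < 0:
            raise ConfigError("n_decoys_per_kind must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0.0 <= self.regulator_cluster_bias <= 1.0:
            raise ConfigError("regulator_cluster_bias must be in [0, 1]")
        for phe in PHENOTYPES:
            if self.n_samples_per_phenotype.get(phe, 0) <= 0:
                raise ConfigError(
                    f"n_samples_per_phenotype[{phe!r}] must be positive")
        total = sum(self.pattern_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"pattern_proportions must sum to 1, got {total!r}")
        for key, prop in self.pattern_proportions.items():
            if key != "null" and key not in ALL_PATTERNS:
                raise ConfigError(f"unknown pattern {key!r} in "
                                  "pattern_proportions")
            if prop < 0:
                raise ConfigError(f"pattern_proportions[{key!r}] negative")
        for pattern, triple in self.effect_sizes.items():
            if pattern not in ALL_PATTERNS:
                raise ConfigError(f"unknown pattern {pattern!r} in "
                                  "effect_sizes")
            if len(triple) != 3:
                raise ConfigError(f"effect_sizes[{pattern!r}] must be a "
                                  "triple")
            for letter, delta in zip(pattern, triple):
                if (letter == "U" and delta <= 0) or \
                        (letter == "D" and delta >= 0):
                    raise ConfigError(
                        f"effect_sizes[{pattern!r}]={tuple(triple)} signs "
                        f"do not match the pattern letters")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "effect_sizes" in d:
            d["effect_sizes"] = {k: tuple(v)
                                 for k, v in d["effect_sizes"].items()}
        return cls(**d)


@dataclass
class RegulatorTruth:
    kind: str                 # "miRNA" | "TF"
    cluster: str              # planted target pattern
    members: tuple[str, ...] = ()   # filled by simulate_target_sets


@dataclass
class SyntheticTruth:
    """Everything that was planted, keyed the way downstream stages
    recover it."""

    gene_pattern: dict[str, str | None]
    gene_effects: dict[str, tuple[float, float, float]]
    regulators: dict[str, RegulatorTruth]
    mirna_directions: dict[str, tuple[float, float, float]]
    mirna_anti_cluster: dict[str, str]
    seed: int

    def validate(self, gene_universe: Sequence[str] | None = None) -> None:
        if gene_universe is not None:
            universe = set(gene_universe)
            for name, reg in self.regulators.items():
                stray = set(reg.members) - universe
                if stray:
                    raise ValueError(
                        f"regulator {name!r} has members outside the gene "
                        f"universe: {sorted(stray)[:5]}")
        for mirna, cluster in self.mirna_anti_cluster.items():
            triple = self.mirna_directions[mirna]
            expected = complement_pattern(cluster)
            observed = "".join("U" if x > 0 else "D" for x in triple)
            if observed != expected:
                raise ValueError(
                    f"anti-miRNA {mirna!r} direction {observed} is not the "
                    f"opposite of its cluster pattern {cluster}")

    def planted_degs(self) -> list[str]:
        return sorted(g for g, p in self.gene_pattern.items()
                      if p is not None)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_pattern": self.gene_pattern,
            "gene_effects": {g: list(e)
                             for g, e in self.gene_effects.items()},
            "regulators": {n: {"kind": r.kind, "cluster": r.cluster,
                               "members": list(r.members)}
                           for n, r in self.regulators.items()},
            "mirna_directions": {m: list(d) for m, d
                                 in self.mirna_directions.items()},
            "mirna_anti_cluster": self.mirna_anti_cluster,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            gene_pattern=d["gene_pattern"],
            gene_effects={g: tuple(e)
                          for g, e in d["gene_effects"].items()},
            regulators={n: RegulatorTruth(kind=r["kind"],
                                          cluster=r["cluster"],
                                          members=tuple(r["members"]))
                        for n, r in d["regulators"].items()},
            mirna_directions={m: tuple(v) for m, v
                              in d["mirna_directions"].items()},
            mirna_anti_cluster=d["mirna_anti_cluster"],
            seed=d["seed"])


# ---------------------------------------------------------------------------

def _sample_ids(config: SimulationConfig) -> dict[str, list[str]]:
    return {phe: [f"{phe}_{i + 1:03d}"
                  for i in range(config.n_samples_per_phenotype[phe])]
            for phe in PHENOTYPES}


def simulate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                   SampleDesign, SyntheticTruth]:
    """Generate the mRNA and miRNA matrices, the design, and the truth.

    Genes are allocated to patterns by exact proportional counts (largest
    remainders), so the planted composition is reproducible rather than
    multinomially noisy.  miRNA regulators are planted on the most populous
    clusters with direction triples opposite to their cluster; TF
    regulators are planted on the same clusters (their own expression is
    not modeled).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    mirnas = [f"miR-{i + 1:04d}" for i in range(config.n_mirnas)]

    # largest-remainder allocation of genes to patterns
    keys = [k for k in (*ALL_PATTERNS, "null")
            if config.pattern_proportions.get(k, 0) > 0]
    quotas = np.array([config.pattern_proportions[k] * config.n_genes
                       for k in keys])
    counts = np.floor(quotas).astype(int)
    remainder = config.n_genes - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1

    labels: list[str | None] = []
    for key, cnt in zip(keys, counts):
        labels.extend([None if key == "null" else key] * int(cnt))
    perm = rng.permutation(config.n_genes)
    gene_pattern = {genes[i]: labels[j] for i, j in enumerate(perm)}

    zero = (0.0, 0.0, 0.0)
    gene_effects = {
        g: (tuple(float(x) for x in config.effect_sizes[p])
            if p is not None else zero)
        for g, p in gene_pattern.items()}

    sample_ids = _sample_ids(config)
    design = SampleDesign({s: phe for phe in PHENOTYPES
                           for s in sample_ids[phe]})
    all_samples = [s for phe in PHENOTYPES for s in sample_ids[phe]]
    phe_index = {phe: i for i, phe in enumerate(CASE_PHENOTYPES)}

    def build_matrix(feature_ids, effects, kind):
        effect_cols = np.zeros((len(feature_ids), len(all_samples)))
        for j, s in enumerate(all_samples):
            phe = design.phenotype_of[s]
            if phe == "HC":
                continue
            col = phe_index[phe]
            effect_cols[:, j] = [effects[f][col] for f in feature_ids]
        noise = rng.normal(0.0, config.noise_sd,
                           size=effect_cols.shape)
        values = config.baseline_mean + effect_cols + noise
        return ExpressionMatrix(
            values=pd.DataFrame(values, index=feature_ids,
                                columns=all_samples),
            feature_kind=kind)

    mrna = build_matrix(genes, gene_effects, "mRNA")

    # plant anti-correlated miRNA regulators on the largest clusters
    cluster_sizes: dict[str, int] = {}
    for g, p in gene_pattern.items():
        if p is not None:
            cluster_sizes[p] = cluster_sizes.get(p, 0) + 1
    ranked_clusters = sorted(cluster_sizes,
                             key=lambda p: (-cluster_sizes[p], p))
    n_regulators = config.n_regulators_per_kind
    if not ranked_clusters:
        # null-only simulation (FDR calibration): nothing to regulate
        n_regulators = 0

    regulators: dict[str, RegulatorTruth] = {}
    mirna_directions: dict[str, tuple[float, float, float]] = {}
    mirna_anti_cluster: dict[str, str] = {}
    mirna_effects: dict[str, tuple[float, float, float]] = \
        {m: zero for m in mirnas}
    if n_regulators > len(mirnas):
        raise ConfigError("more planted miRNA regulators than miRNA "
                          "features")
    planted_mirnas = [mirnas[i] for i in range(n_regulators)]
    for i, mirna in enumerate(planted_mirnas):
        cluster = ranked_clusters[i % len(ranked_clusters)]
        triple = tuple(-x for x in config.effect_sizes[cluster])
        mirna_effects[mirna] = triple
        mirna_directions[mirna] = triple
        mirna_anti_cluster[mirna] = cluster
        regulators[mirna] = RegulatorTruth(kind="miRNA", cluster=cluster)
    for i in range(n_regulators):
        cluster = ranked_clusters[i % len(ranked_clusters)]
        regulators[f"TF{i + 1:02d}"] = RegulatorTruth(kind="TF",
                                                      cluster=cluster)

    mirna_matrix = build_matrix(mirnas, mirna_effects, "miRNA")

    truth = SyntheticTruth(gene_pattern=gene_pattern,
                           gene_effects=gene_effects,
                           regulators=regulators,
                           mirna_directions=mirna_directions,
                           mirna_anti_cluster=mirna_anti_cluster,
                           seed=config.seed)
    truth.validate()
    return mrna, mirna_matrix, design, truth


def simulate_target_sets(truth: SyntheticTruth, config: SimulationConfig
                         ) -> GeneSetCollection:
    """Draw target-gene sets for every planted regulator plus uniform
    decoys, and record the drawn members back into the truth.

    A planted regulator's set takes ``regulator_cluster_bias`` of its
    members from its planted cluster (capped at the cluster size) and the
    remainder uniformly from the other genes.  Decoy sets are uniform draws
    from the whole gene universe.
    """
    config.validate()
    genes = sorted(truth.gene_pattern)
    if config.targets_per_regulator > len(genes):
        raise ConfigError("targets_per_regulator exceeds the gene universe")
    rng = np.random.default_rng([config.seed, 104729])
    by_cluster: dict[str, list[str]] = {}
    for g in genes:
        p = truth.gene_pattern[g]
        if p is not None:
            by_cluster.setdefault(p, []).append(g)

    sets: list[GeneSet] = []
    for name in sorted(truth.regulators):
        reg = truth.regulators[name]
        cluster_genes = by_cluster.get(reg.cluster, [])
        n_bias = int(round(config.regulator_cluster_bias
                           * config.targets_per_regulator))
        n_bias = min(n_bias, len(cluster_genes))
        inside = list(rng.choice(cluster_genes, size=n_bias,
                                 replace=False)) if n_bias else []
        outside_pool = sorted(set(genes) - set(cluster_genes))
        n_out = config.targets_per_regulator - n_bias
        if n_out > len(outside_pool):
            raise ConfigError("requested set size exceeds the available "
                              "outside-cluster genes")
        outside = list(rng.choice(outside_pool, size=n_out,
                                  replace=False)) if n_out else []
        members = tuple(sorted(inside + outside))
        truth.regulators[name] = RegulatorTruth(
            kind=reg.kind, cluster=reg.cluster, members=members)
        sets.append(GeneSet(name=name, kind=reg.kind, members=members))

    for kind, prefix in (("miRNA", "decoy-miR"), ("TF", "decoy-TF")):
        for i in range(config.n_decoys_per_kind):
            members = tuple(sorted(rng.choice(
                genes, size=config.targets_per_regulator, replace=False)))
            sets.append(GeneSet(name=f"{prefix}-{i + 1:04d}", kind=kind,
                                members=members))
    truth.validate(gene_universe=genes)
    return GeneSetCollection(sets)


def simulate_ppi(truth: SyntheticTruth, config: SimulationConfig,
                 n_edges: int = 100) -> list[tuple[str, str]]:
    """Random PPI edges drawn within planted clusters (so that restricted
    networks are non-trivial), deduplicated and lexicographically
    ordered."""
    rng = np.random.default_rng([config.seed, 224737])
    by_cluster: dict[str, list[str]] = {}
    for g, p in truth.gene_pattern.items():
        if p is not None:
            by_cluster.setdefault(p, []).append(g)
    pools = [sorted(v) for v in by_cluster.values() if len(v) >= 2]
    if not pools:
        return []
    edges: set[tuple[str, str]] = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        pool = pools[rng.integers(len(pools))]
        a, b = rng.choice(pool, size=2, replace=False)
        edges.add((a, b) if a < b else (b, a))
    return sorted(edges)


def simulate_qpcr(truth: SyntheticTruth, config: SimulationConfig,
                  case_phenotype: str = "ADT", n_features: int = 11,
                  n_samples_per_group: int = 8,
                  noise_sd: float | None = None,
                  reference_feature: str = "GAPDH") -> pd.DataFrame:
    """Generate a qPCR Ct table whose 2^−ΔΔCt recovers the planted fold
    changes of differentially expressed genes.

    Per-sample Ct offsets (pipetting/loading variation) are added to both
    the target and the reference assay, so reference normalization cancels
    them exactly.  The reference must have no planted effect; naming a
    planted gene as the reference is a configuration error.
    """
    if case_phenotype not in CASE_PHENOTYPES:
        raise ConfigError(f"case_phenotype must be one of "
                          f"{CASE_PHENOTYPES}")
    ref_effect = truth.gene_effects.get(reference_feature)
    if ref_effect is not None and any(x != 0 for x in ref_effect):
        raise ConfigError(
            f"reference feature {reference_feature!r} has a planted "
            "effect; qPCR normalization requires a stable reference")
    planted = truth.planted_degs()
    if not planted:
        raise ConfigError("no planted DE genes to assay")
    n_features = min(n_features, len(planted))
    rng = np.random.default_rng([truth.seed, 299709])
    features = sorted(rng.choice(planted, size=n_features, replace=False))
    sd = config.noise_sd if noise_sd is None else noise_sd
    col = CASE_PHENOTYPES.index(case_phenotype)

    rows = []
    for group in ("HC", case_phenotype):
        for i in range(n_samples_per_group):
            sample = f"q{group}_{i + 1:02d}"
            offset = float(rng.normal(0.0, 0.5))
            for feat in features:
                effect = truth.gene_effects[feat][col] \
                    if group != "HC" else 0.0
                # higher expression -> earlier amplification -> lower Ct
                ct_t = 25.0 - effect + offset + float(rng.normal(0.0, sd))
                ct_r = 18.0 + offset + float(rng.normal(0.0, sd))
                rows.append({"sample_id": sample, "phenotype": group,
                             "feature_id": feat,
                             "ct_target": round(ct_t, 6),
                             "ct_reference": round(ct_r, 6)})
    return pd.DataFrame(rows)
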