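"""End-to-end orchestration: (simulate | load) -> collapse -> DE per
contrast -> overlaps -> direction patterns -> regulator enrichment ->
miRNA consistency -> co-regulatory networks -> qPCR concordance.

Every stage writes its table under the output directory and the run ends
with a manifest recording the seed, a canonical config hash and per-stage
record counts; re-running an identical config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import de, enrichment, io, network, overlap, patterns, validation
from .simulate import (SimulationConfig, simulate_expression, simulate_ppi,
                       simulate_qpcr, simulate_target_sets)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config drives the whole run.

    Exactly one of ``simulation`` (a :class:`SimulationConfig` or its dict
    form) and ``inputs`` (paths: mrna, mirna, design, and optionally
    mirna_gmt, tf_gmt, ppi, qpcr, feature_map) must be provided.
    """

    outdir: str = "corewire_out"
    simulation: SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    q_threshold: float = 0.05
    enrichment_p_threshold: float = 0.01
    universe_override: int | None = None
    equal_var: bool = False
    literal_q: bool = False
    linear_input: bool = False
    ppi_expansion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if not 0 < self.enrichment_p_threshold <= 1:
            raise ValueError("enrichment_p_threshold must be in (0, 1]")
        if bool(self.simulation) == bool(self.inputs):
            raise ValueError("provide exactly one of a simulation config "
                             "or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def canonical_json(self) -> str:
        d = asdict(self)
        d.pop("outdir")  # where results land does not change what they are
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n",
              index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns the in-memory result bundle.

    Raises with the failing stage's name in the message if any stage
    errors out.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}
    counts: dict[str, int] = {}
    stage = "acquire"
    try:
        if config.simulation is not None:
            sim = config.simulation
            mrna, mirna, design, truth = simulate_expression(sim)
            collection = simulate_target_sets(truth, sim)
            ppi = simulate_ppi(truth, sim)
            qpcr = simulate_qpcr(truth, sim)
            truth.to_json(out / "truth.json")
            io.write_expression(mrna, out / "mrna_matrix.tsv")
            io.write_expression(mirna, out / "mirna_matrix.tsv")
            io.write_design(design, out / "design.tsv")
            io.write_gmt(collection.of_kind("miRNA"),
                         out / "mirna_targets.gmt")
            io.write_gmt(collection.of_kind("TF"), out / "tf_targets.gmt")
            io.write_ppi(ppi, out / "ppi.tsv")
            validation.write_qpcr(qpcr, out / "qpcr.tsv")
            bundle["truth"] = truth
        else:
            paths = config.inputs
            mrna = io.read_expression(paths["mrna"], "mRNA",
                                      linear_input=config.linear_input)
            mirna = io.read_expression(paths["mirna"], "miRNA",
                                       linear_input=config.linear_input)
            design = io.read_design(paths["design"])
            sets = []
            if paths.get("mirna_gmt"):
                sets.extend(io.read_gmt(paths["mirna_gmt"], "miRNA"))
            if paths.get("tf_gmt"):
                sets.extend(io.read_gmt(paths["tf_gmt"], "TF"))
            collection = io.GeneSetCollection(sets)
            ppi = io.read_ppi(paths["ppi"]) if paths.get("ppi") else []
            qpcr = validation.read_qpcr(paths["qpcr"]) \
                if paths.get("qpcr") else None
            if paths.get("feature_map"):
                with open(paths["feature_map"]) as fh:
                    fmap = dict(line.rstrip("\n").split("\t")
                                for line in fh if line.strip())
                stage = "collapse"
                mrna = io.collapse_features(mrna, fmap)
        design.validate_against(mrna)
        design.validate_against(mirna)
        counts["genes"] = mrna.shape[0]
        counts["mirnas"] = mirna.shape[0]
        counts["samples"] = len(design)

        stage = "differential_expression"
        de_mrna = de.de_all_contrasts(
            mrna, design, q_threshold=config.q_threshold,
            equal_var=config.equal_var, monotonize=not config.literal_q)
        de_mirna = de.de_all_contrasts(
            mirna, design, q_threshold=config.q_threshold,
            equal_var=config.equal_var, monotonize=not config.literal_q)
        for phe, table in de_mrna.items():
            _write_tsv(table, out / f"de_mrna_{phe}.tsv", "feature_id")
        for phe, table in de_mirna.items():
            _write_tsv(table, out / f"de_mirna_{phe}.tsv", "feature_id")
        deg_sets = {phe: de.deg_ids(t, config.q_threshold)
                    for phe, t in de_mrna.items()}
        mir_sets = {phe: de.deg_ids(t, config.q_threshold)
                    for phe, t in de_mirna.items()}
        for phe in deg_sets:
            counts[f"degs_{phe}"] = len(deg_sets[phe])
            counts[f"de_mirnas_{phe}"] = len(mir_sets[phe])
        bundle.update(de_mrna=de_mrna, de_mirna=de_mirna,
                      deg_sets=deg_sets, mir_sets=mir_sets)

        stage = "overlap_analysis"
        uni_mrna = config.universe_override or mrna.shape[0]
        uni_mirna = config.universe_override or mirna.shape[0]
        rows = []
        for label, sets_, uni in (("mRNA", deg_sets, uni_mrna),
                                  ("miRNA", mir_sets, uni_mirna)):
            for res in overlap.all_pairwise_overlaps(sets_, uni):
                rows.append({"feature_kind": label, **asdict(res)})
        overlap_table = pd.DataFrame(rows)
        overlap_table.to_csv(out / "overlaps.tsv", sep="\t", index=False,
                             lineterminator="\n")
        venn = {"mRNA": overlap.venn_partition(deg_sets),
                "miRNA": overlap.venn_partition(mir_sets)}
        with open(out / "venn.json", "w") as fh:
            json.dump(venn, fh, indent=2, sort_keys=True)
        bundle.update(overlaps=overlap_table, venn=venn)

        stage = "dynamic_clustering"
        union = patterns.union_degs(deg_sets.values())
        counts["union_degs"] = len(union)
        assignments = patterns.assign_patterns(de_mrna, union)
        _write_tsv(assignments, out / "patterns.tsv", "gene")
        census = patterns.cluster_census(assignments, by="subpattern")
        census.to_json(out / "census.json", orient="index", indent=2)
        clusters = patterns.cluster_members(assignments, by="subpattern")
        bundle.update(assignments=assignments, census=census,
                      clusters=clusters)

        stage = "regulator_enrichment"
        universe = mrna.feature_ids
        enr = enrichment.enrich_all(
            clusters, collection, universe,
            p_threshold=config.enrichment_p_threshold) if len(collection) \
            else pd.DataFrame()
        if not enr.empty:
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                       lineterminator="\n")
        sig = enrichment.significant_enrichments(enr) if not enr.empty \
            else enr
        counts["enriched_regulators"] = len(sig)
        bundle["enrichment"] = enr

        stage = "consistency_validation"
        collapsed = network.collapse_families(sig) if not sig.empty else sig
        consistency_rows = []
        mirna_rows = (collapsed[collapsed["kind"] == "miRNA"]
                      if not collapsed.empty else pd.DataFrame())
        for _, row in mirna_rows.iterrows():
            mir = row["regulator"]
            triple = []
            for phe in io.CASE_PHENOTYPES:
                table = de_mirna[phe]
                if mir not in table.index:
                    triple = None
                    break
                triple.append(float(table.loc[mir, "log2fc"]))
            if triple is None:
                logger.info("miRNA %s has no expression profile; skipped",
                            mir)
                continue
            res = validation.direction_consistency(
                mir, triple, row["cluster"][:3].upper(),
                cluster_id=row["cluster"])
            consistency_rows.append({
                "mirna": res.mirna_id, "cluster": res.cluster_id,
                "log2fc_ADU": triple[0], "log2fc_ADT": triple[1],
                "log2fc_ID": triple[2],
                "opposite_ADU": res.opposite_flags[0],
                "opposite_ADT": res.opposite_flags[1],
                "opposite_ID": res.opposite_flags[2],
                "category": res.category})
        consistency = pd.DataFrame(consistency_rows)
        if not consistency.empty:
            consistency.to_csv(out / "consistency.tsv", sep="\t",
                               index=False, lineterminator="\n")
        counts["consistent_mirnas"] = int(
            (consistency["category"] != "inconsistent").sum()
            if not consistency.empty else 0)
        bundle["consistency"] = consistency

        stage = "coregulatory_network"
        summaries = {}
        networks = {}
        if not collapsed.empty:
            for cluster_id in sorted(collapsed["cluster"].unique()):
                net = network.build_network(
                    cluster_id, clusters[cluster_id], collapsed,
                    collection, ppi,
                    expand_ppi_neighbors=config.ppi_expansion)
                if net.graph.number_of_nodes() == 0:
                    continue
                network.export_network(net, out / f"network_{cluster_id}.sif",
                                       "SIF")
                network.export_network(
                    net, out / f"network_{cluster_id}.graphml", "GraphML")
                summaries[cluster_id] = net.summary()
                networks[cluster_id] = net
        with open(out / "network_summaries.json", "w") as fh:
            json.dump(summaries, fh, indent=2, sort_keys=True)
        counts["networks"] = len(summaries)
        bundle.update(networks=networks, network_summaries=summaries)

        stage = "qpcr_concordance"
        if qpcr is not None:
            fold = validation.ddct_fold_change(qpcr, "ADT")
            array_fc = {g: float(de_mrna["ADT"].loc[g, "log2fc"])
                        for g in fold if g in de_mrna["ADT"].index}
            if array_fc:
                n_conc, n_total = validation.platform_concordance(
                    array_fc, fold)
                concordance = {"n_concordant": n_conc, "n_total": n_total,
                               "fold_changes": fold}
                with open(out / "qpcr_concordance.json", "w") as fh:
                    json.dump(concordance, fh, indent=2, sort_keys=True)
                counts["qpcr_concordant"] = n_conc
                counts["qpcr_total"] = n_total
                bundle["concordance"] = concordance

        stage = "manifest"
        manifest = {"config_hash": config.config_hash(),
                    "seed": config.seed, "counts": counts}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") \
            from exc
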