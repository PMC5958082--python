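"""Synthetic-data generator: determinism, planted structure, config
contracts."""

import copy
import dataclasses

import numpy as np
import pytest

from corewire import de, patterns
from corewire.simulate import (ConfigError, SimulationConfig,
                               SyntheticTruth, simulate_expression,
                               simulate_ppi, simulate_qpcr,
                               simulate_target_sets)


def tiny_config(**kw):
    defaults = dict(
        n_genes=60, n_mirnas=10,
        n_samples_per_phenotype={"HC": 4, "ADU": 4, "ADT": 4, "ID": 4},
        n_regulators_per_kind=2, n_decoys_per_kind=2,
        targets_per_regulator=10, seed=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("kw,fragment", [
        (dict(n_genes=0), "n_genes"),
        (dict(noise_sd=0.0), "noise_sd"),
        (dict(regulator_cluster_bias=1.5), "bias"),
        (dict(n_samples_per_phenotype={"HC": 4, "ADU": 4, "ADT": 4}),
         "ID"),
        (dict(pattern_proportions={"UUU": 0.5, "null": 0.4}), "sum"),
        (dict(pattern_proportions={"XYZ": 0.5, "null": 0.5}), "pattern"),
        (dict(effect_sizes={"UUU": (1.0, -1.0, 1.0)}), "signs"),
    ])
    def test_invariant_violations_named(self, kw, fragment):
        with pytest.raises(ConfigError, match=fragment):
            tiny_config(**kw)

    def test_default_config_is_valid(self):
        cfg = SimulationConfig()
        assert abs(sum(cfg.pattern_proportions.values()) - 1) < 1e-9


class TestSimulateExpression:
    def test_determinism_bitwise(self):
        m1 = simulate_expression(tiny_config())
        m2 = simulate_expression(tiny_config())
        assert m1[0].values.equals(m2[0].values)
        assert m1[1].values.equals(m2[1].values)
        assert m1[3].gene_pattern == m2[3].gene_pattern

    def test_different_seed_differs(self):
        m1 = simulate_expression(tiny_config(seed=1))
        m2 = simulate_expression(tiny_config(seed=2))
        assert not m1[0].values.equals(m2[0].values)

    def test_zero_noise_limit_exact_shifts(self):
        cfg = tiny_config(
            noise_sd=1e-12,
            pattern_proportions={"UUU": 0.5, "null": 0.5},
            effect_sizes={"UUU": (1.0, 1.0, 1.0)})
        mrna, _, design, truth = simulate_expression(cfg)
        hc = design.samples("HC")
        for gene, pat in truth.gene_pattern.items():
            if pat != "UUU":
                continue
            base = mrna.values.loc[gene, hc]
            for phe in ("ADU", "ADT", "ID"):
                case = mrna.values.loc[gene, design.samples(phe)]
                assert np.allclose(case.mean() - base.mean(), 1.0,
                                   atol=1e-9)

    def test_zero_noise_pattern_recovery_exact(self):
        cfg = tiny_config(noise_sd=1e-12)
        mrna, _, design, truth = simulate_expression(cfg)
        tables = de.de_all_contrasts(mrna, design)
        planted = {g: p for g, p in truth.gene_pattern.items()
                   if p is not None}
        out = patterns.assign_patterns(tables, sorted(planted))
        for gene, pat in planted.items():
            assert out.loc[gene, "pattern"] == pat

    def test_planted_composition_matches_proportions(self):
        cfg = tiny_config(n_genes=200, pattern_proportions={
            "UUU": 0.25, "DDD": 0.25, "null": 0.5})
        _, _, _, truth = simulate_expression(cfg)
        labels = list(truth.gene_pattern.values())
        assert labels.count("UUU") == 50
        assert labels.count("DDD") == 50
        assert labels.count(None) == 100

    def test_anti_mirnas_opposite_direction(self):
        _, mirna, design, truth = simulate_expression(tiny_config())
        truth.validate()
        for mir, cluster in truth.mirna_anti_cluster.items():
            triple = truth.mirna_directions[mir]
            for letter, val in zip(cluster, triple):
                assert (val < 0) if letter == "U" else (val > 0)

    def test_mirna_expression_recovers_planted_direction(self):
        cfg = tiny_config(noise_sd=1e-12)
        _, mirna, design, truth = simulate_expression(cfg)
        tables = de.de_all_contrasts(mirna, design)
        for mir, triple in truth.mirna_directions.items():
            for phe, expected in zip(("ADU", "ADT", "ID"), triple):
                got = float(tables[phe].loc[mir, "log2fc"])
                assert got == pytest.approx(expected, abs=1e-6)


class TestTargetSets:
    def test_bias_one_subset_of_cluster(self):
        cfg = tiny_config(regulator_cluster_bias=1.0,
                          targets_per_regulator=5)
        _, _, _, truth = simulate_expression(cfg)
        coll = simulate_target_sets(truth, cfg)
        for name, reg in truth.regulators.items():
            cluster_genes = {g for g, p in truth.gene_pattern.items()
                             if p == reg.cluster}
            assert set(coll[name].members) <= cluster_genes

    def test_members_recorded_in_truth_and_in_universe(self):
        cfg = tiny_config()
        _, _, _, truth = simulate_expression(cfg)
        coll = simulate_target_sets(truth, cfg)
        truth.validate(gene_universe=sorted(truth.gene_pattern))
        for name, reg in truth.regulators.items():
            assert coll[name].members == reg.members
            assert len(reg.members) == cfg.targets_per_regulator

    def test_decoys_emitted(self):
        cfg = tiny_config()
        _, _, _, truth = simulate_expression(cfg)
        coll = simulate_target_sets(truth, cfg)
        decoys = [g for g in coll if g.name.startswith("decoy")]
        assert len(decoys) == 2 * cfg.n_decoys_per_kind

    def test_oversized_request_rejected(self):
        cfg = tiny_config(targets_per_regulator=1000)
        _, _, _, truth = simulate_expression(cfg)
        with pytest.raises(ConfigError, match="exceeds"):
            simulate_target_sets(truth, cfg)

    def test_determinism(self):
        cfg = tiny_config()
        _, _, _, t1 = simulate_expression(cfg)
        _, _, _, t2 = simulate_expression(cfg)
        c1 = simulate_target_sets(t1, cfg)
        c2 = simulate_target_sets(t2, cfg)
        assert [(g.name, g.members) for g in c1] == \
               [(g.name, g.members) for g in c2]


class TestQpcr:
    def test_zero_noise_recovers_planted_fold_change(self):
        from corewire.validation import ddct_fold_change
        cfg = tiny_config(effect_sizes={
            p: tuple((1.0 if c == "U" else -1.0) for c in p)
            for p in patterns.ALL_PATTERNS})
        _, _, _, truth = simulate_expression(cfg)
        table = simulate_qpcr(truth, cfg, noise_sd=0.0)
        fold = ddct_fold_change(table, "ADT")
        for feat, fc in fold.items():
            assert fc == pytest.approx(
                2.0 ** truth.gene_effects[feat][1], rel=1e-9)

    def test_planted_reference_rejected(self):
        cfg = tiny_config()
        _, _, _, truth = simulate_expression(cfg)
        planted = truth.planted_degs()[0]
        with pytest.raises(ConfigError, match="reference"):
            simulate_qpcr(truth, cfg, reference_feature=planted)

    def test_determinism(self):
        cfg = tiny_config()
        _, _, _, truth = simulate_expression(cfg)
        t1 = simulate_qpcr(truth, cfg)
        t2 = simulate_qpcr(truth, cfg)
        assert t1.equals(t2)


class TestTruthSerialization:
    def test_json_roundtrip(self, tmp_path):
        cfg = tiny_config()
        _, _, _, truth = simulate_expression(cfg)
        simulate_target_sets(truth, cfg)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back.gene_pattern == truth.gene_pattern
        assert back.gene_effects == truth.gene_effects
        assert back.regulators == truth.regulators
        assert back.mirna_anti_cluster == truth.mirna_anti_cluster

    def test_ppi_within_clusters_and_deterministic(self):
        cfg = tiny_config()
        _, _, _, truth = simulate_expression(cfg)
        e1 = simulate_ppi(truth, cfg, n_edges=20)
        e2 = simulate_ppi(truth, cfg, n_edges=20)
        assert e1 == e2
        for a, b in e1:
            assert a < b
            assert truth.gene_pattern[a] == truth.gene_pattern[b]
            assert truth.gene_pattern[a] is not None


class TestNullCalibration:
    def test_empirical_fdr_under_all_null(self):
        # all-null datasets: BH at q<=0.05 controls the realized FDR
        n_datasets, n_features = 60, 300
        fdrs = []
        for seed in range(n_datasets):
            cfg = tiny_config(
                n_genes=n_features, seed=seed,
                n_regulators_per_kind=1,
                pattern_proportions={"UUU": 1.0 / n_features,
                                     "null": 1 - 1.0 / n_features})
            mrna, _, design, truth = simulate_expression(cfg)
            table = de.differential_expression(mrna, design, "ADT")
            called = set(de.deg_ids(table))
            false = called - set(truth.planted_degs())
            fdrs.append(len(false) / max(len(called), 1))
        mean_fdr = float(np.mean(fdrs))
        se = float(np.std(fdrs, ddof=1) / np.sqrt(n_datasets))
        assert mean_fdr <= 0.05 + 3 * max(se, 0.01)
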