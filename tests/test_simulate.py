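"""Synthetic-data generator: determinism, planted truth, degenerate cases."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from phylostrat_rt import (
    SimulationConfig,
    assign_duplication_age,
    call_cnv_genes,
    simulate_dataset,
)
from phylostrat_rt.errors import CapacityError, ConfigurationError
from phylostrat_rt.simulate import (
    simulate_chromosome_map,
    simulate_copy_number_matrix,
    simulate_gene_trees,
    simulate_genome_annotation,
    simulate_rt_probes,
    simulate_true_ages,
)
from phylostrat_rt.trees import assignments_to_frame


class TestGenomeAnnotation:
    def test_empty_gene_table(self):
        cfg = SimulationConfig(n_genes=0)
        genes, cmap = simulate_genome_annotation(cfg)
        assert len(genes) == 0
        assert len(cmap.table) == cfg.n_chromosomes

    def test_centromere_centered(self):
        cfg = SimulationConfig(
            n_chromosomes=1, chromosome_length=10_000_000,
            centromere_position=0.5, centromere_width=2_000_000, n_genes=10,
        )
        row = simulate_chromosome_map(cfg).table.iloc[0]
        assert (row["cen_start"] + row["cen_end"]) // 2 == 5_000_000

    def test_determinism(self):
        cfg = SimulationConfig(seed=42, n_genes=100)
        g1, _ = simulate_genome_annotation(cfg)
        g2, _ = simulate_genome_annotation(cfg)
        pd.testing.assert_frame_equal(g1, g2)

    def test_capacity_error(self):
        cfg = SimulationConfig(
            n_genes=1000, n_chromosomes=1, chromosome_length=1_000_000,
            gene_length_range=(2_000, 20_000),
        )
        with pytest.raises(CapacityError):
            simulate_genome_annotation(cfg)

    def test_coordinates_valid_and_sorted(self, small_config):
        genes, cmap = simulate_genome_annotation(small_config)
        assert (genes["end"] > genes["start"]).all()
        assert (genes["start"] >= 0).all()
        lengths = cmap.table.set_index("chrom")["length"]
        assert (genes["end"].to_numpy() <=
                lengths.loc[genes["chrom"]].to_numpy()).all()
        for _, sub in genes.groupby("chrom"):
            assert sub["start"].is_monotonic_increasing

    def test_sex_chromosome_optional(self):
        cfg = SimulationConfig(n_genes=50, include_sex_chromosome=True,
                               n_chromosomes=2)
        genes, cmap = simulate_genome_annotation(cfg)
        assert "chrX" in set(cmap.table["chrom"])
        assert "chrX" in set(genes["chrom"])


class TestGeneTrees:
    def test_all_singletons_forced(self, human_timeline):
        n_cl = human_timeline.n_classes
        cfg = SimulationConfig(
            seed=1, n_genes=50, n_families=5,
            age_distribution=[0.0] * n_cl + [1.0],
        )
        trees, truth = simulate_gene_trees(cfg, human_timeline)
        assert truth["true_singleton"].all()
        for tree in trees:
            for leaf in tree.focal_leaves(human_timeline.focal_species):
                node = leaf.parent
                while node is not None:
                    assert node.event != "duplication"
                    node = node.parent

    def test_perfect_scores_recover_truth(self, human_timeline):
        """Point mass at score 1.0: assignment equals the truth table."""
        cfg = SimulationConfig(
            seed=2, n_genes=500, n_families=50,
            score_distribution={"kind": "point", "value": 1.0},
        )
        trees, truth = simulate_gene_trees(cfg, human_timeline)
        frame = assignments_to_frame(
            [a for t in trees for a in assign_duplication_age(t, human_timeline)]
        ).set_index("gene_id")
        truth = truth.set_index("gene_id")
        for gid in truth.index:
            if truth.loc[gid, "true_singleton"]:
                assert frame.loc[gid, "status"] == "SINGLETON"
            else:
                assert frame.loc[gid, "status"] == "PDG"
                assert frame.loc[gid, "age_class_index"] == \
                    truth.loc[gid, "true_age_class"]

    def test_zero_score_decoy_skipped(self, human_timeline):
        """Zero-score decoy duplications at younger classes never change
        the recovered age."""
        cfg = SimulationConfig(
            seed=3, n_genes=300, n_families=30, decoy_zero_prob=1.0,
            score_distribution={"kind": "point", "value": 1.0},
        )
        trees, truth = simulate_gene_trees(cfg, human_timeline)
        frame = assignments_to_frame(
            [a for t in trees for a in assign_duplication_age(t, human_timeline)]
        ).set_index("gene_id")
        dup = truth[~truth["true_singleton"]].set_index("gene_id")
        assert (
            frame.loc[dup.index, "age_class_index"].astype("Int64")
            == dup["true_age_class"]
        ).all()

    def test_every_gene_in_exactly_one_tree(self, small_config, human_timeline):
        trees, truth = simulate_gene_trees(small_config, human_timeline)
        focal = [
            l.gene_id for t in trees for l in t.focal_leaves(human_timeline.focal_species)
        ]
        assert sorted(focal) == sorted(truth["gene_id"])


class TestCopyNumber:
    def _truth(self, cfg, timeline, genes):
        return simulate_true_ages(cfg, timeline, list(genes["gene_id"]))

    def test_no_cnv_when_probs_zero(self, human_timeline):
        n_cl = human_timeline.n_classes
        cfg = SimulationConfig(seed=4, n_genes=200, n_individuals=30,
                               cnv_prob_by_age=[0.0] * (n_cl + 1))
        genes, _ = simulate_genome_annotation(cfg)
        matrix, truth = simulate_copy_number_matrix(
            genes, self._truth(cfg, human_timeline, genes), cfg, human_timeline
        )
        calls = call_cnv_genes(matrix)
        assert (calls["status"] != "CNV").all()
        assert not truth["true_cnv"].any()

    def test_planted_cnv_always_called(self, human_timeline):
        n_cl = human_timeline.n_classes
        cfg = SimulationConfig(seed=5, n_genes=300, n_individuals=40,
                               cnv_prob_by_age=[1.0] * (n_cl + 1))
        genes, _ = simulate_genome_annotation(cfg)
        matrix, truth = simulate_copy_number_matrix(
            genes, self._truth(cfg, human_timeline, genes), cfg, human_timeline
        )
        calls = call_cnv_genes(matrix).set_index("gene_id")
        assert (calls["status"] == "CNV").all()

    def test_step_function_recovery(self, human_timeline):
        """CNV probability 1 for the youngest class, 0 elsewhere: calls
        reproduce the planted step exactly."""
        n_cl = human_timeline.n_classes
        probs = [0.0] * (n_cl + 1)
        probs[n_cl - 1] = 1.0
        cfg = SimulationConfig(seed=6, n_genes=400, n_individuals=30,
                               cnv_prob_by_age=probs)
        genes, _ = simulate_genome_annotation(cfg)
        truth0 = self._truth(cfg, human_timeline, genes)
        matrix, truth = simulate_copy_number_matrix(
            genes, truth0, cfg, human_timeline
        )
        calls = call_cnv_genes(matrix).set_index("gene_id")
        t = truth.set_index("gene_id")
        youngest = (t["true_age_class"] == n_cl).fillna(False)
        assert (calls.loc[youngest[youngest].index, "status"] == "CNV").all()
        assert (calls.loc[youngest[~youngest].index, "status"] == "NON_CNV").all()

    def test_two_individual_minimum(self, human_timeline):
        cfg = SimulationConfig(n_genes=10, n_individuals=1)
        genes, _ = simulate_genome_annotation(cfg)
        with pytest.raises(ConfigurationError):
            simulate_copy_number_matrix(
                genes, self._truth(cfg, human_timeline, genes), cfg, human_timeline
            )

    def test_determinism(self, small_config, human_timeline):
        genes, _ = simulate_genome_annotation(small_config)
        truth = self._truth(small_config, human_timeline, genes)
        m1, _ = simulate_copy_number_matrix(genes, truth, small_config, human_timeline)
        m2, _ = simulate_copy_number_matrix(genes, truth, small_config, human_timeline)
        pd.testing.assert_frame_equal(m1.copies, m2.copies)


class TestRTProbes:
    def test_degenerate_flat_world(self, human_timeline):
        cfg = SimulationConfig(seed=7, n_genes=40, n_chromosomes=1,
                               chromosome_length=10_000_000,
                               rt_age_effect=0.0, rt_noise_sd=0.0)
        genes, cmap = simulate_genome_annotation(cfg)
        truth = simulate_true_ages(cfg, human_timeline, list(genes["gene_id"]))
        ps, truth = simulate_rt_probes(genes, truth, cmap, cfg, human_timeline)
        for sid in ps.sample_ids:
            assert ps.probes[sid].nunique() == 1

    def test_sample_count_shape(self, human_timeline):
        cfg = SimulationConfig(seed=8, n_genes=20, n_rt_samples=4,
                               n_chromosomes=1, chromosome_length=5_000_000)
        genes, cmap = simulate_genome_annotation(cfg)
        truth = simulate_true_ages(cfg, human_timeline, list(genes["gene_id"]))
        ps, _ = simulate_rt_probes(genes, truth, cmap, cfg, human_timeline)
        assert len(ps.sample_ids) == 4
        assert ps.probes.shape[1] == 2 + 4  # chrom, pos + samples

    def test_probe_spacing_error(self, human_timeline):
        cfg = SimulationConfig(n_genes=5, probe_spacing=10_000_000,
                               chromosome_length=1_000_000, n_chromosomes=1,
                               gene_length_range=(500, 1000))
        genes, cmap = simulate_genome_annotation(cfg)
        truth = simulate_true_ages(cfg, human_timeline, list(genes["gene_id"]))
        with pytest.raises(ConfigurationError):
            simulate_rt_probes(genes, truth, cmap, cfg, human_timeline)

    def test_noiseless_age_signal(self, human_timeline):
        """With zero noise, the gene latent equals baseline - effect *
        (age_index - 1), singletons behaving like the oldest class."""
        cfg = SimulationConfig(seed=9, n_genes=100, rt_noise_sd=0.0,
                               rt_age_effect=0.5, n_chromosomes=2,
                               chromosome_length=20_000_000)
        genes, cmap = simulate_genome_annotation(cfg)
        truth = simulate_true_ages(cfg, human_timeline, list(genes["gene_id"]))
        _, truth = simulate_rt_probes(genes, truth, cmap, cfg, human_timeline)
        for _, row in truth.iterrows():
            dist = 0 if row["true_singleton"] else row["true_age_class"] - 1
            assert row["true_rt_latent"] == pytest.approx(-0.5 * dist)


class TestDatasetDeterminism:
    def test_byte_identical_outputs(self, tmp_path, small_config):
        """The whole written dataset is byte-identical across runs of one
        config+seed."""
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(small_config).write(d1)
        simulate_dataset(small_config).write(d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel

    def test_seed_changes_output(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        g1, _ = simulate_genome_annotation(small_config)
        g2, _ = simulate_genome_annotation(other)
        assert not g1.equals(g2)


class TestMarginalControl:
    def test_cnv_fraction_tracks_probabilities(self, human_timeline):
        """Empirical per-class planted-CNV fractions match cnv_prob_by_age
        within ~4 binomial standard errors at n=5,000."""
        n_cl = human_timeline.n_classes
        probs = [0.2] * n_cl + [0.05]
        cfg = SimulationConfig(seed=10, n_genes=5_000, n_individuals=10,
                               cnv_prob_by_age=probs)
        genes, _ = simulate_genome_annotation(cfg)
        truth = simulate_true_ages(cfg, human_timeline, list(genes["gene_id"]))
        _, truth = simulate_copy_number_matrix(genes, truth, cfg, human_timeline)
        for cls in range(1, n_cl + 1):
            sub = truth[truth["true_age_class"] == cls]
            if len(sub) < 50:
                continue
            frac = sub["true_cnv"].mean()
            se = np.sqrt(0.2 * 0.8 / len(sub))
            assert abs(frac - 0.2) < 4 * se
        sing = truth[truth["true_singleton"]]
        assert abs(sing["true_cnv"].mean() - 0.05) < 4 * np.sqrt(
            0.05 * 0.95 / len(sing)
        )
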