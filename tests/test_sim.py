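import numpy as np
import pandas as pd
import pytest

from btnmeth.features import enumerate_cpg_sites
from btnmeth.sim import (PRESETS, classify_intensity, cohort_plan,
                         simulate_expression, simulate_genome,
                         simulate_methylome, simulate_te_copies)
from btnmeth.sim.consensus import consensus_elements
from btnmeth.te import kimura_distance
from conftest import TEST_SEED


class TestGenomeStructure:
    def test_tracks_are_consistent(self, healthy_sim):
        sg, _, _ = healthy_sim
        lengths = sg.contig_lengths
        # intergenic is the complement of genes: together they tile the genome
        total = sg.tracks["gene"].merge().total_bases() \
            + sg.tracks["intergenic"].total_bases()
        assert total == sum(lengths.values())
        # gene parts stay within their gene
        gene_mask = sg.tracks["gene"].coverage_mask("chr1", lengths["chr1"])
        for part in ("exon", "intron", "utr5", "utr3"):
            part_mask = sg.tracks[part].coverage_mask("chr1", lengths["chr1"])
            assert not (part_mask & ~gene_mask).any()

    def test_sequence_alphabet_and_n_blocks(self, healthy_sim):
        sg, _, _ = healthy_sim
        seq = sg.genome[0].sequence
        assert set(seq) <= set("ACGTN")
        for contig, s, e, _, _ in sg.tracks["n_block"].iter_intervals():
            if contig == "chr1":
                assert sg.genome[0].sequence[s:e] == "N" * 500

    def test_cpg_density_elevated_in_planted_islands(self, healthy_sim):
        sg, _, _ = healthy_sim
        sites = enumerate_cpg_sites(sg.genome)["chr1"]
        mask = sg.tracks["cpg_island"].membership("chr1", sites)
        island_bases = sg.tracks["cpg_island"].merge().total_bases() / 2  # both contigs approx
        density_in = mask.sum() / max(island_bases, 1)
        density_out = (~mask).sum() / sg.contig_lengths["chr1"]
        assert density_in > 2 * density_out

    def test_same_seed_reproduces_identical_genome(self):
        a = simulate_genome(PRESETS["healthy"], 7)
        b = simulate_genome(PRESETS["healthy"], 7)
        assert [g.sequence for g in a.genome] == [g.sequence for g in b.genome]
        pd.testing.assert_frame_equal(a.truth["genes"], b.truth["genes"])

    def test_different_seed_changes_sequence(self):
        a = simulate_genome(PRESETS["healthy"], 7)
        b = simulate_genome(PRESETS["healthy"], 8)
        assert a.genome[0].sequence != b.genome[0].sequence


class TestMethylome:
    def test_same_seed_byte_identical_calls(self, healthy_sim):
        sg, calls, _ = healthy_sim
        again, _ = simulate_methylome(sg, PRESETS["healthy"], TEST_SEED, "healthy")
        pd.testing.assert_frame_equal(calls, again)

    def test_calls_respect_depth_and_fraction_bounds(self, healthy_sim):
        _, calls, _ = healthy_sim
        assert (calls["depth"] > 0).all()
        assert calls["mc_frac"].between(0, 1).all()
        assert (calls["mc_frac"] + calls["hmc_frac"] <= 1 + 1e-12).all()

    def test_zero_depth_config_rejected(self, healthy_sim):
        import dataclasses
        sg, _, _ = healthy_sim
        broken = dataclasses.replace(PRESETS["healthy"], depth_lambda=0.0)
        with pytest.raises(ValueError):
            simulate_methylome(sg, broken, 1, "x")

    def test_tumour_hypomethylation(self, healthy_sim, cedbtn1_sim):
        _, h_calls, _ = healthy_sim
        _, t_calls, _ = cedbtn1_sim
        assert t_calls["mc_frac"].mean() < h_calls["mc_frac"].mean() - 0.05

    def test_purity_interpolates_site_means(self, healthy_sim):
        sg, _, _ = healthy_sim
        mid, _ = simulate_methylome(sg, PRESETS["healthy"], TEST_SEED, "m",
                                    purity=0.5, tumour_preset=PRESETS["cedbtn1"])
        host, _ = simulate_methylome(sg, PRESETS["healthy"], TEST_SEED, "h")
        tum, _ = simulate_methylome(sg, PRESETS["healthy"], TEST_SEED, "t",
                                    purity=1.0, tumour_preset=PRESETS["cedbtn1"])
        assert host["mc_frac"].mean() > mid["mc_frac"].mean() > tum["mc_frac"].mean()


class TestExpressionCoupling:
    def test_coupling_monotone_in_beta(self, healthy_sim):
        """Larger coupling slopes never yield weaker expected correlation."""
        import dataclasses
        from btnmeth.expression import methylation_expression_correlation, tpm_table
        sg, calls, truth = healthy_sim
        rs = []
        for beta in (0.0, 0.5, 1.0, 2.0):
            preset = dataclasses.replace(PRESETS["healthy"], expr_beta=beta)
            counts = simulate_expression(sg, truth["gene_true_prop"], preset, 3)
            expr = tpm_table(counts).set_index("gene_id")["tpm"]
            r = methylation_expression_correlation(
                truth["gene_true_prop"], expr).pearson_r
            rs.append(r)
        assert abs(rs[0]) < 0.1  # beta = 0: no coupling
        assert all(b >= a - 0.02 for a, b in zip(rs, rs[1:]))


class TestTeCopySimulation:
    def test_zero_divergence_copies_identical(self, consensus):
        cs = simulate_te_copies(consensus["CedCL34"], {"healthy": 2, "t": 2},
                                seed=1, shared_divergence=0.0,
                                healthy_private=0.0, tumour_private=0.0)
        assert all(s == consensus["CedCL34"].sequence for s in cs.sequences.values())

    def test_measured_k2p_close_to_model_truth(self, consensus):
        cs = simulate_te_copies(consensus["CedCL34"],
                                {"healthy": 3, "cedbtn1": 3}, seed=2)
        for i, a in enumerate(cs.labels):
            for b in cs.labels[i + 1:]:
                measured = kimura_distance(cs.sequences[a], cs.sequences[b])
                assert measured == pytest.approx(
                    cs.true_distances.loc[a, b], abs=0.02)

    def test_nj_shows_healthy_only_cluster(self, consensus):
        import io as _io
        from Bio import Phylo
        from btnmeth.te import nj_tree
        cs = simulate_te_copies(consensus["CedCL34"],
                                {"healthy": 6, "cedbtn1": 8, "cedbtn2": 8}, seed=3)
        n = len(cs.labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = kimura_distance(
                    cs.sequences[cs.labels[i]], cs.sequences[cs.labels[j]])
        tree = Phylo.read(_io.StringIO(nj_tree(D, cs.labels)), "newick")
        healthy = {l for l in cs.labels if l.startswith("healthy")}
        clades = [frozenset(t.name for t in c.get_terminals())
                  for c in tree.get_nonterminals()]
        assert any(c == healthy or c == set(cs.labels) - healthy for c in clades)


class TestIntensityClassification:
    @pytest.mark.parametrize("fraction,expected", [
        (0.0, "N0"), (0.05, "N1"), (0.15, "N1"), (0.5, "N2"),
        (0.75, "N2"), (0.80, "N3"), (1.0, "N3"),
    ])
    def test_boundaries(self, fraction, expected):
        assert classify_intensity(fraction) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity(1.2)

    def test_cohort_plan_structure(self):
        plan = cohort_plan()
        assert len(plan) == 8
        purity = {s.tissue: s.tumour_purity for s in plan}
        assert all(s.tumour_purity == 0 for s in plan if s.lineage == "healthy")
        assert all(s.tumour_purity >= 0.9 for s in plan
                   if s.tissue == "haemolymph")
        gills = [s for s in plan if s.tissue == "gill"]
        assert all(0.3 <= s.tumour_purity <= 0.6 for s in gills)
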