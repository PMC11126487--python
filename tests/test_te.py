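import io as _io

import numpy as np
import pytest
from Bio import Phylo

from btnmeth.io import GenomeSequence, InsertionCall
from btnmeth.sim.consensus import mutate, random_dna
from btnmeth.te import (TEConsensus, divergence_landscape, element_methylation,
                        filter_insertions, kimura_distance, nj_tree, scan_copies)


def _genome(seq, name="c1"):
    return [GenomeSequence(name, seq)]


@pytest.fixture(scope="module")
def small_consensus():
    rng = np.random.default_rng(8)
    return TEConsensus("mini", random_dna(rng, 1200, gc=0.45))


class TestScanCopies:
    def test_exact_copy_found_full_length(self, small_consensus, rng):
        background = random_dna(rng, 12_000, gc=0.4)
        seq = background[:4000] + small_consensus.sequence + background[4000:]
        copies = scan_copies(_genome(seq), small_consensus)
        assert len(copies) == 1
        c = copies[0]
        assert c.is_full_length and c.aligned_identity == pytest.approx(1.0)
        assert (c.start, c.end) == (4000, 4000 + 1200)

    def test_truncated_copy_found_but_not_full_length(self, small_consensus, rng):
        frag = small_consensus.sequence[:600]
        seq = random_dna(rng, 5000, 0.4) + frag + random_dna(rng, 5000, 0.4)
        copies = scan_copies(_genome(seq), small_consensus, min_len=200)
        assert len(copies) == 1
        assert not copies[0].is_full_length
        assert copies[0].coverage_of_consensus == pytest.approx(0.5, abs=0.05)

    def test_reverse_strand_copy_recovered(self, small_consensus, rng):
        from btnmeth.te import revcomp
        seq = random_dna(rng, 4000, 0.4) + revcomp(small_consensus.sequence) \
            + random_dna(rng, 4000, 0.4)
        copies = scan_copies(_genome(seq), small_consensus)
        assert len(copies) == 1 and copies[0].strand == "-"

    def test_recall_up_to_ten_percent_divergence(self, small_consensus, rng):
        parts = [random_dna(rng, 2000, 0.4)]
        for div in (0.02, 0.06, 0.10):
            parts += [mutate(small_consensus.sequence, div, rng),
                      random_dna(rng, 2000, 0.4)]
        copies = scan_copies(_genome("".join(parts)), small_consensus)
        assert len(copies) == 3
        assert all(c.is_full_length for c in copies)

    def test_no_hits_in_shuffled_genome(self, small_consensus, rng):
        shuffled = "".join(rng.permutation(list(random_dna(rng, 50_000, 0.45))))
        assert scan_copies(_genome(shuffled), small_consensus) == []

    def test_planted_healthy_preset_copies(self, healthy_sim, consensus):
        sg, _, _ = healthy_sim
        copies = scan_copies(sg.genome, consensus["CedCL34"])
        assert sum(c.is_full_length for c in copies) == 6


class TestKimura:
    def test_identical_sequences(self):
        assert kimura_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_transitions_only(self):
        # P = 0.1, Q = 0 over 100 columns: d = -ln(0.8)/2 = 0.1116
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert kimura_distance(a, b) == pytest.approx(0.11157, abs=1e-4)

    def test_symmetry(self, rng):
        for _ in range(5):
            a = random_dna(rng, 300)
            b = mutate(a, 0.15, rng)
            assert kimura_distance(a, b) == kimura_distance(b, a)

    def test_saturation_flagged_as_inf(self):
        a = "A" * 50
        b = "C" * 50  # all transversions: Q = 1
        assert kimura_distance(a, b) == np.inf

    def test_gapped_columns_ignored(self):
        assert kimura_distance("AC-GT", "ACNGT") == 0.0


class TestLandscape:
    def test_single_exact_copy_in_first_bin(self, small_consensus, rng):
        cons = TEConsensus("m", random_dna(rng, 100))
        seq = random_dna(rng, 5000, 0.4) + cons.sequence + random_dna(rng, 4900, 0.4)
        copies = scan_copies(_genome(seq), cons, min_len=80)
        land = divergence_landscape(copies, cons, genome_size=10_000)
        assert land.total_percent == pytest.approx(1.0, abs=0.02)
        assert land.coverage_percent[0] == land.total_percent

    def test_no_copies_all_zero(self, small_consensus):
        land = divergence_landscape([], small_consensus, 10_000)
        assert land.total_percent == 0.0 and (land.coverage_percent == 0).all()

    def test_healthy_cl24_coverage(self, healthy_sim, consensus):
        sg, _, _ = healthy_sim
        copies = scan_copies(sg.genome, consensus["CedCL24"])
        land = divergence_landscape(copies, consensus["CedCL24"],
                                    sg.config.genome_size)
        assert land.total_percent == pytest.approx(0.30, abs=0.05)
        # recently expanded element: mass concentrated at low divergence
        assert land.coverage_percent[:5].sum() == pytest.approx(land.total_percent)


class TestNeighbourJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1):1) -> additive distances
        D = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], dtype=float)
        nwk = nj_tree(D, list("ABCD"))
        tree = Phylo.read(_io.StringIO(nwk), "newick")
        dist = {frozenset(p): tree.distance(*p)
                for p in [("A", "B"), ("A", "C"), ("A", "D"),
                          ("B", "C"), ("B", "D"), ("C", "D")]}
        assert dist[frozenset(("A", "B"))] == pytest.approx(3)
        assert dist[frozenset(("A", "C"))] == pytest.approx(5)
        assert dist[frozenset(("B", "D"))] == pytest.approx(4)
        assert dist[frozenset(("C", "D"))] == pytest.approx(4)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        nwk = nj_tree(D, list("XYZ"))
        tree = Phylo.read(_io.StringIO(nwk), "newick")
        # v_x = (4 + 6 - 8)/2 = 1, v_y = 3, v_z = 5
        term = {t.name: t.branch_length for t in tree.get_terminals()}
        assert term == {"X": pytest.approx(1), "Y": pytest.approx(3),
                        "Z": pytest.approx(5)}

    def test_random_additive_five_taxon_battery(self, rng):
        """Any additive 5-taxon matrix is reconstructed as a tree metric."""
        import itertools
        for _ in range(10):
            # random unrooted binary tree on 5 taxa via random split
            bl = rng.uniform(0.5, 3.0, 7)
            # topology ((A,B),(C,D),E) with internal edges bl[5], bl[6]
            D = np.zeros((5, 5))
            pathlens = {
                (0, 1): bl[0] + bl[1], (2, 3): bl[2] + bl[3],
                (0, 2): bl[0] + bl[5] + bl[6] + bl[2],
                (0, 3): bl[0] + bl[5] + bl[6] + bl[3],
                (1, 2): bl[1] + bl[5] + bl[6] + bl[2],
                (1, 3): bl[1] + bl[5] + bl[6] + bl[3],
                (0, 4): bl[0] + bl[5] + bl[4], (1, 4): bl[1] + bl[5] + bl[4],
                (2, 4): bl[2] + bl[6] + bl[4], (3, 4): bl[3] + bl[6] + bl[4],
            }
            for (i, j), d in pathlens.items():
                D[i, j] = D[j, i] = d
            nwk = nj_tree(D, list("ABCDE"))
            tree = Phylo.read(_io.StringIO(nwk), "newick")
            for i, j in itertools.combinations(range(5), 2):
                # branch lengths serialise at 10 significant digits
                assert tree.distance("ABCDE"[i], "ABCDE"[j]) == \
                    pytest.approx(D[i, j], abs=1e-6)

    def test_agrees_with_skbio_on_topology(self, rng):
        """Independent cross-check against scikit-bio's NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        n = 6
        pts = rng.uniform(0, 1, (n, 4))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]

        def norm(names):
            return min(names, frozenset(labels) - names, key=sorted)

        ours = Phylo.read(_io.StringIO(nj_tree(D, labels)), "newick")
        ours_splits = set()
        for c in ours.get_nonterminals():
            names = frozenset(t.name for t in c.get_terminals())
            if 1 < len(names) < n - 1:
                ours_splits.add(norm(names))
        sk_splits = set()
        for node in skbio_nj(DistanceMatrix(D, labels)).non_tips():
            names = frozenset(t.name for t in node.tips())
            if 1 < len(names) < n - 1:
                sk_splits.add(norm(names))
        assert ours_splits == sk_splits

    def test_nan_matrix_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(D, list("ABC"))


class TestInsertionFilter:
    def _call(self, seq, support=10, flags=("PASS",), precise=True, svtype="INS",
              rid="r"):
        return InsertionCall("c1", 100, svtype, len(seq), support,
                             frozenset(flags), precise, seq, rid)

    def test_support_three_rejected_with_reason(self, small_consensus):
        call = self._call(small_consensus.sequence, support=3)
        res = filter_insertions([call], [small_consensus])
        assert res.kept == [] and res.rejected[0][1] == "support"

    def test_perfect_record_kept_with_tandem_one(self, small_consensus):
        res = filter_insertions([self._call(small_consensus.sequence)],
                                [small_consensus])
        assert len(res.kept) == 1
        k = res.kept[0]
        assert k.family == "mini" and k.tandem_count == 1
        assert not k.needs_validation

    def test_head_to_tail_dimer_counted_and_flagged(self, consensus, rng):
        cl24 = consensus["CedCL24"]
        dimer = mutate(cl24.sequence, 0.01, rng) + mutate(cl24.sequence, 0.01, rng)
        res = filter_insertions([self._call(dimer)], list(consensus.values()))
        assert len(res.kept) == 1
        k = res.kept[0]
        assert k.family == "CedCL24"
        assert k.tandem_count == 2
        assert k.needs_validation  # ~12.4 kb > 5 kb validation threshold

    def test_rejection_reason_precedence(self, small_consensus):
        calls = [
            self._call("ACGT" * 100, svtype="DEL", rid="a"),
            self._call(small_consensus.sequence, support=2, flags=("GT",),
                       precise=False, rid="b"),
            self._call(small_consensus.sequence, flags=("GT",), precise=False,
                       rid="c"),
            self._call(small_consensus.sequence, precise=False, rid="d"),
            self._call("A" * 500, rid="e"),
        ]
        res = filter_insertions(calls, [small_consensus])
        reasons = {c.record_id: r for c, r in res.rejected}
        assert reasons == {"a": "svtype", "b": "support", "c": "filter",
                           "d": "precision", "e": "no_consensus_match"}

    def test_partition_invariant(self, cedbtn2_sim, consensus):
        from btnmeth.sim import PRESETS, simulate_insertion_callset
        sg, _, _ = cedbtn2_sim
        calls = simulate_insertion_callset(sg, PRESETS["cedbtn2"], 77)
        res = filter_insertions(calls, list(consensus.values()))
        assert len(res.kept) + len(res.rejected) == len(calls)


class TestElementMethylation:
    def test_single_copy_mean(self):
        import pandas as pd
        from btnmeth.te import TECopy
        copy = TECopy("c1", 100, 200, "+", 1.0, 1.0, True, 0, 100, "", "cp1")
        calls = pd.DataFrame({"contig": "c1", "pos": [110, 150],
                              "mc_frac": [0.1, 0.3], "hmc_frac": 0.0,
                              "depth": 9, "sample_id": "s"})
        em = element_methylation(calls, [copy])
        assert em.mean == pytest.approx(0.2)
        assert em.per_copy_means["cp1"] == pytest.approx(0.2)

    def test_pooled_mean_matches_per_site_oracle(self, healthy_sim, consensus):
        sg, calls, _ = healthy_sim
        copies = scan_copies(sg.genome, consensus["CedCL34"])
        em = element_methylation(calls, copies)
        vals = []
        for c in copies:
            sub = calls[(calls["contig"] == c.contig) & (calls["pos"] >= c.start)
                        & (calls["pos"] < c.end)]
            vals.append(sub["mc_frac"].to_numpy())
        assert em.mean == pytest.approx(np.concatenate(vals).mean())

    def test_no_sites_rejected(self):
        import pandas as pd
        from btnmeth.te import TECopy
        copy = TECopy("c9", 0, 10, "+", 1.0, 1.0, True, 0, 10, "", "cp")
        calls = pd.DataFrame({"contig": ["c1"], "pos": [5], "mc_frac": [0.1],
                              "hmc_frac": [0.0], "depth": [9], "sample_id": ["s"]})
        with pytest.raises(ValueError):
            element_methylation(calls, [copy])
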