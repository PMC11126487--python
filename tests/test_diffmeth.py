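import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from btnmeth.diffmeth import (GeneMethylationMatrix, bimodal_split,
                              differential_genes, gene_matrix,
                              hierarchical_cluster)
from btnmeth.features import FeatureTrack
from oracles import welch_t_oracle


def _calls(rows, sample="s"):
    return pd.DataFrame([(c, p, f, 0.0, 9, sample) for c, p, f in rows],
                        columns=["contig", "pos", "mc_frac", "hmc_frac",
                                 "depth", "sample_id"])


class TestGeneMatrix:
    def test_site_mean_per_gene(self):
        track = FeatureTrack.from_intervals("gene", [("c1", 0, 100, "+", "g1")])
        gm = gene_matrix({"s": _calls([("c1", 10, 0.2), ("c1", 20, 0.8),
                                       ("c1", 30, 0.5)])}, track)
        assert gm.values.loc["g1", "s"] == pytest.approx(0.5)

    def test_gene_without_sites_is_missing(self):
        track = FeatureTrack.from_intervals("gene", [("c1", 0, 50, "+", "g1"),
                                                     ("c1", 500, 600, "+", "g2")])
        gm = gene_matrix({"s": _calls([("c1", 10, 0.2), ("c1", 20, 0.4),
                                       ("c1", 30, 0.6)])}, track)
        assert np.isnan(gm.values.loc["g2", "s"])

    def test_matrix_matches_per_site_oracle(self, healthy_sim):
        sg, calls, _ = healthy_sim
        gm = gene_matrix({"h": calls}, sg.tracks["gene"])
        g = sg.truth["genes"].iloc[5]
        sub = calls[(calls["contig"] == g["contig"]) & (calls["pos"] >= g["start"])
                    & (calls["pos"] < g["end"])]
        assert gm.values.loc[g["gene_id"], "h"] == pytest.approx(sub["mc_frac"].mean())

    def test_empty_gene_track_errors(self):
        with pytest.raises(ValueError, match="empty"):
            gene_matrix({"s": _calls([])}, FeatureTrack("gene"))


class TestDifferentialGenes:
    def _matrix(self, values):
        df = pd.DataFrame(values).T  # gene -> sample values
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        meta = pd.DataFrame(index=pd.Index(df.columns, name="sample_id"))
        counts = df.notna().astype(int) * 10
        return GeneMethylationMatrix(df, counts, meta), list(df.columns)

    def test_identical_groups_all_ns(self, rng):
        vals = {f"g{i}": list(rng.uniform(0.1, 0.9, 1)) * 6 for i in range(20)}
        gm, cols = self._matrix(vals)
        res = differential_genes(gm, cols[:3], cols[3:])
        assert (res["class"] == "ns").all()
        assert np.allclose(res["log2fc"], 0.0)

    def test_planted_up_gene_detected(self, rng):
        vals = {"up": [0.05, 0.05, 0.06, 0.60, 0.62, 0.58, 0.61, 0.59],
                **{f"null{i}": list(np.repeat(rng.uniform(0.2, 0.4), 8)
                                    + rng.normal(0, 0.01, 8)) for i in range(10)}}
        gm, cols = self._matrix(vals)
        res = differential_genes(gm, cols[:3], cols[3:]).set_index("gene_id")
        assert res.loc["up", "class"] == "up"

    def test_welch_p_matches_textbook_oracle(self):
        a = [0.31, 0.28, 0.35]
        b = [0.52, 0.49, 0.61, 0.55, 0.47]
        vals = {"g": b[:0] + a + b}
        gm, cols = self._matrix(vals)
        res = differential_genes(gm, cols[:3], cols[3:])
        t_o, p_o = welch_t_oracle(np.array(b), np.array(a))
        assert res.loc[0, "t_statistic"] == pytest.approx(t_o, abs=1e-10)
        assert res.loc[0, "p_value"] == pytest.approx(p_o, abs=1e-10)

    def test_antisymmetry_under_group_swap(self, rng):
        vals = {f"g{i}": list(rng.uniform(0.05, 0.9, 8)) for i in range(30)}
        gm, cols = self._matrix(vals)
        fwd = differential_genes(gm, cols[:3], cols[3:]).set_index("gene_id")
        rev = differential_genes(gm, cols[3:], cols[:3]).set_index("gene_id")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert (fwd["class"].map(swap) == rev["class"]).all()

    def test_global_null_calibration(self, rng):
        """3-vs-5 Welch over 1,000 null genes: p<=0.05 rate 0.05 +/- 0.02 and
        essentially nothing passes the fold-change gate."""
        base = rng.uniform(0.2, 0.6, 1000)
        data = base[:, None] + rng.normal(0, 0.05, (1000, 8))
        df = pd.DataFrame(np.clip(data, 0.01, 0.99),
                          index=[f"g{i}" for i in range(1000)],
                          columns=[f"s{i}" for i in range(8)])
        gm = GeneMethylationMatrix(df, df.notna().astype(int) * 10,
                                   pd.DataFrame(index=df.columns))
        res = differential_genes(gm, list(df.columns[:3]), list(df.columns[3:]))
        rate = (res["p_value"] <= 0.05).mean()
        assert abs(rate - 0.05) <= 0.02
        assert (res["class"] != "ns").mean() <= 0.002

    def test_missing_gene_skipped_with_warning(self, rng):
        vals = {f"g{i}": list(rng.uniform(0.1, 0.9, 6)) for i in range(5)}
        gm, cols = self._matrix(vals)
        gm.values.iloc[0, 0] = np.nan
        res = differential_genes(gm, cols[:3], cols[3:])
        assert len(res) == 4


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self, rng):
        df = pd.DataFrame({"a": [0.1, 0.5, 0.9], "b": [0.1, 0.5, 0.9],
                           "c": [0.8, 0.2, 0.4]},
                          index=["g1", "g2", "g3"])
        gm = GeneMethylationMatrix(df, df * 0 + 5, pd.DataFrame(index=df.columns))
        res = hierarchical_cluster(gm, k=2)
        assert res.sample_linkage[0, 2] == pytest.approx(0.0)
        assert set(res.sample_linkage[0, :2]) == {0.0, 1.0}

    def test_four_point_average_linkage_oracle(self):
        pts = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 0.0],
                            "c": [10.0, 0.0], "d": [12.0, 0.0]})
        gm = GeneMethylationMatrix(pts, pts * 0 + 5, pd.DataFrame(index=pts.columns))
        Z = hierarchical_cluster(gm, k=2).sample_linkage
        # merges: (a,b)@1, (c,d)@2, then average linkage
        # d(ab,cd) = mean(|a-c|,|a-d|,|b-c|,|b-d|) = (10+12+9+11)/4 = 10.5
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(2.0)
        assert Z[2, 2] == pytest.approx(10.5)

    def test_k_larger_than_samples_errors(self):
        df = pd.DataFrame({"a": [0.1], "b": [0.2]})
        gm = GeneMethylationMatrix(df, df * 0 + 5, pd.DataFrame(index=df.columns))
        with pytest.raises(ValueError):
            hierarchical_cluster(gm, k=3)

    def test_cohort_recovers_three_purity_groups(self, cohort_matrix):
        res = hierarchical_cluster(cohort_matrix, k=3)
        groups = {}
        for sid, lab in res.sample_labels.items():
            kind = ("healthy" if "healthy" in sid
                    else "gill" if "gill" in sid else "haemolymph")
            groups.setdefault(lab, set()).add(kind)
        assert sorted(map(tuple, groups.values())) == \
            [("gill",), ("haemolymph",), ("healthy",)]


class TestBimodalSplit:
    def test_parameter_recovery_on_logit_mixture(self, rng):
        from scipy.special import expit
        z = np.concatenate([rng.normal(-3, 0.3, 400), rng.normal(0.5, 0.9, 400)])
        vals = expit(z)
        split = bimodal_split(vals, seed=0)
        assert split.bimodal
        assert split.low_mean == pytest.approx(expit(-3 + 0.3**2 / 2), rel=0.10)
        assert split.prop_high == pytest.approx(0.5, abs=0.05)
        assert split.low_mean < split.high_mean

    def test_unimodal_input_flagged(self, rng):
        vals = np.clip(rng.normal(0.4, 0.05, 300), 0.01, 0.99)
        split = bimodal_split(vals, seed=0)
        assert not split.bimodal

    def test_assignments_cover_all_genes(self, rng):
        vals = pd.Series(np.concatenate([rng.normal(0.03, 0.008, 50),
                                         rng.normal(0.6, 0.1, 50)]).clip(0.001, 0.999),
                         index=[f"g{i}" for i in range(100)])
        split = bimodal_split(vals, seed=0)
        assert set(split.assignments.index) == set(vals.index)
        assert set(split.assignments.unique()) == {"low", "high"}
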