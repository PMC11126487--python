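import numpy as np
import pandas as pd
import pytest

from btnmeth.features import FeatureTrack
from btnmeth.io import GenomeSequence
from btnmeth.profiling import (compare_distributions, exact_mannwhitney_p,
                               feature_distribution, genome_summary,
                               per_read_matrix, rolling_element_profile,
                               star_annotation, window_profile)


def _calls(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "mc_frac", "hmc_frac",
                                       "depth", "sample_id"])


class TestWindowProfile:
    def test_mean_of_three_sites(self):
        genome = [GenomeSequence("c1", "A" * 1000)]
        calls = _calls([("c1", p, f, 0.0, 10, "s")
                        for p, f in ((10, 0.2), (20, 0.4), (30, 0.6))])
        prof = window_profile(calls, genome, window_size=1000)
        assert prof.loc[0, "mean_mc"] == pytest.approx(0.4)
        assert prof.loc[0, "n_cpg"] == 3

    def test_empty_window_is_undefined(self):
        genome = [GenomeSequence("c1", "A" * 2000)]
        calls = _calls([("c1", 10, 0.5, 0.0, 10, "s")])
        prof = window_profile(calls, genome, window_size=1000)
        assert prof.loc[1, "n_cpg"] == 0 and np.isnan(prof.loc[1, "mean_mc"])

    def test_invariant_to_row_order_and_chunking(self, healthy_sim):
        sg, calls, _ = healthy_sim
        sub = calls[calls["contig"] == "chr1"].head(20_000)
        prof_a = window_profile(sub, sg.genome[:1])
        shuffled = sub.sample(frac=1.0, random_state=0)
        prof_b = window_profile(shuffled, sg.genome[:1])
        pd.testing.assert_frame_equal(prof_a, prof_b)

    def test_window_means_match_per_site_oracle(self, healthy_sim):
        sg, calls, _ = healthy_sim
        prof = window_profile(calls, sg.genome)
        sub = calls[calls["contig"] == "chr1"]
        w = 7
        oracle = sub[(sub["pos"] >= w * 100_000) & (sub["pos"] < (w + 1) * 100_000)]
        assert prof.loc[w, "mean_mc"] == pytest.approx(oracle["mc_frac"].mean())


class TestGenomeSummary:
    def test_hand_computed_mean_and_sample_sd(self):
        prof = pd.DataFrame({"mean_mc": [0.1, 0.3]})
        mean, sd = genome_summary(prof, "window", "mc")
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.1414, abs=1e-4)

    def test_single_window_sd_undefined(self):
        mean, sd = genome_summary(pd.DataFrame({"mean_mc": [0.2]}), "window")
        assert mean == 0.2 and np.isnan(sd)

    def test_site_level_summary(self):
        calls = _calls([("c1", 1, 0.2, 0.0, 5, "s"), ("c1", 3, 0.8, 0.0, 5, "s")])
        mean, _ = genome_summary(calls, "site", "mc")
        assert mean == pytest.approx(0.5)


class TestFeatureDistribution:
    def test_min_cpg_filter(self):
        track = FeatureTrack.from_intervals("gene", [("c1", 0, 100, "+", "g1"),
                                                     ("c1", 200, 300, "+", "g2")])
        calls = _calls([("c1", 10, 0.5, 0, 9, "s"), ("c1", 20, 0.7, 0, 9, "s"),
                        ("c1", 210, 0.9, 0, 9, "s")])
        assert list(feature_distribution(calls, track, min_cpg=2)) == [0.6]
        assert len(feature_distribution(calls, track, min_cpg=3)) == 0

    def test_satellite_array_is_modification_desert(self, healthy_sim):
        sg, calls, _ = healthy_sim
        for channel in ("mc", "hmc"):
            vals = feature_distribution(calls, sg.tracks["satellite"], channel)
            assert len(vals) and vals.mean() < 0.02


class TestMannWhitney:
    def test_star_legend(self):
        assert star_annotation(0.03) == "*"
        assert star_annotation(2e-5) == "****"
        assert star_annotation(0.2) == "ns"
        assert star_annotation(5e-3) == "**"
        assert star_annotation(5e-4) == "***"

    def test_exact_two_sided_p_one_third(self):
        res = compare_distributions([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"
        assert exact_mannwhitney_p([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_not_significant(self):
        res = compare_distributions([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0 and res.star == "ns"

    def test_p_matches_exact_enumeration_oracle(self, rng):
        for _ in range(12):
            n_a, n_b = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            a = rng.normal(size=n_a)
            b = rng.normal(0.8, 1.0, size=n_b)
            assert compare_distributions(a, b).p_value == \
                pytest.approx(exact_mannwhitney_p(a, b), abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        """Tie-free samples up to n=20: asymptotic p within 0.02 of exact."""
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(8, 21)))
            b = rng.normal(0.5, 1.0, size=int(rng.integers(8, 21)))
            exact = compare_distributions(a, b, exact_limit=10**9)
            approx = compare_distributions(a, b, exact_limit=0)
            assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_null_rejection_rate_calibrated(self, rng):
        """Type-I error at alpha=0.05 is 0.05 +/- 0.02 over 1,000 null reps."""
        rejections = 0
        for _ in range(1000):
            a, b = rng.normal(size=20), rng.normal(size=20)
            rejections += compare_distributions(a, b).p_value <= 0.05
        assert abs(rejections / 1000 - 0.05) <= 0.02


class TestRollingProfile:
    def test_constant_profile_stays_constant(self):
        pos = np.arange(0, 200, 5.0)
        prof = rolling_element_profile({"c1": (pos, np.full(len(pos), 0.5))})
        assert np.allclose(prof.smoothed_mean, 0.5)
        assert np.isnan(prof.ci95_low).all()  # one copy: CI undefined

    def test_step_profile_smooths_to_ramp(self):
        pos = np.arange(0, 200, 2.0)
        vals = (pos >= 100).astype(float)
        prof = rolling_element_profile({"c1": (pos, vals)}, window=20)
        sm = dict(zip(prof.positions, prof.smoothed_mean))
        assert sm[80.0] == 0.0 and sm[120.0] == 1.0
        assert 0.0 < sm[96.0] < 0.5 < sm[104.0] < 1.0
        # hand convolution at the midpoint: half the window is methylated
        assert sm[100.0] == pytest.approx(np.mean(vals[(pos >= 90) & (pos < 110)]))

    def test_hypermethylated_copy_exceeds_neighbours(self, rng):
        pos = np.arange(0, 500, 4.0)
        profiles = {f"low{i}": (pos, rng.uniform(0, 0.15, len(pos))) for i in range(5)}
        hot = rolling_element_profile({"hot": (pos, rng.uniform(0.6, 0.9, len(pos)))})
        neighbours = rolling_element_profile(profiles)
        assert np.nanmean(hot.smoothed_mean) > np.nanmean(neighbours.smoothed_mean) + 0.3
        assert (neighbours.ci95_low[1:-1] <= neighbours.smoothed_mean[1:-1]).all()


class TestPerReadMatrix:
    def test_identical_reads_fully_consistent(self):
        calls = pd.DataFrame({"read_id": ["r1"] * 3 + ["r2"] * 3,
                              "pos": [10, 20, 30] * 2,
                              "state": [1, 0, 1] * 2})
        res = per_read_matrix(calls)
        assert res.consistency_score == 1.0
        assert res.matrix.shape == (2, 3)

    def test_split_site_not_consistent(self):
        rows = []
        for r in range(10):
            rows.append({"read_id": f"r{r}", "pos": 1, "state": int(r < 5)})
            rows.append({"read_id": f"r{r}", "pos": 2, "state": 1})
        res = per_read_matrix(pd.DataFrame(rows))
        assert res.consistency_score == 0.5  # the 5/5 site fails the 80% bar

    def test_consistent_locus_preset(self):
        from btnmeth.sim import simulate_per_read_calls
        calls = simulate_per_read_calls(np.arange(0, 300, 10),
                                        np.tile([0.9, 0.1], 15), seed=3)
        assert per_read_matrix(calls).consistency_score >= 0.9
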