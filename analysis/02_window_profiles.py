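"""Genome-wide 100-kb window 5mC/5hmC profiles for the three lineages.

Reproduces the headline comparison: the healthy genome is globally more
methylated than the neoplastic haemolymphs, while 5hmC runs the other way.
Writes the per-window tables, a lineage summary, and Mann-Whitney feature
comparisons (gene-body vs satellite vs tandem repeats) with the
significance-star legend.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

from _common import ensure_dirs, lineage_sim
from btnmeth import io
from btnmeth.pipeline import profile_table
from btnmeth.profiling import compare_distributions, feature_distribution, genome_summary


def main():
    results, _ = ensure_dirs()
    summary_rows, comparison_rows = [], []
    for name in ("healthy", "cedbtn1", "cedbtn2"):
        sg, calls, _ = lineage_sim(name)
        prof = profile_table(sg, calls)
        io.write_tsv(prof.drop(columns=["hmc"]), results / f"02_windows_{name}.tsv")
        for channel in ("mc", "hmc"):
            mean, sd = genome_summary(prof, "window", channel)
            summary_rows.append({"lineage": name, "channel": channel,
                                 "window_mean_percent": round(mean * 100, 2),
                                 "window_sd_percent": round(sd * 100, 2)})
        dists = {feat: feature_distribution(calls, sg.tracks[feat])
                 for feat in ("gene", "tandem_repeat", "satellite")}
        for a, b in (("gene", "satellite"), ("gene", "tandem_repeat"),
                     ("tandem_repeat", "satellite")):
            res = compare_distributions(dists[a], dists[b])
            comparison_rows.append({
                "lineage": name, "feature_a": a, "feature_b": b,
                "median_a": round(float(pd.Series(dists[a]).median()), 4),
                "median_b": round(float(pd.Series(dists[b]).median()), 4),
                "u_statistic": res.u_statistic, "p_value": res.p_value,
                "star": res.star})
    summary = pd.DataFrame(summary_rows)
    io.write_tsv(summary, results / "02_window_summary.tsv")
    io.write_tsv(pd.DataFrame(comparison_rows), results / "02_feature_comparisons.tsv")
    print(summary.to_string(index=False))
    print("\nhealthy > neoplastic for 5mC; neoplastic > healthy for 5hmC;"
          " satellite array is a modification desert in every lineage.")


if __name__ == "__main__":
    main()
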