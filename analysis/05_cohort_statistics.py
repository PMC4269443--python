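"""Rank-based group comparisons and Spearman correlation heatmaps.

Mann–Whitney U per family × stratum (two groups), plus a Spearman heatmap
of BSH cluster abundances vs. the disease indicator, rendered to PNG and
emitted as TSV for testability.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = importlib.import_module("00_config")

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import seaborn as sns

import bilescreen as bs

out = cfg.RESULTS / "05_statistics"
out.mkdir(parents=True, exist_ok=True)

community = cfg.community()
cohort = bs.simulate_cohort(cfg.cohort_spec(), community.genomes)
analysis = bs.run_cohort_analysis(community, cohort, keep_tables=False)

comparisons = bs.group_comparisons(analysis.abundance)
comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)

wide = bs.to_wide(analysis.abundance, "BSH", "cluster")
indicator = (wide["group"] != "control").astype(int).to_numpy()
heat = bs.spearman_heatmap(wide.drop(columns="group"), indicator)
heat.to_csv(out / "spearman_bsh_clusters.tsv", sep="\t", index=False)

pivot = heat.pivot(index="stratum", columns="dataset", values="rho")
annot = heat.pivot(index="stratum", columns="dataset", values="flag").fillna("")
fig, ax = plt.subplots(figsize=(4, 3))
sns.heatmap(pivot, annot=annot, fmt="", cmap="vlag", center=0, ax=ax,
            cbar_kws={"label": "Spearman rho"})
fig.tight_layout()
fig.savefig(out / "spearman_bsh_clusters.png", dpi=150)

key = comparisons[comparisons["stratum"].isin(["TOTAL", "cluster:1"])]
print(key[["family", "stratum", "statistic", "p_printed", "mean_ranks"]].to_string(index=False))
print("\nSpearman vs disease:")
print(heat.to_string(index=False))
print(f"\nwrote statistics to {out}")
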