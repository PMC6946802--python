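#!/usr/bin/env python
"""Beta-diversity matrices and alpha diversity on the preprocessed survey.

Computes Jaccard and unweighted UniFrac between samples, Bray-Curtis between
species diet profiles, and host patristic distances; summarizes alpha
diversity (observed ASVs, Shannon, Pielou, Faith's PD) per host class.

Reads scratch/prep/ and scratch/sim/; matrices go to scratch/dist/ (large),
the alpha summary to results/.
"""

from pathlib import Path

import pandas as pd

from phylosym import distances as dist
from phylosym import io_prep

ROOT = Path(__file__).resolve().parent.parent
PREP = ROOT / "scratch" / "prep"

if not (PREP / "table.tsv").exists():
    raise SystemExit("run analysis/02_preprocess.py first")

table = io_prep.read_feature_table(PREP / "table.tsv")
metadata = io_prep.read_metadata(PREP / "metadata.tsv", renormalize_diet=True)
host_tree = io_prep.read_tree(PREP / "host_tree.nwk")
microbial_tree = io_prep.read_tree(ROOT / "scratch" / "sim" / "microbial_tree.nwk")

out = ROOT / "scratch" / "dist"
out.mkdir(parents=True, exist_ok=True)
dist.write_distance_matrix(dist.jaccard_matrix(table), out / "jaccard.tsv")
dist.write_distance_matrix(dist.unweighted_unifrac_matrix(table, microbial_tree), out / "unifrac.tsv")
dist.write_distance_matrix(dist.braycurtis_matrix(metadata.species_diet()), out / "diet_braycurtis.tsv")
dist.write_distance_matrix(dist.patristic_matrix(host_tree), out / "host_patristic.tsv")

alpha = pd.DataFrame(
    {m: dist.alpha_diversity(table, m) for m in ("observed", "shannon", "pielou")}
)
alpha["faith_pd"] = dist.alpha_diversity(table, "faith_pd", tree=microbial_tree)
alpha["host_class"] = metadata.frame.loc[alpha.index, "host_class"]
summary = alpha.groupby("host_class").agg(["mean", "std"]).round(3)
summary.columns = ["_".join(c) for c in summary.columns]
summary.to_csv(ROOT / "results" / "03_alpha_diversity_by_class.tsv", sep="\t")
print("distance matrices -> scratch/dist/")
print(summary)
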