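#!/usr/bin/env python
"""Per-ASV host-specificity statistics on the preprocessed survey.

Pielou-evenness SES per class (how evenly each ASV spreads over the class's
orders, against a uniform-draw null), log risk ratios of mammal-vs-bird
prevalence (cap 3), and the per-sample mean LRR by host order.

Writes per-ASV and per-sample tables plus a class-level summary to results/.
"""

from pathlib import Path

import pandas as pd

from phylosym import io_prep, specificity

ROOT = Path(__file__).resolve().parent.parent
SEED = 20260921
PREP = ROOT / "scratch" / "prep"

if not (PREP / "table.tsv").exists():
    raise SystemExit("run analysis/02_preprocess.py first")

table = io_prep.read_feature_table(PREP / "table.tsv")
metadata = io_prep.read_metadata(PREP / "metadata.tsv", renormalize_diet=True)

ses = {}
for class_name in ("Mammalia", "Aves"):
    ses[class_name] = specificity.evenness_ses(
        table, metadata, class_name, n_perm=100, min_samples=10, seed=SEED
    )

lrr = specificity.log_risk_ratio(table, metadata, cap=3.0)
per_sample = specificity.sample_mean_lrr(table, lrr)
per_sample["host_order"] = metadata.frame.loc[per_sample.index, "host_order"]
per_sample["host_class"] = metadata.frame.loc[per_sample.index, "host_class"]

per_asv = lrr.copy()
for class_name, frame in ses.items():
    per_asv[f"ses_{class_name}"] = frame["ses"]
per_asv.to_csv(ROOT / "results" / "05_per_asv_specificity.tsv", sep="\t", index_label="asv_id")
per_sample.to_csv(ROOT / "results" / "05_per_sample_mean_lrr.tsv", sep="\t", index_label="sample_id")

summary = pd.DataFrame(
    {
        "median_ses": {c: ses[c]["ses"].median() for c in ses},
        "n_scored": {c: len(ses[c]) for c in ses},
        "mean_sample_lrr": per_sample.groupby("host_class")["mean_lrr"].mean(),
    }
).round(3)
summary.to_csv(ROOT / "results" / "05_specificity_summary.tsv", sep="\t", index_label="host_class")
print(summary)
n_cap = int((lrr["lrr"].abs() == 3.0).sum())
print(f"{n_cap} of {len(lrr)} scored ASVs at the +/-3 LRR cap (class-exclusive)")
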