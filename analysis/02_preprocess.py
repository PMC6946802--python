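#!/usr/bin/env python
"""Apply the survey preprocessing: rarefaction, capping, prevalence filter.

Samples are rarefied to 10,000 reads (dropping shallower samples), at most 5
individuals are kept per species, ASVs seen in fewer than 10 samples are
removed, and IDs are harmonized across table / metadata / host tree.

Reads scratch/sim/ (from 01), writes scratch/prep/ and a drops summary to
results/.
"""

from pathlib import Path

import pandas as pd

from phylosym import io_prep

ROOT = Path(__file__).resolve().parent.parent
SEED = 20260921
SIM = ROOT / "scratch" / "sim"

if not (SIM / "feature_table.tsv").exists():
    raise SystemExit("run analysis/01_simulate.py first")

table = io_prep.read_feature_table(SIM / "feature_table.tsv")
metadata = io_prep.read_metadata(SIM / "metadata.tsv", renormalize_diet=True)
host_tree = io_prep.read_tree(SIM / "host_tree.nwk")

steps = [("input", table.shape)]
table = io_prep.rarefy(table, 10000, seed=SEED)
steps.append(("rarefied_10000", table.shape))
table, metadata, host_tree = io_prep.harmonize_ids(table, metadata, host_tree)
table = io_prep.cap_per_species(table, metadata, max_n=5, seed=SEED)
steps.append(("capped_5_per_species", table.shape))
table = io_prep.filter_min_prevalence(table, 10)
steps.append(("min_10_samples", table.shape))
table, metadata, host_tree = io_prep.harmonize_ids(table, metadata, host_tree)
steps.append(("harmonized", table.shape))

out = ROOT / "scratch" / "prep"
out.mkdir(parents=True, exist_ok=True)
header = [f"preprocess seed={SEED} depth=10000 cap=5 min_samples=10"]
io_prep.write_feature_table(table, out / "table.tsv", header_lines=header)
io_prep.write_metadata(metadata.select(table.sample_ids), out / "metadata.tsv", header_lines=header)
io_prep.write_tree(host_tree, out / "host_tree.nwk")

frame = pd.DataFrame(
    [{"step": name, "n_asvs": shape[0], "n_samples": shape[1]} for name, shape in steps]
)
frame.to_csv(ROOT / "results" / "02_preprocessing_steps.tsv", sep="\t", index=False)
print(frame.to_string(index=False))
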