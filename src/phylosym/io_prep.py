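"""Readers, writers, and the preprocessing steps applied to raw inputs.

Preprocessing mirrors the standard workflow for large cross-species 16S
surveys: rarefaction to a fixed read depth, capping the number of individuals
retained per host species, dropping rare ASVs, and harmonizing sample /
species IDs across table, metadata, and host tree.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from phylosym._seeding import substream
from phylosym.containers import DIET_PREFIX, FeatureTable, SampleMetadata

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "rarefy",
    "cap_per_species",
    "filter_min_prevalence",
    "harmonize_ids",
]

logger = logging.getLogger("phylosym")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path, format: str = "tsv") -> FeatureTable:
    """Read an ASV-by-sample count table.

    ``tsv``: tab-separated, header row of sample IDs, first column ASV IDs.
    ``biom_json``: BIOM v1 (JSON) with sparse or dense matrix data; read-only.
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = next(line for line in fh if not line.startswith("#"))
        sample_ids = header.rstrip("\n").split("\t")[1:]
        dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
        if dupes:
            raise ValueError(f"{path}: duplicate sample IDs: {sorted(dupes)}")
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
        frame.columns = sample_ids
        frame.index = frame.index.astype(str)
        try:
            frame = frame.apply(pd.to_numeric)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric count: {exc}") from exc
        return FeatureTable(frame)
    if format == "biom_json":
        with open(path) as fh:
            doc = json.load(fh)
        asv_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        counts = np.zeros(shape, dtype=np.int64)
        if doc.get("matrix_type", "sparse") == "sparse":
            for r, c, v in doc["data"]:
                counts[int(r), int(c)] = v
        else:
            counts[:] = np.asarray(doc["data"])
        return FeatureTable.from_arrays(counts, asv_ids, sample_ids)
    raise ValueError(f"unknown feature-table format: {format!r}")


def write_feature_table(table: FeatureTable, path, header_lines=()) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("asv_id\t" + "\t".join(table.sample_ids) + "\n")
        table.data.to_csv(fh, sep="\t", header=False)


def read_metadata(path, renormalize_diet: bool = False, diet_tolerance: float = 1e-6) -> SampleMetadata:
    """Read sample metadata TSV (first column = sample ID).

    Diet columns are those prefixed ``diet_``.  If their per-row sum deviates
    from 100 by more than ``diet_tolerance``, a warning is logged; with
    ``renormalize_diet`` the rows are rescaled to 100, otherwise it is an
    error.
    """
    frame = pd.read_csv(Path(path), sep="\t", index_col=0, comment="#", dtype=str)
    frame.index = frame.index.astype(str)
    diet_cols = [c for c in frame.columns if c.startswith(DIET_PREFIX)]
    for c in diet_cols:
        frame[c] = pd.to_numeric(frame[c])
    md = SampleMetadata(frame, diet_tolerance=diet_tolerance)
    if diet_cols:
        dev = md.check_diet_sums()
        off = dev[dev > diet_tolerance]
        if len(off):
            if not renormalize_diet:
                raise ValueError(
                    f"diet percentages do not sum to 100 for {len(off)} sample(s) "
                    f"(max deviation {off.max():.4g}); pass renormalize_diet=True to rescale"
                )
            logger.warning("renormalizing diet for %d sample(s) off by up to %.4g", len(off), off.max())
            sums = md.diet.sum(axis=1)
            frame = frame.copy()
            frame.loc[:, diet_cols] = md.diet.div(sums, axis=0) * 100.0
            md = SampleMetadata(frame, diet_tolerance=diet_tolerance)
    return md


def write_metadata(metadata: SampleMetadata, path, header_lines=()) -> None:
    with open(Path(path), "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sample_id\t" + "\t".join(metadata.frame.columns) + "\n")
        metadata.frame.to_csv(fh, sep="\t", header=False)


def _newick_offset_hint(text: str) -> int:
    """Best-effort character offset of the first structural problem."""
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
        elif ch == ";" and depth > 0:
            return i
    return len(text)


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; duplicate tip labels are an error."""
    path = Path(path)
    text = path.read_text()
    try:
        tree = TreeNode.read(path, format="newick")
    except Exception as exc:
        raise ValueError(
            f"{path}: unparseable Newick near character {_newick_offset_hint(text)}: {exc}"
        ) from exc
    names = [t.name for t in tree.tips()]
    seen, dupes = set(), set()
    for n in names:
        (dupes if n in seen else seen).add(n)
    if dupes:
        raise ValueError(f"{path}: duplicate tip label(s): {sorted(dupes)}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(Path(path), format="newick")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int, seed: int | None = None) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (and logged).  Sampling
    is multivariate hypergeometric per sample, deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = substream(seed, "rarefy")
    sums = table.sample_sums()
    kept = [s for s in table.sample_ids if sums[s] >= depth]
    dropped = [s for s in table.sample_ids if sums[s] < depth]
    if dropped:
        logger.info("rarefy: dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    out = {}
    for s in kept:
        col = table.data[s].to_numpy()
        if sums[s] == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    frame = pd.DataFrame(out, index=table.data.index, columns=kept, dtype=np.int64)
    return FeatureTable(frame)


def cap_per_species(
    table: FeatureTable, metadata: SampleMetadata, max_n: int, seed: int | None = None
) -> FeatureTable:
    """Keep at most ``max_n`` samples per host species, chosen uniformly."""
    if max_n < 1:
        raise ValueError(f"max_n must be >= 1, got {max_n}")
    rng = substream(seed, "cap_per_species")
    species = metadata.species_of(table.sample_ids)
    keep: set[str] = set()
    for sp in sorted(species.unique()):
        members = [s for s in table.sample_ids if species[s] == sp]
        if len(members) <= max_n:
            keep.update(members)
        else:
            chosen = rng.choice(len(members), size=max_n, replace=False)
            keep.update(members[i] for i in chosen)
    kept = [s for s in table.sample_ids if s in keep]
    return table.select_samples(kept)


def filter_min_prevalence(table: FeatureTable, min_samples: int) -> FeatureTable:
    """Drop ASVs present (count > 0) in fewer than ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    prev = table.asv_prevalence()
    kept = [a for a in table.asv_ids if prev[a] >= min_samples]
    return table.select_asvs(kept)


def harmonize_ids(
    table: FeatureTable, metadata: SampleMetadata, host_tree: TreeNode
) -> tuple[FeatureTable, SampleMetadata, TreeNode]:
    """Restrict all three inputs to their common sample/species universe.

    Samples must appear in both table and metadata and their species must be a
    tip of the host tree; the tree is pruned to the surviving species.
    Dropped IDs are logged; an empty intersection is an error.
    """
    tree_species = {t.name for t in host_tree.tips()}
    common = [s for s in table.sample_ids if s in metadata.frame.index]
    dropped_samples = [s for s in table.sample_ids if s not in metadata.frame.index]
    species = metadata.species_of(common)
    kept = [s for s in common if species[s] in tree_species]
    dropped_samples += [s for s in common if species[s] not in tree_species]
    if not kept:
        raise ValueError("no samples survive table/metadata/tree harmonization")
    if dropped_samples:
        logger.info("harmonize_ids: dropping %d sample(s): %s", len(dropped_samples), dropped_samples)
    kept_species = sorted(set(species[s] for s in kept))
    pruned = host_tree.shear(kept_species)
    pruned.prune()
    return table.select_samples(kept), metadata.select(kept), pruned
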