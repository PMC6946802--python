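"""Synthetic data with controlled host specificity and phylosymbiosis.

The generator produces the four inputs every pipeline stage consumes — host
tree with class/order taxonomy, sample metadata with diet profiles, microbial
tree, ASV count table — plus the generating truth, so estimator behavior can
be checked against known parameters.

Model
-----
Hosts: one pure-birth (Yule) tree per host class, rescaled ultrametric, the
classes joined at the root of a deeper ultrametric tree.  Order-level taxa
are the clades obtained by cutting each class subtree at the depth where
exactly ``n_orders`` lineages exist.  Diet: each order draws a mean
composition from a flat Dirichlet; species draw around their order's mean,
so diet is phylogenetically structured at the order level.

Microbes: every ASV belongs to one of three guilds.  A *phylogeny-tracking*
ASV has a focal host species and occupies a sample of species i with
probability ``b + (c - b) * exp(-d(i, focal) / lambda)`` where d is patristic
distance (Ma) — small lambda confines the ASV to the focal species' close
relatives ("mammal-like", order-restricted), large lambda approaches the
cosmopolitan limit ("bird-like", broadly shared).  A *diet-tracking* ASV
replaces d with the Bray-Curtis distance between diet profiles (scale
``lambda_diet``).  A *cosmopolitan* ASV occupies every sample with
probability c.  Occupied cells get lognormal abundances and each sample is
multinomially resampled to a fixed read depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from phylosym._seeding import substream
from phylosym.containers import FeatureTable, SampleMetadata
from phylosym.distances import braycurtis_matrix, patristic_matrix
from phylosym.io_prep import write_feature_table, write_metadata, write_tree

__all__ = ["SimConfig", "SimTruth", "SimResult", "sim_host_tree", "sim_diet", "sim_microbial_tree", "sim_table", "simulate"]


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate a two-class vertebrate survey."""

    n_species: int = 32  # per class
    n_orders: int = 8  # per class
    class_names: tuple = ("Mammalia", "Aves")
    tree_depth: float = 200.0  # root depth, Ma
    class_crown_frac: float = 0.75  # class crown age / tree_depth
    samples_per_species: int = 3
    n_asvs: int = 400
    reads_per_sample: int = 10000
    specificity_lambda: float | dict = 20.0  # Ma; dict maps class -> lambda
    lambda_diet: float | dict = 0.3  # Bray-Curtis units; dict maps class -> scale
    guild_mix: tuple = (0.7, 0.15, 0.15)  # phylogeny / diet / cosmopolitan
    baseline_occupancy: float = 0.01  # b
    focal_occupancy: float = 0.9  # c
    diet_categories: tuple = ("plant", "seed", "fruit", "invertebrate", "meat")
    diet_concentration: float = 8.0  # species around order mean
    abundance_sigma: float = 1.0  # lognormal sd of occupied-cell abundance
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.baseline_occupancy <= self.focal_occupancy <= 1):
            raise ValueError("need 0 <= baseline_occupancy <= focal_occupancy <= 1")
        if abs(sum(self.guild_mix) - 1.0) > 1e-9:
            raise ValueError("guild_mix must sum to 1")
        if self.n_species < self.n_orders or self.n_orders < 2:
            raise ValueError("need n_species >= n_orders >= 2")

    def lambda_for(self, class_name: str) -> float:
        if isinstance(self.specificity_lambda, dict):
            return float(self.specificity_lambda[class_name])
        return float(self.specificity_lambda)

    def lambda_diet_for(self, class_name: str) -> float:
        if isinstance(self.lambda_diet, dict):
            return float(self.lambda_diet[class_name])
        return float(self.lambda_diet)


@dataclass
class SimTruth:
    """Generating parameters per ASV plus the occupancy-probability matrix."""

    asv_frame: pd.DataFrame  # guild, focal_species, lambda_used
    occupancy_prob: pd.DataFrame  # ASV x species

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.asv_frame.to_csv(fh, sep="\t")


@dataclass
class SimResult:
    config: SimConfig
    host_tree: TreeNode
    microbial_tree: TreeNode
    metadata: SampleMetadata
    table: FeatureTable
    truth: SimTruth

    def write_fixtures(self, outdir) -> dict[str, Path]:
        """Write the standard file set (table, metadata, two trees, truth)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "table": outdir / "feature_table.tsv",
            "metadata": outdir / "metadata.tsv",
            "host_tree": outdir / "host_tree.nwk",
            "microbial_tree": outdir / "microbial_tree.nwk",
            "truth": outdir / "truth.tsv",
        }
        header = [f"phylosym simulate seed={self.config.seed}"]
        write_feature_table(self.table, paths["table"], header_lines=header)
        write_metadata(self.metadata, paths["metadata"], header_lines=header)
        write_tree(self.host_tree, paths["host_tree"])
        write_tree(self.microbial_tree, paths["microbial_tree"])
        self.truth.to_tsv(paths["truth"], header_lines=header)
        return paths


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _yule(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Pure-birth tree; returns a rooted binary tree with exact birth times."""
    root = TreeNode()
    root.birth = 0.0
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.split_time = t
        for _ in range(2):
            child = TreeNode()
            child.birth = t
            parent.append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in root.traverse(include_self=True):
        end = getattr(node, "split_time", t_end)
        node.length = end - node.birth
    root.length = None
    return root


def _rescale_ultrametric(tree: TreeNode, depth: float) -> None:
    """Scale branch lengths so every root-to-tip path equals ``depth``."""
    heights = [tree.distance(tip) for tip in tree.tips()]
    h = heights[0]
    assert np.allclose(heights, h)
    scale = depth / h
    for node in tree.traverse(include_self=False):
        node.length = (node.length or 0.0) * scale


def _assign_orders(class_root: TreeNode, n_orders: int, class_name: str) -> dict[str, str]:
    """Order labels from the depth cut that leaves exactly ``n_orders`` lineages.

    Returns species -> order.  Internal-node depths below the class root sort
    the cut; with fewer splits than needed (n_orders > n_tips) it errors.
    """
    depths = []  # depth of each internal node's split below the class root
    node_depth = {id(class_root): 0.0}
    for node in class_root.preorder(include_self=False):
        node_depth[id(node)] = node_depth[id(node.parent)] + (node.length or 0.0)
    internal_depths = sorted(
        node_depth[id(n)] for n in class_root.traverse(include_self=True) if not n.is_tip()
    )
    if n_orders - 1 >= len(internal_depths):
        raise ValueError(
            f"cannot cut {n_orders} orders from a {len(internal_depths) + 1}-lineage subtree; "
            "decrease n_orders or increase n_species"
        )
    lo, hi = internal_depths[n_orders - 2], internal_depths[n_orders - 1]
    if not hi > lo:
        raise ValueError("tied divergence depths prevent an exact order cut; try another seed")
    cut = 0.5 * (lo + hi)
    orders: dict[str, str] = {}
    order_roots = []
    for node in class_root.preorder(include_self=True):
        parent_d = node_depth[id(node.parent)] if node.parent is not None and id(node.parent) in node_depth else -1.0
        d = node_depth[id(node)]
        if d >= cut and (node is class_root or parent_d < cut):
            order_roots.append(node)
    if len(order_roots) != n_orders:
        raise ValueError("order cut did not yield the requested number of clades; try another seed")
    # larger clades get smaller order indices (stable, size-based tie-break)
    order_roots.sort(key=lambda nd: -len(list(nd.tips(include_self=True))))
    for j, node in enumerate(order_roots, start=1):
        label = f"{class_name}_ord{j:02d}"
        for tip in node.tips(include_self=True):
            orders[tip.name] = label
    return orders


def sim_host_tree(config: SimConfig) -> tuple[TreeNode, SampleMetadata]:
    """Simulate the host phylogeny and the sample-metadata skeleton.

    One Yule subtree per class, each rescaled to crown age
    ``class_crown_frac * tree_depth`` and joined at a root of depth
    ``tree_depth``; species and order names are deterministic under the seed.
    Diet columns are filled by :func:`sim_diet`.
    """
    rng = substream(config.seed, "host_tree")
    class_trees = []
    orders_all: dict[str, str] = {}
    for class_name in config.class_names:
        sub = _yule(config.n_species, rng)
        crown = config.tree_depth * (config.class_crown_frac if len(config.class_names) > 1 else 1.0)
        _rescale_ultrametric(sub, crown)
        for i, tip in enumerate(sub.tips()):
            tip.name = f"{class_name}_sp{i + 1:03d}"
        orders_all.update(_assign_orders(sub, config.n_orders, class_name))
        class_trees.append(sub)
    if len(class_trees) == 1:
        tree = class_trees[0]
    else:
        tree = TreeNode()
        stem = config.tree_depth * (1.0 - config.class_crown_frac)
        for sub in class_trees:
            sub.length = stem
            tree.append(sub)

    rows = []
    idx = 0
    for class_name, sub in zip(config.class_names, class_trees):
        for tip in sub.tips():
            for _ in range(config.samples_per_species):
                idx += 1
                rows.append(
                    {
                        "sample_id": f"S{idx:04d}",
                        "host_species": tip.name,
                        "host_order": orders_all[tip.name],
                        "host_class": class_name,
                        "flight": "flighted" if class_name == "Aves" else "flightless",
                        "captive_wild": "wild",
                    }
                )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return tree, SampleMetadata(frame)


def sim_diet(metadata: SampleMetadata, config: SimConfig, seed: int | None = None) -> SampleMetadata:
    """Fill diet columns: order-level Dirichlet means, species drawn around them.

    All samples of a species share its diet (a species-level trait); rows sum
    to 100.  ``diet_concentration -> inf`` collapses species onto the order
    mean.
    """
    rng = substream(config.seed if seed is None else seed, "diet")
    k = len(config.diet_categories)
    frame = metadata.frame.copy()
    order_means: dict[str, np.ndarray] = {}
    for order in sorted(frame["host_order"].unique()):
        order_means[order] = rng.dirichlet(np.ones(k))
    species_diet: dict[str, np.ndarray] = {}
    for sp in sorted(frame["host_species"].unique()):
        order = frame.loc[frame["host_species"] == sp, "host_order"].iloc[0]
        alpha = config.diet_concentration * (order_means[order] + 1e-3)
        species_diet[sp] = rng.dirichlet(alpha) * 100.0
    diet = np.array([species_diet[sp] for sp in frame["host_species"]])
    for j, cat in enumerate(config.diet_categories):
        frame[f"diet_{cat}"] = diet[:, j]
    return SampleMetadata(frame)


def sim_microbial_tree(config: SimConfig) -> TreeNode:
    """Ultrametric Yule tree over the ASVs, unit height."""
    if config.n_asvs < 2:
        raise ValueError("need n_asvs >= 2")
    rng = substream(config.seed, "microbial_tree")
    tree = _yule(config.n_asvs, rng)
    _rescale_ultrametric(tree, 1.0)
    for i, tip in enumerate(tree.tips()):
        tip.name = f"asv{i + 1:04d}"
    return tree


# ---------------------------------------------------------------------------
# occupancy + counts
# ---------------------------------------------------------------------------

def sim_table(
    config: SimConfig,
    host_tree: TreeNode,
    metadata: SampleMetadata,
    microbial_tree: TreeNode,
) -> tuple[FeatureTable, SimTruth]:
    """Draw the ASV count table from the guild-structured occupancy model."""
    rng = substream(config.seed, "occupancy")
    species = sorted({t.name for t in host_tree.tips()})
    sp_index = {sp: i for i, sp in enumerate(species)}
    host_d = patristic_matrix(host_tree, species)
    diet_sp = metadata.species_diet().loc[species]
    diet_d = braycurtis_matrix(diet_sp)
    sp_class = (
        metadata.frame.drop_duplicates("host_species").set_index("host_species")["host_class"].to_dict()
    )
    asv_ids = [t.name for t in microbial_tree.tips()]
    n_asvs, n_species = len(asv_ids), len(species)
    b, c = config.baseline_occupancy, config.focal_occupancy

    guilds = rng.choice(
        ["phylogeny", "diet", "cosmopolitan"], size=n_asvs, p=list(config.guild_mix)
    )
    probs = np.empty((n_asvs, n_species))
    focal = np.empty(n_asvs, dtype=object)
    lam_used = np.full(n_asvs, np.nan)
    for a in range(n_asvs):
        if guilds[a] == "phylogeny":
            f = species[int(rng.integers(n_species))]
            lam = config.lambda_for(sp_class[f])
            d = host_d.data[sp_index[f]]
            probs[a] = b + (c - b) * np.exp(-d / lam)
            focal[a], lam_used[a] = f, lam
        elif guilds[a] == "diet":
            f = species[int(rng.integers(n_species))]
            lam = config.lambda_diet_for(sp_class[f])
            d = diet_d.data[sp_index[f]]
            probs[a] = b + (c - b) * np.exp(-d / lam)
            focal[a], lam_used[a] = f, lam
        else:
            probs[a] = c
            focal[a] = ""

    sample_ids = metadata.sample_ids
    sp_of_sample = metadata.species_of(sample_ids)
    col_prob = probs[:, [sp_index[sp_of_sample[s]] for s in sample_ids]]
    occupied = rng.random(col_prob.shape) < col_prob
    # every sample must contain something: force the most probable ASV if empty
    empty_cols = ~occupied.any(axis=0)
    if empty_cols.any():
        occupied[col_prob.argmax(axis=0)[empty_cols], np.where(empty_cols)[0]] = True

    abundance = np.where(occupied, rng.lognormal(0.0, config.abundance_sigma, occupied.shape), 0.0)
    counts = np.zeros(occupied.shape, dtype=np.int64)
    depth_rng = substream(config.seed, "depth")
    for j in range(len(sample_ids)):
        w = abundance[:, j]
        total = w.sum()
        counts[:, j] = depth_rng.multinomial(config.reads_per_sample, w / total)

    table = FeatureTable.from_arrays(counts, asv_ids, sample_ids)
    truth = SimTruth(
        asv_frame=pd.DataFrame(
            {"guild": guilds, "focal_species": focal, "lambda_used": lam_used},
            index=pd.Index(asv_ids, name="asv_id"),
        ),
        occupancy_prob=pd.DataFrame(probs, index=asv_ids, columns=species),
    )
    return table, truth


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: trees, taxonomy, diets, occupancy, counts."""
    host_tree, skeleton = sim_host_tree(config)
    metadata = sim_diet(skeleton, config)
    microbial_tree = sim_microbial_tree(config)
    table, truth = sim_table(config, host_tree, metadata, microbial_tree)
    return SimResult(
        config=config,
        host_tree=host_tree,
        microbial_tree=microbial_tree,
        metadata=metadata,
        table=table,
        truth=truth,
    )
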