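"""Node-wise phylosymbiosis scan over the host phylogeny.

Phylosymbiosis — closer host species carrying more similar microbiomes — is
quantified as the Mantel Pearson correlation between microbiome dissimilarity
and host patristic distance, plus the partial Mantel correlation conditioned
on dietary (Bray-Curtis) distances.  The scan evaluates both at every
internal node of the host tree with at least ``min_tips`` descendant species,
on one randomly chosen representative sample per species (avoiding zero-length
within-species branches).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from skbio import DistanceMatrix, TreeNode

from phylosym._seeding import substream
from phylosym.containers import FeatureTable, SampleMetadata
from phylosym.distances import patristic_matrix
from phylosym.matrix_stats import mantel, partial_mantel

__all__ = [
    "pick_representatives",
    "species_distance_matrix",
    "node_scan",
    "between_species_pairs",
    "PhylosymbiosisScan",
    "annotated_newick",
]


@dataclass
class PhylosymbiosisScan:
    """Result of the node scan: one row per qualifying internal node."""

    rows: pd.DataFrame  # node_id, n_tips, r, p, partial_r, partial_p
    representatives: dict  # species -> sample_id
    seed: int | None
    min_tips: int

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.rows.to_csv(fh, sep="\t", index=False)


def pick_representatives(
    table: FeatureTable, metadata: SampleMetadata, seed: int | None = None
) -> dict[str, str]:
    """Choose exactly one sample per species, uniformly at random."""
    rng = substream(seed, "pick_representatives")
    species = metadata.species_of(table.sample_ids)
    reps: dict[str, str] = {}
    for sp in sorted(species.unique()):
        members = [s for s in table.sample_ids if species[s] == sp]
        reps[sp] = members[int(rng.integers(len(members)))]
    return reps


def species_distance_matrix(sample_d: DistanceMatrix, representatives: dict[str, str]) -> DistanceMatrix:
    """Restrict a sample-level matrix to the representatives, relabeled by species."""
    species = sorted(representatives)
    sub = sample_d.filter([representatives[sp] for sp in species])
    return DistanceMatrix(sub.data, ids=species)


def _node_ids(tree: TreeNode) -> dict[int, str]:
    """Stable id per node: its name if set, else 'node<k>' in preorder."""
    out = {}
    for k, node in enumerate(tree.preorder(include_self=True)):
        out[id(node)] = node.name if node.name else f"node{k}"
    return out


def node_scan(
    microbiome_d: DistanceMatrix,
    host_tree: TreeNode,
    diet_d: DistanceMatrix | None = None,
    min_tips: int = 7,
    n_perm: int = 999,
    seed: int | None = None,
    representatives: dict | None = None,
    bh_adjust: bool = False,
) -> PhylosymbiosisScan:
    """Mantel scan at every host-tree node with >= ``min_tips`` descendants.

    ``microbiome_d`` (and ``diet_d`` if given) must be indexed by species —
    i.e. already collapsed to one representative sample per species via
    :func:`species_distance_matrix`.  For each qualifying node all matrices
    are restricted to the node's descendant species and Mantel / diet-partial
    Mantel tests are run against patristic distances.
    """
    species_in_d = set(microbiome_d.ids)
    tree_species = [t.name for t in host_tree.tips()]
    missing = [s for s in tree_species if s not in species_in_d]
    if missing:
        raise ValueError(f"species in tree but absent from microbiome matrix: {missing}")
    if diet_d is not None:
        missing_diet = [s for s in tree_species if s not in set(diet_d.ids)]
        if missing_diet:
            raise ValueError(f"species absent from diet matrix: {missing_diet}")
    host_d = patristic_matrix(host_tree)
    ids = _node_ids(host_tree)
    rows = []
    for node in host_tree.preorder(include_self=True):
        if node.is_tip():
            continue
        tips = [t.name for t in node.tips()]
        if len(tips) < min_tips:
            continue
        sub_m = microbiome_d.filter(tips)
        sub_h = host_d.filter(tips)
        node_seed = None if seed is None else int(substream(seed, ids[id(node)]).integers(2**31))
        res = mantel(sub_h, sub_m, n_perm=n_perm, seed=node_seed)
        row = {
            "node_id": ids[id(node)],
            "n_tips": len(tips),
            "r": res.r,
            "p": res.p,
            "partial_r": float("nan"),
            "partial_p": float("nan"),
        }
        if diet_d is not None:
            pres = partial_mantel(sub_h, sub_m, diet_d.filter(tips), n_perm=n_perm, seed=node_seed)
            row["partial_r"] = pres.r
            row["partial_p"] = pres.p
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["node_id", "n_tips", "r", "p", "partial_r", "partial_p"])
    if bh_adjust and len(frame):
        frame["p_bh"] = _bh(frame["p"].to_numpy())
    return PhylosymbiosisScan(rows=frame, representatives=representatives or {}, seed=seed, min_tips=min_tips)


def _bh(p):
    import numpy as np

    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def between_species_pairs(
    microbiome_d: DistanceMatrix,
    host_d: DistanceMatrix,
    metadata: SampleMetadata,
    max_divergence: float | None = None,
) -> pd.DataFrame:
    """All between-species sample pairs with host and microbiome distances.

    ``microbiome_d`` is sample-level; ``host_d`` is species-level patristic.
    Within-species pairs are excluded; with ``max_divergence`` only pairs with
    host distance <= the cutoff (e.g. 150 Ma) are kept.
    """
    ids = list(microbiome_d.ids)
    species = metadata.species_of(ids)
    records = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            sp_i, sp_j = species[ids[i]], species[ids[j]]
            if sp_i == sp_j:
                continue
            hd = host_d[sp_i, sp_j]
            if max_divergence is not None and hd > max_divergence:
                continue
            records.append(
                {
                    "sample_a": ids[i],
                    "sample_b": ids[j],
                    "species_a": sp_i,
                    "species_b": sp_j,
                    "host_distance": hd,
                    "microbiome_distance": microbiome_d[i, j],
                }
            )
    return pd.DataFrame(
        records,
        columns=["sample_a", "sample_b", "species_a", "species_b", "host_distance", "microbiome_distance"],
    )


def annotated_newick(host_tree: TreeNode, scan: PhylosymbiosisScan) -> str:
    """Newick string where qualifying nodes carry their Mantel r as a comment.

    Branches of scanned nodes are tagged ``[&r=<value>]`` after the branch
    length, the convention tree renderers accept for per-branch coloring.
    """
    by_node = {row.node_id: row.r for row in scan.rows.itertuples()}
    ids = _node_ids(host_tree)

    def _fmt(node: TreeNode) -> str:
        if node.is_tip():
            core = node.name or ""
        else:
            core = "(" + ",".join(_fmt(c) for c in node.children) + ")"
            if node.name:
                core += node.name
        if node.length is not None:
            core += f":{node.length:g}"
        node_id = ids[id(node)]
        if node_id in by_node:
            core += f"[&r={by_node[node_id]:.4f}]"
        return core

    return _fmt(host_tree) + ";"
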