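"""Dissimilarity matrices and alpha diversity.

Jaccard and unweighted UniFrac are presence/absence metrics (a feature counts
as present when its count is > 0); Bray-Curtis serves the quantitative diet
profiles; patristic distances come from the time-calibrated host tree, so on
an ultrametric tree an entry is twice the divergence time of the pair.

UniFrac and Faith's PD follow the root-inclusive convention of mainstream 16S
tooling: every branch on the path from the root to a present tip contributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from phylosym.containers import FeatureTable

__all__ = [
    "jaccard_matrix",
    "braycurtis_matrix",
    "unweighted_unifrac_matrix",
    "patristic_matrix",
    "alpha_diversity",
    "write_distance_matrix",
]


def _reject_empty_samples(table: FeatureTable) -> None:
    empty = [s for s, tot in table.sample_sums().items() if tot == 0]
    if empty:
        raise ValueError(f"all-zero sample(s): {empty}")


def jaccard_matrix(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity, d = 1 - |A∩B| / |A∪B| on presence sets."""
    if not table.shape[0] or not table.shape[1]:
        raise ValueError("empty feature table")
    _reject_empty_samples(table)
    pres = table.presence().T  # samples x asvs
    d = pdist(pres, metric="jaccard")
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


def braycurtis_matrix(vectors: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between labeled non-negative row vectors."""
    values = np.asarray(vectors, dtype=float)
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = list(np.asarray(vectors.index)[sums <= 0])
        raise ValueError(f"zero-sum vector(s): {bad}")
    d = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=list(vectors.index))


# ---------------------------------------------------------------------------
# tree-based metrics via an edge table
# ---------------------------------------------------------------------------

def _edge_table(tree: TreeNode, asv_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and tip-membership masks for every non-root edge.

    Returns ``(lengths (E,), masks (E, n_asvs) bool)`` where ``masks[e, a]``
    is True iff ASV ``a`` descends from edge ``e``.  The tree is sheared to
    ``asv_ids`` first; ASVs missing from the tree are an error.
    """
    tip_names = {t.name for t in tree.tips()}
    missing = [a for a in asv_ids if a not in tip_names]
    if missing:
        raise ValueError(f"ASV(s) missing from tree: {missing}")
    work = tree.shear(asv_ids)
    work.prune()
    index = {a: i for i, a in enumerate(asv_ids)}
    lengths, masks = [], []
    cache: dict[int, np.ndarray] = {}
    for node in work.postorder(include_self=True):
        if node.is_tip():
            m = np.zeros(len(asv_ids), dtype=bool)
            m[index[node.name]] = True
        else:
            m = np.zeros(len(asv_ids), dtype=bool)
            for child in node.children:
                m |= cache.pop(id(child))
        cache[id(node)] = m
        if node is not work:  # the root carries no edge
            lengths.append(node.length or 0.0)
            masks.append(m)
    return np.asarray(lengths, dtype=float), np.asarray(masks, dtype=bool)


def unweighted_unifrac_matrix(table: FeatureTable, microbial_tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac between samples.

    d(i, j) = (branch length leading only to taxa of one sample) /
    (branch length leading to taxa of either sample), where an edge "leads
    to" a sample iff at least one descendant tip is present in it.
    """
    _reject_empty_samples(table)
    lengths, masks = _edge_table(microbial_tree, table.asv_ids)
    pres = table.presence()  # asvs x samples
    # sample_edges[s, e]: edge e has a descendant present in sample s
    sample_edges = (masks @ pres).T > 0  # (n_samples, E)
    weighted = sample_edges * lengths  # (n_samples, E)
    shared = weighted @ sample_edges.T  # pairwise shared branch length
    totals = weighted.sum(axis=1)
    union = totals[:, None] + totals[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - shared / union
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(d, ids=table.sample_ids)


def patristic_matrix(host_tree: TreeNode, tips=None) -> DistanceMatrix:
    """Path-length (patristic) distances between tips of the tree."""
    dm = host_tree.tip_tip_distances()
    if tips is not None:
        tips = list(tips)
        missing = [t for t in tips if t not in set(dm.ids)]
        if missing:
            raise ValueError(f"tip(s) not in tree: {missing}")
        dm = dm.filter(tips)
    return dm


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: FeatureTable, metric: str, tree: TreeNode | None = None) -> pd.Series:
    """Per-sample alpha diversity.

    Metrics: ``observed`` (# ASVs with count > 0), ``shannon`` (H in nats),
    ``pielou`` (H / ln(observed); NaN for single-ASV samples), ``faith_pd``
    (total branch length of the root-inclusive subtree spanning present tips;
    requires ``tree``).
    """
    counts = table.counts.astype(float)
    observed = (counts > 0).sum(axis=0).astype(float)
    if metric == "observed":
        values = observed
    elif metric in ("shannon", "pielou"):
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("all-zero sample")
        p = counts / totals
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        h = -plogp.sum(axis=0)
        if metric == "shannon":
            values = h
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                values = np.where(observed > 1, h / np.log(observed), np.nan)
    elif metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a microbial tree")
        lengths, masks = _edge_table(tree, table.asv_ids)
        sample_edges = (masks @ table.presence()).T > 0
        values = sample_edges @ lengths
    else:
        raise ValueError(f"unknown alpha-diversity metric: {metric!r}")
    return pd.Series(values, index=table.sample_ids, name=metric)


def write_distance_matrix(dm: DistanceMatrix, path, long_format: bool = False, header_lines=()) -> None:
    """Serialize a distance matrix as labeled square TSV or long (id1, id2, d)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if long_format:
            fh.write("id1\tid2\tdistance\n")
            ids = dm.ids
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    fh.write(f"{ids[i]}\t{ids[j]}\t{dm[i, j]:.10g}\n")
        else:
            fh.write("id\t" + "\t".join(dm.ids) + "\n")
            for i, id_ in enumerate(dm.ids):
                fh.write(id_ + "\t" + "\t".join(f"{v:.10g}" for v in dm.data[i]) + "\n")
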