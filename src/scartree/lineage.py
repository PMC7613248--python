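"""Lineage statistics over reconstructed scar trees.

Quantifies which cell types share clonal origin, integrating several
replicate trees at one time point:

* vertical-branch contraction, so only lineage splits remain;
* per-node cell-type compositions (subtree-inclusive by default: a node's
  cells are everything placed at it or below, since descendants share the
  node's developmental ancestor);
* node-size-weighted Pearson correlation between cell-type ratio vectors,
  with hierarchical clustering of the resulting similarity matrix;
* downsampling stability: repeatedly drop half of the cells (robustness to
  low cell numbers) or half of the nodes (robustness to low clonality and
  clone-specific transition rates) and record how often each type pair
  stays in one cluster;
* conditional co-occurrence probabilities over leaf nodes, the targeted
  statistic that stays informative when transition rates differ between
  clones: P(source | target) = fraction of leaves containing the target
  type that also contain the source type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .tree import LineageTree, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "NodeComposition",
    "StabilityReport",
    "contract_vertical_branches",
    "node_composition",
    "weighted_correlation",
    "cluster_cell_types",
    "downsample_stability",
    "conditional_probability",
]


def contract_vertical_branches(tree: LineageTree) -> LineageTree:
    """Remove nodes that are not part of a lineage split.

    Every node with exactly one child is merged downward into that child,
    pooling its cells; the root is exempt when it carries cells of its own
    (they have nowhere else to live). A pure chain therefore collapses to
    a single node holding all cells.
    """
    out = LineageTree(replicate=tree.replicate, timepoint=tree.timepoint)
    out.nodes = {}

    def build(old_id: int, new_parent: int | None) -> int:
        pooled: list[str] = []
        cur = tree.nodes[old_id]
        while len(cur.children) == 1 and not (
            cur.id == tree.root and cur.cells
        ):
            pooled.extend(cur.cells)
            cur = tree.nodes[cur.children[0]]
        nid = out._next_id if new_parent is not None else 0
        if new_parent is not None:
            out._next_id += 1
        out.nodes[nid] = TreeNode(nid, cur.scar, new_parent, [], pooled + list(cur.cells))
        if new_parent is not None:
            out.nodes[new_parent].children.append(nid)
        for c in cur.children:
            build(c, nid)
        return nid

    out._next_id = 1
    out.root = build(tree.root, None)
    return out


@dataclass
class NodeComposition:
    """Cell-type counts per node, pooled over replicate trees.

    counts: nodes x cell types (integer cell counts); rows are indexed by
    (replicate, node id). node_size is the row sum; is_leaf marks nodes
    without children in their tree.
    """

    counts: pd.DataFrame
    node_size: pd.Series
    is_leaf: pd.Series

    def ratios(self) -> pd.DataFrame:
        return self.counts.div(self.node_size, axis=0)


def _tree_arrays(
    tree: LineageTree, type_of: dict[str, str], types: list[str]
) -> tuple[list[int], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Preorder node ids, parent positions, local count matrix inputs."""
    order = [n.id for n in tree.iter_preorder()]
    pos = {nid: i for i, nid in enumerate(order)}
    parent_pos = np.array(
        [pos[tree.nodes[nid].parent] if tree.nodes[nid].parent is not None else -1
         for nid in order],
        dtype=int,
    )
    tindex = {t: i for i, t in enumerate(types)}
    cell_node, cell_type = [], []
    skipped = 0
    for nid in order:
        for bc in tree.nodes[nid].cells:
            t = type_of.get(bc)
            if t is None:
                skipped += 1
                continue
            cell_node.append(pos[nid])
            cell_type.append(tindex[t])
    if skipped:
        logger.warning("%d placed cells missing from the annotation; excluded", skipped)
    is_leaf = np.array([not tree.nodes[nid].children for nid in order])
    return order, parent_pos, np.array(cell_node, int), np.array(cell_type, int), is_leaf


def _accumulate_subtree(local: np.ndarray, parent_pos: np.ndarray) -> np.ndarray:
    """Add each node's counts into all its ancestors (reverse preorder)."""
    inc = local.copy()
    for i in range(len(parent_pos) - 1, 0, -1):
        if parent_pos[i] >= 0:
            inc[parent_pos[i]] += inc[i]
    return inc


def node_composition(
    trees: list[LineageTree],
    annotation: pd.DataFrame,
    subtree_inclusive: bool = True,
) -> NodeComposition:
    """Per-node cell-type counts, pooled across replicate trees.

    With ``subtree_inclusive`` a node's cells include everything placed in
    its subtree. Nodes with zero annotated cells are dropped.
    """
    type_of = dict(zip(annotation["cell_barcode"], annotation["cell_type"]))
    types = sorted(set(type_of.values()))
    rows, sizes, leaf_flags, index = [], [], [], []
    for tree in trees:
        order, parent_pos, cell_node, cell_type, is_leaf = _tree_arrays(
            tree, type_of, types
        )
        local = np.zeros((len(order), len(types)), dtype=int)
        if len(cell_node):
            np.add.at(local, (cell_node, cell_type), 1)
        mat = _accumulate_subtree(local, parent_pos) if subtree_inclusive else local
        for i, nid in enumerate(order):
            if mat[i].sum() == 0:
                continue
            rows.append(mat[i])
            sizes.append(int(mat[i].sum()))
            leaf_flags.append(bool(is_leaf[i]))
            index.append((tree.replicate, nid))
    idx = pd.MultiIndex.from_tuples(index, names=["replicate", "node"])
    counts = pd.DataFrame(rows, index=idx, columns=types, dtype=int)
    return NodeComposition(
        counts=counts,
        node_size=pd.Series(sizes, index=idx, name="node_size"),
        is_leaf=pd.Series(leaf_flags, index=idx, name="is_leaf"),
    )


def _weighted_corr(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Size-weighted Pearson correlation of cell-type ratios across nodes.

    Entries are NaN for types present (count > 0) in fewer than two nodes
    or with zero weighted variance; the diagonal is 1 where defined.
    """
    sizes = sizes.astype(float)
    ratios = counts / sizes[:, None]
    w = sizes / sizes.sum()
    means = w @ ratios
    centered = ratios - means
    cov = (centered * w[:, None]).T @ centered
    var = np.diag(cov).copy()
    present = (counts > 0).sum(axis=0) >= 2
    valid = present & (var > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan
    di = np.where(valid)[0]
    corr[di, di] = 1.0
    return corr


def weighted_correlation(composition: NodeComposition) -> pd.DataFrame:
    """Lineage-similarity matrix between cell types.

    Correlates cell-type ratio vectors across nodes, weighting each node by
    its size; undefined entries (types in < 2 nodes, zero variance) are NaN.
    """
    if len(composition.counts) < 2:
        raise ValueError("need at least two nodes to correlate cell types")
    corr = _weighted_corr(
        composition.counts.to_numpy(float), composition.node_size.to_numpy(float)
    )
    types = composition.counts.columns
    return pd.DataFrame(corr, index=types, columns=types)


def _cluster_labels(
    corr: np.ndarray,
    n_clusters: int | None,
    distance_threshold: float | None,
    linkage: str,
) -> np.ndarray:
    """fcluster labels over the types whose diagonal is defined; absent
    types (NaN diagonal) get label 0."""
    n = corr.shape[0]
    defined = ~np.isnan(np.diag(corr))
    labels = np.zeros(n, dtype=int)
    k = int(defined.sum())
    if k == 0:
        return labels
    if k == 1:
        labels[defined] = 1
        return labels
    sub = corr[np.ix_(defined, defined)].copy()
    sub[np.isnan(sub)] = 0.0  # missing pairwise entries imputed as 0 correlation
    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = sch.linkage(squareform(dist, checks=False), method=linkage)
    if n_clusters is not None:
        fl = sch.fcluster(z, t=min(n_clusters, k), criterion="maxclust")
    else:
        fl = sch.fcluster(z, t=distance_threshold, criterion="distance")
    labels[defined] = fl
    return labels


def cluster_cell_types(
    correlations: pd.DataFrame,
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
    linkage: str = "average",
) -> pd.Series:
    """Agglomerative clustering of cell types on distance 1 - correlation.

    Cut either at a fixed cluster count or at a distance threshold (give
    exactly one). Types absent from the matrix (NaN diagonal) are excluded;
    remaining missing entries are imputed as zero correlation.
    """
    if (n_clusters is None) == (distance_threshold is None):
        raise ValueError("give exactly one of n_clusters / distance_threshold")
    corr = correlations.to_numpy(float)
    if n_clusters is not None and int((~np.isnan(np.diag(corr))).sum()) < n_clusters:
        raise ValueError("fewer defined cell types than requested clusters")
    if np.isnan(corr).any():
        logger.info("missing correlation entries imputed as 0 for clustering")
    labels = _cluster_labels(corr, n_clusters, distance_threshold, linkage)
    out = pd.Series(labels, index=correlations.index, name="cluster")
    return out[out > 0]


@dataclass
class StabilityReport:
    """Pairwise co-clustering frequencies across downsampling repetitions.

    frequency[a, b] = (repetitions where a and b share a cluster label) /
    (repetitions where both were present); diagonal 1. n_observed counts
    the denominators. reference_labels is the clustering of the full data.
    """

    frequency: pd.DataFrame
    n_observed: pd.DataFrame
    reference_labels: pd.Series
    mode: str
    fraction: float
    reps: int

    def exact_match_rate(self) -> float:
        """Fraction of repetitions whose partition (restricted to present
        types) equals the reference partition on those types."""
        return self._exact_rate

    _exact_rate: float = float("nan")


def downsample_stability(
    trees: list[LineageTree],
    annotation: pd.DataFrame,
    mode: str = "cells",
    fraction: float = 0.5,
    reps: int = 1000,
    seed: int = 0,
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
    linkage: str = "average",
    subtree_inclusive: bool = True,
) -> StabilityReport:
    """Cluster stability under repeated downsampling of cells or nodes.

    Per repetition, a ``fraction`` of the cells (or of the pooled nodes) is
    kept without replacement, correlations and clusters are recomputed, and
    every present type pair is scored as co-clustered or not; pairs with an
    absent member are recorded as missing for that repetition.
    """
    if mode not in ("cells", "nodes"):
        raise ValueError("mode must be 'cells' or 'nodes'")
    rng = np.random.default_rng(seed)
    type_of = dict(zip(annotation["cell_barcode"], annotation["cell_type"]))
    types = sorted(set(type_of.values()))
    T = len(types)

    # Pooled per-tree arrays (local counts; inclusive accumulation per rep).
    arrays = [_tree_arrays(t, type_of, types) for t in trees]

    def composition_arrays(keep_mask_per_tree: list[np.ndarray] | None):
        """Stacked (counts, sizes) over all trees, zero rows dropped."""
        mats = []
        for (order, parent_pos, cell_node, cell_type, _), keep in zip(
            arrays, keep_mask_per_tree or [None] * len(arrays)
        ):
            cn, ct = cell_node, cell_type
            if keep is not None:
                cn, ct = cn[keep], ct[keep]
            local = np.zeros((len(order), T), dtype=int)
            if len(cn):
                np.add.at(local, (cn, ct), 1)
            mats.append(
                _accumulate_subtree(local, parent_pos) if subtree_inclusive else local
            )
        mat = np.vstack(mats)
        sizes = mat.sum(axis=1)
        nz = sizes > 0
        return mat[nz], sizes[nz]

    full_counts, full_sizes = composition_arrays(None)
    ref_corr = _weighted_corr(full_counts, full_sizes)
    ref_labels = _cluster_labels(ref_corr, n_clusters, distance_threshold, linkage)

    n_cells_per_tree = [len(a[2]) for a in arrays]
    n_nodes_full = full_counts.shape[0]

    same = np.zeros((T, T))
    obs = np.zeros((T, T))
    exact = 0
    for _ in range(reps):
        if mode == "cells":
            keeps = []
            for n in n_cells_per_tree:
                k = int(round(n * fraction))
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, size=k, replace=False)] = True
                keeps.append(mask)
            counts, sizes = composition_arrays(keeps)
        else:
            k = max(2, int(round(n_nodes_full * fraction)))
            rows = rng.choice(n_nodes_full, size=k, replace=False)
            counts, sizes = full_counts[rows], full_sizes[rows]
        if counts.shape[0] < 2:
            continue
        corr = _weighted_corr(counts, sizes)
        labels = _cluster_labels(corr, n_clusters, distance_threshold, linkage)
        present = labels > 0
        pp = np.outer(present, present)
        eq = np.equal.outer(labels, labels) & pp
        same += eq
        obs += pp
        # exact partition match on the present types
        if present.any():
            ref_sub = ref_labels[present]
            lab_sub = labels[present]
            ref_pairs = np.equal.outer(ref_sub, ref_sub)
            lab_pairs = np.equal.outer(lab_sub, lab_sub)
            exact += int((ref_pairs == lab_pairs).all())

    with np.errstate(invalid="ignore"):
        freq = np.where(obs > 0, same / np.where(obs > 0, obs, 1), np.nan)
    di = np.arange(T)
    freq[di, di] = np.where(obs[di, di] > 0, 1.0, np.nan)
    report = StabilityReport(
        frequency=pd.DataFrame(freq, index=types, columns=types),
        n_observed=pd.DataFrame(obs.astype(int), index=types, columns=types),
        reference_labels=pd.Series(ref_labels, index=types, name="cluster"),
        mode=mode,
        fraction=fraction,
        reps=reps,
    )
    report._exact_rate = exact / reps if reps else float("nan")
    return report


def conditional_probability(
    trees: list[LineageTree],
    annotation: pd.DataFrame,
    targets: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Leaf-level conditional co-occurrence of cell types.

    P(source | target) = leaves containing both types / leaves containing
    the target, pooled over the replicate trees (contract first so leaves
    are lineage-split end points). Returns (probability table with sources
    as rows, targets as columns; per-target leaf counts). Targets with no
    leaves are NaN with a warning.
    """
    type_of = dict(zip(annotation["cell_barcode"], annotation["cell_type"]))
    all_types = sorted(set(type_of.values()))
    targets = list(targets) if targets is not None else all_types
    leaf_sets: list[set[str]] = []
    for tree in trees:
        for nid in tree.leaves():
            present = {type_of[bc] for bc in tree.nodes[nid].cells if bc in type_of}
            if present:
                leaf_sets.append(present)
    prob = pd.DataFrame(np.nan, index=all_types, columns=targets, dtype=float)
    counts = pd.Series(0, index=targets, dtype=int, name="n_leaves")
    for tgt in targets:
        with_t = [s for s in leaf_sets if tgt in s]
        counts[tgt] = len(with_t)
        if not with_t:
            logger.warning("target type %r absent from all leaves", tgt)
            continue
        for src in all_types:
            prob.loc[src, tgt] = sum(src in s for s in with_t) / len(with_t)
    return prob, counts
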