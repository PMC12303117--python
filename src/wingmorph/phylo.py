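"""Phylogenetic comparative machinery: Newick IO, the Brownian-motion
variance-covariance matrix, ancestral state reconstruction, the
phylomorphospace projection, and multivariate phylogenetic signal
(K_mult, the multivariate generalization of Blomberg's K).

All statistics assume a rooted tree with positive branch lengths and
trait evolution by Brownian motion, under which the expected covariance
of tip values is proportional to C, the matrix of shared root-to-MRCA
path lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from wingmorph.morphospace import ShapeSpace, project

__all__ = [
    "read_newick",
    "write_newick",
    "phylo_vcv",
    "tip_labels",
    "asr_bm",
    "phylomorphospace",
    "kmult",
    "PhyloSignalResult",
]


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree; requires branch lengths and unique tips."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        msg = str(exc)
        if "multiple" in msg.lower() or "already" in msg.lower():
            raise ValueError(f"duplicate tip labels in tree: {msg}") from exc
        raise ValueError(f"invalid newick in {path}: {msg}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has missing branch lengths")
        if edge.length <= 0:
            raise ValueError("tree has non-positive branch lengths")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    """Root-to-node path length for every node."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def phylo_vcv(tree: dendropy.Tree, labels: list[str] | None = None) -> np.ndarray:
    """C[i, j] = shared root-to-MRCA path length of tips i and j.

    Row/column order follows ``labels`` (default: tree leaf order).
    Symmetric positive definite for a tree with positive branch lengths.
    """
    leaves = list(tree.leaf_node_iter())
    order = labels if labels is not None else [lf.taxon.label for lf in leaves]
    by_label = {lf.taxon.label: lf for lf in leaves}
    missing = set(order) - set(by_label)
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    depths = _node_depths(tree)

    # ancestor sets per tip for MRCA lookup
    anc: dict[str, list] = {}
    for lab in order:
        node = by_label[lab]
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[lab] = chain
    n = len(order)
    C = np.empty((n, n))
    for i, la in enumerate(order):
        seta = set(id(x) for x in anc[la])
        C[i, i] = depths[by_label[la]]
        for j in range(i + 1, n):
            lb = order[j]
            mrca = next(x for x in anc[lb] if id(x) in seta)
            C[i, j] = C[j, i] = depths[mrca]
    return C


def _align_traits(tree: dendropy.Tree, traits: pd.DataFrame):
    """Match trait rows to tree tips; error on tips without traits."""
    labels = tip_labels(tree)
    missing = [t for t in labels if t not in traits.index]
    if missing:
        raise ValueError(f"tips without trait rows: {missing[:5]}")
    Y = traits.loc[labels].to_numpy(dtype=float)
    if np.any(np.isnan(Y)):
        raise ValueError("missing trait values")
    return labels, Y


def _phylo_mean(C_inv: np.ndarray, Y: np.ndarray) -> np.ndarray:
    one = np.ones(C_inv.shape[0])
    w = C_inv @ one
    return (w @ Y) / (one @ w)


def asr_bm(tree: dendropy.Tree, traits: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood (GLS) Brownian-motion ancestral states.

    ``traits``: rows indexed by tip label, one column per trait.  Every
    tree tip must have a trait row.  Returns a DataFrame of internal-node
    estimates (index = internal node ids, root first); the root equals
    the phylogenetic mean (1'C^-1 1)^-1 1'C^-1 Y, and each internal node
    k is the GLS/BLUP estimate a_hat + c_k' C^-1 (Y - 1 a_hat) with c_k
    the vector of node-tip shared path lengths.
    """
    labels, Y = _align_traits(tree, traits)
    C = phylo_vcv(tree, labels)
    C_inv = np.linalg.inv(C)
    a_hat = _phylo_mean(C_inv, Y)
    resid = Y - a_hat

    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    depths = _node_depths(tree)
    # ancestor id set per internal node for shared-path computation
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    est = np.empty((len(internal), Y.shape[1]))
    names = []
    for k, node in enumerate(internal):
        chain = set()
        x = node
        while x is not None:
            chain.add(id(x))
            x = x.parent_node
        c_k = np.empty(len(labels))
        for i, lab in enumerate(labels):
            tip = leaves[lab]
            x = tip
            while id(x) not in chain:
                x = x.parent_node
            c_k[i] = depths[x]
        est[k] = a_hat + c_k @ C_inv @ resid
        names.append(node.label or f"node{k}")
    return pd.DataFrame(est, index=names, columns=traits.columns)


def phylomorphospace(
    tree: dendropy.Tree, traits: pd.DataFrame, space: ShapeSpace,
    extra_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tips, BM-reconstructed ancestors, and unplaced taxa in (PC1, PC2).

    ``traits`` are normalized coefficient vectors per tip; internal-node
    coefficients are reconstructed under BM and projected through the
    shape space.  ``extra_scores`` (taxon -> PC scores) adds taxa absent
    from the tree as unconnected points.  Returns a table with columns
    node_id, type (tip/internal/unplaced), pc1, pc2, parent_id.
    """
    labels, Y = _align_traits(tree, traits)
    anc = asr_bm(tree, traits)
    rows = []
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    ids = {}
    for k, node in enumerate(internal):
        ids[id(node)] = f"internal_{k}"
    for leaf in tree.leaf_node_iter():
        ids[id(leaf)] = leaf.taxon.label

    anc_scores = project(anc.to_numpy(), space)
    tip_scores = project(Y, space)
    for k, node in enumerate(internal):
        parent = ids[id(node.parent_node)] if node.parent_node else ""
        rows.append(("internal_" + str(k), "internal",
                     anc_scores[k, 0], anc_scores[k, 1], parent))
    for i, lab in enumerate(labels):
        node = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == lab)
        parent = ids[id(node.parent_node)]
        rows.append((lab, "tip", tip_scores[i, 0], tip_scores[i, 1], parent))
    if extra_scores is not None:
        for lab, row in extra_scores.iterrows():
            rows.append((lab, "unplaced", row.iloc[0], row.iloc[1], ""))
    return pd.DataFrame(rows, columns=["node_id", "type", "pc1", "pc2", "parent_id"])


@dataclass(frozen=True)
class PhyloSignalResult:
    K: float
    p_value: float
    n_iterations: int


def kmult(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    n_iterations: int = 9999,
    seed: int = 0,
) -> PhyloSignalResult:
    """Multivariate Blomberg's K with a permutation test.

    K = [tr(E'E) / tr(E'C^-1 E)] / [(tr(C) - N / (1'C^-1 1)) / (N - 1)]
    with E = Y - 1 a_hat.  K = 1 is the Brownian-motion expectation; the
    p-value permutes trait rows across tips, p = (#{K_perm >= K_obs} + 1)
    / (n_iterations + 1).
    """
    labels, Y = _align_traits(tree, traits)
    N = len(labels)
    if N < 4:
        raise ValueError("need >= 4 tips")
    C = phylo_vcv(tree, labels)
    C_inv = np.linalg.inv(C)
    one = np.ones(N)
    denom_expect = (np.trace(C) - N / (one @ C_inv @ one)) / (N - 1)

    def _k(Ym: np.ndarray) -> float:
        a = _phylo_mean(C_inv, Ym)
        E = Ym - a
        num = float(np.sum(E * E))
        den = float(np.sum(E * (C_inv @ E)))
        if den == 0.0:
            raise ValueError("zero trait variance")
        return (num / den) / denom_expect

    K_obs = _k(Y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_iterations):
        perm = rng.permutation(N)
        if _k(Y[perm]) >= K_obs:
            count += 1
    p = (count + 1) / (n_iterations + 1)
    return PhyloSignalResult(K=float(K_obs), p_value=float(p), n_iterations=n_iterations)
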