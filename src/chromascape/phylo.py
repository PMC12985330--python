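"""Phylogenetic relatedness of communities: MCC tree and PSV.

Uncertainty in the species-level phylogeny is represented by a sample of
trees over a common tip set.  The maximum clade credibility (MCC) tree is
the member of that sample whose rooted clades are jointly most frequent
across the sample (selection only, no consensus construction).  Phylogenetic species variability (PSV) of a community is
computed from the tree-implied correlation matrix

    C_ij = depth(MRCA(i, j)) / sqrt(depth(i) * depth(j)),

as PSV = (n * tr(C) - sum(C)) / (n * (n - 1)) over the community
submatrix.  On an ultrametric tree PSV lies in [0, 1]; lower values mean a
community of more closely related species.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DegenerateTreeError,
    EmptyInputError,
    InvalidInputError,
    MissingSpeciesError,
    UndefinedStatisticError,
)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def rooted_clades(tree: dendropy.Tree) -> list[frozenset]:
    """Tip-label sets of all internal nodes (clades with >= 2 tips)."""
    clades = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._clade = frozenset([node.taxon.label])
        else:
            labels = frozenset().union(*(c._clade for c in node.child_nodes()))
            node._clade = labels
            clades.append(labels)
    return clades


def max_clade_credibility(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Select the tree whose rooted clades are jointly most frequent.

    score(tree) = product over its internal clades of the clade's
    frequency in the sample (equivalently the sum of log frequencies);
    scores are compared in exact integer arithmetic, and ties break to the
    first index.  The result is always a member of the input list.
    """
    if not trees:
        raise EmptyInputError("no trees supplied")
    tipsets = [frozenset(tip_labels(t)) for t in trees]
    if any(ts != tipsets[0] for ts in tipsets[1:]):
        raise InvalidInputError("trees do not share an identical tip set")
    per_tree_clades = [rooted_clades(t) for t in trees]
    counts: Counter = Counter()
    for clades in per_tree_clades:
        counts.update(clades)
    # score = prod(clade frequency) = prod(counts)/n^k; compare exactly in
    # integer arithmetic (cross-multiplication) so distinct topologies with
    # mathematically tied scores break deterministically to the first index
    n = len(trees)
    best_idx = 0
    best_num, best_k = _clade_score(per_tree_clades[0], counts)
    for i, clades in enumerate(per_tree_clades[1:], start=1):
        num, k = _clade_score(clades, counts)
        if num * n**best_k > best_num * n**k:
            best_idx, best_num, best_k = i, num, k
    return trees[best_idx]


def _clade_score(clades, counts: Counter) -> tuple[int, int]:
    """Numerator and exponent of the exact clade-credibility product."""
    num = 1
    for c in clades:
        num *= counts[c]
    return num, len(clades)


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            edge = node.edge.length if node.edge.length is not None else 0.0
            if edge < 0:
                raise InvalidInputError("negative branch length")
            depths[node] = depths[node.parent_node] + edge
    return depths


def phylo_correlation(tree: dendropy.Tree) -> pd.DataFrame:
    """Species x species phylogenetic correlation matrix.

    C_ij = shared root-to-MRCA depth over the geometric mean of the two
    root-to-tip depths; diagonal fixed at 1.  For an ultrametric tree this
    is the standard correlation structure of a Brownian trait.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise InvalidInputError("tree needs at least 2 tips")
    depths = _node_depths(tree)
    labels = [leaf.taxon.label for leaf in leaves]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("duplicate tip labels")
    tip_depth = np.array([depths[leaf] for leaf in leaves])
    if (tip_depth <= 0).any():
        raise DegenerateTreeError("zero root-to-tip depth")
    index = {leaf: i for i, leaf in enumerate(leaves)}
    mrca_depth = np.zeros((len(leaves), len(leaves)))
    # at each internal node, tip pairs drawn from two different children
    # have that node as their MRCA
    tips_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = [index[node]]
            continue
        groups = [tips_below[c] for c in node.child_nodes()]
        d = depths[node]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        mrca_depth[i, j] = mrca_depth[j, i] = d
        tips_below[node] = [i for g in groups for i in g]
    denom = np.sqrt(np.outer(tip_depth, tip_depth))
    corr = mrca_depth / denom
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=labels, columns=labels)


def psv(
    community: Iterable[str],
    correlation: pd.DataFrame,
    prune_missing: bool = False,
) -> float:
    """Phylogenetic species variability of one community.

    PSV = (n tr(C) - sum(C)) / (n (n - 1)) over the community submatrix of
    ``correlation``.  Species absent from the matrix raise an error unless
    ``prune_missing`` drops them (with a warning) instead.
    """
    species = sorted(set(community))
    missing = [s for s in species if s not in correlation.index]
    if missing:
        if not prune_missing:
            raise MissingSpeciesError(
                f"species absent from correlation matrix: {missing}"
            )
        import logging

        logging.getLogger(__name__).warning(
            "pruning %d species absent from the tree", len(missing)
        )
        species = [s for s in species if s not in missing]
    n = len(species)
    if n < 2:
        raise UndefinedStatisticError("PSV requires at least 2 species")
    sub = correlation.loc[species, species].to_numpy()
    return float((n * np.trace(sub) - sub.sum()) / (n * (n - 1)))


def psv_table(
    community: pd.DataFrame,
    tree: dendropy.Tree,
    prune_missing: bool = False,
) -> pd.Series:
    """Per-site PSV for a binary site x species presence/absence matrix."""
    corr = phylo_correlation(tree)
    values = {}
    for site_id, row in community.iterrows():
        present = row.index[row.astype(int) == 1]
        values[site_id] = psv(present, corr, prune_missing=prune_missing)
    out = pd.Series(values, name="psv")
    out.index.name = "site_id"
    return out


def read_trees(path) -> list[dendropy.Tree]:
    """Read a Newick tree list sharing one taxon namespace."""
    return list(
        dendropy.TreeList.get(path=str(path), schema="newick", rooting="default-rooted")
    )


def write_trees(trees: list[dendropy.Tree], path) -> None:
    dendropy.TreeList(trees).write(path=str(path), schema="newick")
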