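"""Phylogenetic trees and Brownian-motion covariance structures.

A rooted tree with branch lengths induces the expected covariance of a trait
evolving by Brownian motion: var(species i) is the root-to-tip path length and
cov(i, j) is the length of the path shared from the root down to the most
recent common ancestor.  Pagel's lambda rescales the off-diagonal (shared)
part of that matrix, interpolating between a star phylogeny (lambda = 0) and
pure Brownian motion (lambda = 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["PhyloTree", "PhyloCovariance", "parse_newick", "vcv_matrix", "lambda_transform"]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be turned into a usable tree."""


@dataclass
class PhyloTree:
    """A rooted phylogeny with branch lengths, backed by a dendropy tree.

    Tip labels must be unique and every edge must carry a nonnegative length
    (the root edge may be absent, in which case it is treated as 0).
    Polytomies and non-ultrametric trees are accepted as-is.
    """

    tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                if edge.length is None:
                    edge.length = 0.0
                continue
            if edge.length is None:
                raise NewickParseError(
                    f"missing branch length on edge above {_node_name(edge.head_node)}"
                )
            if edge.length < 0:
                raise NewickParseError(
                    f"negative branch length ({edge.length}) above {_node_name(edge.head_node)}"
                )
        self.tip_labels = labels
        zero_tips = [
            leaf.taxon.label
            for leaf in self.tree.leaf_node_iter()
            if (leaf.edge.length or 0.0) == 0.0
        ]
        if zero_tips:
            logger.warning(
                "zero-length terminal branches (tips exchangeable under BM): %s", zero_tips
            )

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def prune_to(self, keep: list[str]) -> "PhyloTree":
        """Return a copy pruned to the given tip labels (order ignored).

        Tips not found in the tree are reported via a logged warning so data /
        tree mismatches are never silent.
        """
        keep_set = set(keep)
        missing = sorted(keep_set - set(self.tip_labels))
        if missing:
            logger.warning("%d species in table but not in tree: %s", len(missing), missing)
        retain = [l for l in self.tip_labels if l in keep_set]
        if len(retain) < 1:
            raise ValueError("no overlap between requested labels and tree tips")
        dropped = len(self.tip_labels) - len(retain)
        if dropped:
            logger.warning("pruning %d tips absent from the trait table", dropped)
        def _tip_depth(tr, label):
            for leaf in tr.leaf_node_iter():
                if leaf.taxon.label == label:
                    d, node = 0.0, leaf
                    while node is not None:
                        d += node.edge.length or 0.0
                        node = node.parent_node
                    return d
            raise KeyError(label)

        ref = retain[0]
        orig_depth = _tip_depth(self.tree, ref)
        clone = self.tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep_set]
        clone.retain_taxa(taxa)
        # collapsing chains above the new root removes ancestry shared by all
        # retained tips; restore it on the root edge so root-to-tip path
        # lengths (hence the Brownian covariance) match the original tree
        new_depth = _tip_depth(clone, ref)
        missing = orig_depth - new_depth
        if missing > 1e-12:
            clone.seed_node.edge.length = (clone.seed_node.edge.length or 0.0) + missing
        return PhyloTree(clone)

    def to_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def _node_name(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return "<internal node>"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths mandatory below the root)."""
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if not any(True for _ in tree.leaf_node_iter()):
        raise NewickParseError("tree has no tips")
    tree.is_rooted = True
    return PhyloTree(tree)


def read_newick(path: str) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance matrix aligned to an explicit species order."""

    matrix: np.ndarray
    species_order: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.species_order)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match species order")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.species_order)

    def reorder(self, species: list[str]) -> "PhyloCovariance":
        idx = [self.species_order.index(s) for s in species]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(species))

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.species_order, columns=self.species_order).to_csv(
            path, sep="\t"
        )


def vcv_matrix(tree: PhyloTree) -> PhyloCovariance:
    """Expected Brownian covariance: shared root-to-MRCA path lengths.

    Computed in one preorder pass by accumulating each node's depth; the
    covariance of two tips is the depth of their MRCA, the variance of a tip
    its own depth.
    """
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    depth: dict[int, float] = {}
    tips_below: dict[int, list[int]] = {}
    seed = tree.tree.seed_node
    for node in tree.tree.preorder_node_iter():
        parent_depth = 0.0 if node is seed else depth[id(node.parent_node)]
        # the root's own edge (if any) is shared by every tip
        depth[id(node)] = parent_depth + (node.edge.length or 0.0)
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[id(node)] = [index[node.taxon.label]]
            i = index[node.taxon.label]
            V[i, i] = depth[id(node)]
        else:
            children = [tips_below[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            # every cross-child tip pair has this node as its MRCA
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = d
            tips_below[id(node)] = [i for ch in children for i in ch]
    return PhyloCovariance(V, list(labels))


def lambda_transform(V: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda rescaling: multiply off-diagonal entries by ``lam``.

    lam = 1 leaves the Brownian structure untouched; lam = 0 removes all
    phylogenetic covariance, leaving independent species with their original
    variances.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    M = V.matrix
    out = lam * M + (1.0 - lam) * np.diag(np.diag(M))
    return PhyloCovariance(out, list(V.species_order))
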