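"""Phylogenetic correlation structure from a Newick topology.

The species-level random effect of the meta-analytic model needs an
expected correlation matrix A under shared ancestry.  When divergence
times are unknown (a topology pulled from a reference taxonomy has no
meaningful branch lengths), Grafen's method assigns each internal node a
height proportional to the number of tips it subtends, producing an
ultrametric tree on which A[i, j] is simply the depth of the most recent
common ancestor of tips i and j, with total tree depth normalised to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "PhyloCorrelation",
    "parse_newick",
    "grafen_lengths",
    "phylo_correlation",
]

_ULTRAMETRIC_TOL = 1e-9


@dataclass
class Phylogeny:
    """A rooted tree; branch lengths meaningful only after Grafen assignment."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def is_ultrametric(self, tol: float = _ULTRAMETRIC_TOL) -> bool:
        depths = _tip_depths(self.tree)
        return bool(depths and max(depths) - min(depths) <= tol)

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


class PhyloCorrelation:
    """Species-by-species correlation matrix A, label-indexed.

    Unit diagonal, symmetric, entries in [0, 1], positive semi-definite by
    construction (it is a covariance of shared root-to-MRCA path lengths).
    """

    def __init__(self, species: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(species), len(species)):
            raise ValueError("matrix shape does not match species list")
        if len(set(species)) != len(species):
            raise ValueError("duplicate species labels")
        self.species = list(species)
        self.values = values
        self._index = {s: i for i, s in enumerate(self.species)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values[self._index[i], self._index[j]])

    def submatrix(self, species: list[str]) -> np.ndarray:
        """A restricted to (and ordered by) the given species labels."""
        missing = [s for s in species if s not in self._index]
        if missing:
            raise KeyError(
                "species absent from phylogenetic correlation matrix: "
                + ", ".join(sorted(missing))
            )
        idx = [self._index[s] for s in species]
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def identity(cls, species: list[str]) -> "PhyloCorrelation":
        return cls(list(species), np.eye(len(species)))


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a rooted tree; branch lengths are ignored."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid Newick: {exc}") from None
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise ValueError("invalid Newick: unlabeled tip")
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 tips")
    if len(set(labels)) != len(labels):
        raise ValueError("invalid Newick: duplicate tip labels")
    return Phylogeny(tree)


def grafen_lengths(phylogeny: Phylogeny, rho: float = 1.0) -> Phylogeny:
    """Assign Grafen branch lengths in place and return the phylogeny.

    Node height = ((k - 1) / (n - 1)) ** rho where k is the number of tips
    the node subtends and n the total tip count; tips sit at height 0 and
    the root at height 1, so the tree is exactly ultrametric.  Polytomies
    need no special handling.  rho > 1 stretches old nodes upward, rho < 1
    compresses them; the default rho = 1 is Grafen's.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    tree = phylogeny.tree
    n = phylogeny.n_tips
    heights: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = 1
            heights[id(node)] = 0.0
        else:
            k = sum(1 for _ in node.leaf_iter())
            heights[id(node)] = ((k - 1) / (n - 1)) ** rho
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[id(node.parent_node)] - heights[id(node)]
    return phylogeny


def phylo_correlation(phylogeny: Phylogeny) -> PhyloCorrelation:
    """Correlation matrix A from an ultrametric tree of depth 1.

    A[i, j] = shared root-to-MRCA depth of tips i and j = 1 - height(MRCA);
    A[i, i] = 1.  Requires Grafen (or otherwise depth-1 ultrametric)
    branch lengths.
    """
    tree = phylogeny.tree
    depths = _tip_depths(tree)
    if not depths:
        raise ValueError("empty tree")
    total = max(depths)
    if total <= 0 or (max(depths) - min(depths)) > _ULTRAMETRIC_TOL * max(1.0, total):
        raise ValueError(
            "tree is not ultrametric; run grafen_lengths before phylo_correlation"
        )

    labels = phylogeny.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    m = len(labels)
    A = np.eye(m)

    # Depth of each node measured from the root, normalised by tree depth.
    node_depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_depth[id(node)] = 0.0
        else:
            node_depth[id(node)] = (
                node_depth[id(node.parent_node)] + (node.edge.length or 0.0)
            )

    # Tip pairs drawn from distinct children of a node have that node as MRCA.
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        depth = node_depth[id(node)] / total
        child_tip_sets = [
            [index[leaf.taxon.label] for leaf in child.leaf_iter()]
            for child in node.child_nodes()
        ]
        for a in range(len(child_tip_sets)):
            for b in range(a + 1, len(child_tip_sets)):
                for i in child_tip_sets[a]:
                    for j in child_tip_sets[b]:
                        A[i, j] = A[j, i] = depth
    return PhyloCorrelation(labels, A)


def _tip_depths(tree: dendropy.Tree) -> list[float]:
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return depths
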