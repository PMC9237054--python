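"""Phylogeny utilities shared by the generator, diversity and imputation code.

Trees live in dendropy containers at the boundary (newick I/O, simulation);
internally most computation runs on a :class:`TreeIndex`, a flat array view
of the edges: for every non-root edge we hold its length and the boolean
incidence of tips descending through it. Faith's PD, patristic distances and
total tree length are then simple masked sums, and assemblage-level PD over
many random draws vectorizes to one matrix product.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .exceptions import ConfigurationError, InputError


@dataclass
class TreeIndex:
    """Array view of a rooted tree with branch lengths.

    Attributes
    ----------
    labels : list of tip labels, sorted
    lengths : (E,) branch length of each non-root edge
    masks : (E, S) bool; masks[e, i] is True if tip i descends through edge e
    """

    labels: List[str]
    lengths: np.ndarray
    masks: np.ndarray

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeIndex":
        labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        if len(set(labels)) != len(labels):
            raise InputError("duplicate tip labels")
        idx = {lab: i for i, lab in enumerate(labels)}
        lengths = []
        masks = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            mask = np.zeros(len(labels), dtype=bool)
            for leaf in node.leaf_iter():
                mask[idx[leaf.taxon.label]] = True
            masks.append(mask)
            lengths.append(float(node.edge.length or 0.0))
        return cls(labels=labels, lengths=np.asarray(lengths, dtype=float),
                   masks=np.asarray(masks, dtype=bool))

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def tip_indices(self, subset: Iterable[str]) -> np.ndarray:
        idx = {lab: i for i, lab in enumerate(self.labels)}
        out = []
        for lab in subset:
            if lab not in idx:
                raise InputError(f"unknown species label {lab!r}")
            out.append(idx[lab])
        return np.asarray(out, dtype=int)

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path length for every tip."""
        return self.lengths @ self.masks

    def patristic_matrix(self) -> np.ndarray:
        """Pairwise tip-to-tip path lengths, ordered like ``labels``."""
        M = self.masks.astype(float)
        depths = self.lengths @ M
        shared = M.T @ (M * self.lengths[:, None])  # shared root-path length
        D = depths[:, None] + depths[None, :] - 2.0 * shared
        np.fill_diagonal(D, 0.0)
        return D


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    depths = TreeIndex.from_dendropy(tree).tip_depths()
    return bool(np.ptp(depths) <= tol)


def yule_tree(n_species: int, seed: int, height: float = 100.0) -> dendropy.Tree:
    """Pure-birth tree with ``n_species`` extant tips, rescaled to a fixed
    root height (the absolute scale stands in for millions of years)."""
    if n_species < 2:
        raise ConfigurationError("a phylogeny needs at least 2 species")
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0,
        num_extant_tips=n_species, rng=random.Random(int(seed)),
    )
    # deterministic species labels in traversal order
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"s{i:04d}"
    depth = tree.max_distance_from_root()
    if depth <= 0:
        raise ConfigurationError("degenerate simulated tree (zero height)")
    f = height / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * f
    return tree


def _internal_edges(tree: dendropy.Tree):
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        out.append(node)
    return out


def nni_perturb(tree: dendropy.Tree, n_moves: int, rng: random.Random) -> dendropy.Tree:
    """Copy of ``tree`` after ``n_moves`` random nearest-neighbour-interchange
    moves. Branch lengths are carried along unchanged, so perturbed trees are
    generally no longer ultrametric; only their topology is consumed (MCC)."""
    new = tree.clone(depth=1)
    for _ in range(max(0, int(n_moves))):
        candidates = [n for n in _internal_edges(new)
                      if n.parent_node is not None and len(n.child_nodes()) >= 2
                      and len(n.parent_node.child_nodes()) >= 2]
        if not candidates:
            break
        child = rng.choice(candidates)
        parent = child.parent_node
        siblings = [c for c in parent.child_nodes() if c is not child]
        if not siblings:
            continue
        sib = rng.choice(siblings)
        grandkids = child.child_nodes()
        gk = rng.choice(grandkids)
        # exchange one grandchild with the sibling subtree
        parent.remove_child(sib)
        child.remove_child(gk)
        parent.add_child(gk)
        child.add_child(sib)
    return new


def tip_label_set(tree: dendropy.Tree) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def clade_sets(tree: dendropy.Tree) -> List[frozenset]:
    """Tip-label sets of all internal clades (root included, leaves excluded)."""
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        out.append(frozenset(leaf.taxon.label for leaf in node.leaf_iter()))
    return out


def read_newick_list(path) -> List[dendropy.Tree]:
    tl = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(tl)


def write_newick_list(trees: Sequence[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick").strip() + "\n")
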