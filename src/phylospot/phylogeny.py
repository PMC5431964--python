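"""Rooted phylogenies: Newick I/O, age smoothing, Faith's PD, clade ranges.

Trees are held as :class:`dendropy.Tree` objects behind a thin wrapper that
fixes the conventions the diversity metrics rely on:

* rooted trees; polytomies are kept as-is (supertrees are polytomy-rich);
* branch lengths ≥ 0 in time units; zero-length branches contribute nothing
  to PD/PE but are retained for topology;
* Faith's PD uses the *rooted* convention by default — the spanning paths
  connect the taxa to the root, so the stem above the taxa's MRCA is
  included and the PD of a single taxon is its root-path length.  This is
  what makes the branch-wise accounting of phylogenetic endemism exact
  (every branch contributes its full length once across cells).  The
  unrooted variant (paths spanning only the taxa) is available via
  ``rooted=False``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .occurrences import DataError, OccurrenceMatrix


class TreeError(ValueError):
    """Malformed tree or inconsistent age constraints."""


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labeled leaves."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise TreeError("every leaf must be labeled")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError("negative branch length")

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | io.TextIOBase, is_path: bool = True) -> "Phylogeny":
        kwargs = dict(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        try:
            if is_path:
                tree = dendropy.Tree.get(path=str(source), **kwargs)
            else:
                tree = dendropy.Tree.get(data=source, **kwargs)
        except Exception as exc:  # dendropy raises schema-specific errors
            raise TreeError(f"cannot parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick_string(cls, newick: str) -> "Phylogeny":
        return cls.from_newick(newick, is_path=False)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        ).strip() + "\n"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    # -- basic structure ---------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label if lf.taxon else lf.label
                for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def total_branch_length(self) -> float:
        return float(sum(e.length or 0.0 for e in self.tree.preorder_edge_iter()))

    def leaf_depths(self) -> dict[str, float]:
        depths = {}
        for lf in self.tree.leaf_node_iter():
            depths[lf.taxon.label if lf.taxon else lf.label] = lf.distance_from_root()
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = list(self.leaf_depths().values())
        return (max(d) - min(d)) <= tol

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Prune to the given leaves; unifurcations created by pruning are
        collapsed, summing the two adjacent branch lengths."""
        keep = set(labels)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise TreeError(f"unknown leaves: {sorted(missing)[:5]}")
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels(list(keep))
        return Phylogeny(tree)

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))


# ---------------------------------------------------------------------------
# branch/cell presence sweep (shared by PD, PE and clade ranges)
# ---------------------------------------------------------------------------

def _edge_arrays(phylo: Phylogeny, matrix: OccurrenceMatrix):
    """One post-order sweep over the tree.

    Returns (nodes, lengths, counts) where for edge i (the edge above
    ``nodes[i]``): ``lengths[i]`` is its branch length and ``counts[i]`` is
    the per-cell number of descendant leaves present (shape n_edges ×
    n_cells, so ``counts > 0`` is the presence mask).  The root's edge is
    included with length 0 unless the Newick carried a root edge length.
    """
    species_idx = {s: i for i, s in enumerate(matrix.species)}
    n_cells = len(matrix.cells)
    nodes = list(phylo.tree.postorder_node_iter())
    lengths = np.array([n.edge.length or 0.0 for n in nodes], dtype=float)
    counts = np.zeros((len(nodes), n_cells), dtype=np.int32)
    pos = {id(n): i for i, n in enumerate(nodes)}
    for i, node in enumerate(nodes):
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            j = species_idx.get(label)
            if j is not None:
                counts[i] = matrix.incidence[j]
        else:
            for child in node.child_nodes():
                counts[i] += counts[pos[id(child)]]
    return nodes, lengths, counts


@dataclass
class CladeRangeIndex:
    """Per-branch clade range R_c: number of cells occupied by ≥ 1
    descendant leaf; overlapping cells are counted once (set union)."""

    lengths: np.ndarray          # branch lengths, present branches only
    ranges: np.ndarray           # R_c per branch
    presence: np.ndarray         # bool, n_branches × n_cells
    leaf_branch: dict = field(default_factory=dict)  # leaf label -> row index

    def range_for_leaf(self, label: str) -> int:
        return int(self.ranges[self.leaf_branch[label]])


def clade_ranges(phylo: Phylogeny, matrix: OccurrenceMatrix) -> CladeRangeIndex:
    """Compute R_c for every branch with at least one present descendant.

    Branches whose descendants are all absent from the matrix are excluded.
    """
    nodes, lengths, counts = _edge_arrays(phylo, matrix)
    presence = counts > 0
    ranges = presence.sum(axis=1)
    keep = ranges > 0
    leaf_branch = {}
    kept_pos = np.cumsum(keep) - 1
    for i, node in enumerate(nodes):
        if node.is_leaf() and keep[i]:
            label = node.taxon.label if node.taxon else node.label
            leaf_branch[label] = int(kept_pos[i])
    return CladeRangeIndex(
        lengths=lengths[keep],
        ranges=ranges[keep].astype(int),
        presence=presence[keep],
        leaf_branch=leaf_branch,
    )


# ---------------------------------------------------------------------------
# Faith's PD
# ---------------------------------------------------------------------------

def faith_pd(phylo: Phylogeny, taxa: Iterable[str], rooted: bool = True) -> float:
    """Sum of branch lengths on the minimum spanning paths of `taxa`.

    rooted=True (default): paths connect the taxa to the root, so stem
    branches above the taxa's MRCA are included.  rooted=False: only
    branches strictly inside the subtree spanning the taxa count, so a
    single taxon has PD 0.
    """
    taxa = list(taxa)
    if not taxa:
        raise DataError("faith_pd: empty taxa set")
    taxa_set = set(taxa)
    leaf_set = set(phylo.leaf_labels)
    unknown = taxa_set - leaf_set
    if unknown:
        raise DataError(f"faith_pd: unknown taxa {sorted(unknown)[:5]}")
    k = len(taxa_set)
    total = 0.0
    counts: dict[int, int] = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            c = 1 if label in taxa_set else 0
        else:
            c = sum(counts[id(ch)] for ch in node.child_nodes())
        counts[id(node)] = c
        length = node.edge.length or 0.0
        if rooted:
            if c > 0:
                total += length
        else:
            if 0 < c < k:
                total += length
    return total


# ---------------------------------------------------------------------------
# BLADJ-style branch smoothing
# ---------------------------------------------------------------------------

def bladj_smooth(phylo: Phylogeny, ages: Mapping[str, float]) -> Phylogeny:
    """Assign node ages from constraints and even interpolation.

    `ages` maps node labels (internal node labels; the root must be
    constrained) to ages in time units before present.  Leaves are fixed at
    age 0.  Unconstrained internal nodes along each path between consecutive
    constrained nodes are spaced at equal age steps; branch lengths are then
    recomputed as parent_age − child_age.  Interpolation runs in
    deterministic pre-order; when an unconstrained node lies on several
    constrained-to-constrained paths, its first (pre-order) assignment wins
    and becomes the anchor for deeper nodes.
    """
    out = phylo.clone()
    tree = out.tree
    age: dict[int, float] = {}
    fixed: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            a = float(ages.get(label, 0.0)) if label in ages else 0.0
            age[id(node)] = a
            fixed[id(node)] = a
        elif node.label is not None and node.label in ages:
            age[id(node)] = float(ages[node.label])
            fixed[id(node)] = float(ages[node.label])
    root = tree.seed_node
    if id(root) not in fixed:
        raise TreeError("bladj_smooth: the root age must be constrained")
    # constraint consistency: each fixed node vs nearest fixed ancestor
    def check(node, ancestor_age):
        a = fixed.get(id(node))
        if a is not None and node is not root:
            if a > ancestor_age + 1e-12:
                raise TreeError(
                    f"age constraint {a} older than nearest fixed ancestor ({ancestor_age})"
                )
            ancestor_age = a
        for child in node.child_nodes():
            check(child, ancestor_age)
    check(root, fixed[id(root)])

    def walk(node, anchor_age, chain):
        """Descend from a known-age anchor; `chain` collects unassigned nodes."""
        if id(node) in age:
            a = age[id(node)]
            k = len(chain)
            for i, u in enumerate(chain, start=1):
                age[id(u)] = anchor_age - i * (anchor_age - a) / (k + 1)
            for child in node.child_nodes():
                walk(child, a, [])
        else:
            for child in node.child_nodes():
                if id(node) in age:  # assigned while visiting an earlier child
                    walk(child, age[id(node)], [])
                else:
                    walk(child, anchor_age, chain + [node])

    for child in root.child_nodes():
        walk(child, age[id(root)], [])

    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = None
            continue
        length = age[id(node.parent_node)] - age[id(node)]
        if length < -1e-9:
            raise TreeError(
                "inconsistent age constraints produce a negative branch length"
            )
        node.edge.length = max(length, 0.0)
    return Phylogeny(tree)
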