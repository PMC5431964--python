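"""Independent brute-force oracle for the per-cell diversity metrics.

Everything here materializes root paths and set unions explicitly, one cell
and one branch at a time, with no shared code with the package's vectorized
post-order sweep.  Intentionally slow and obvious.
"""

import math

import numpy as np


def root_path_edges(tree, leaf_label):
    """List of nodes whose (parent) edge lies on the root path of a leaf."""
    for leaf in tree.tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        if label == leaf_label:
            path = []
            node = leaf
            while node is not None:
                path.append(node)
                node = node.parent_node
            return path
    raise KeyError(leaf_label)


def brute_pd(tree, taxa, rooted=True):
    """Faith's PD by explicit union of root paths."""
    edges = set()
    for t in taxa:
        for node in root_path_edges(tree, t):
            edges.add(id(node))
    if not rooted:
        # drop edges ancestral to every taxon (shared suffix of all paths)
        shared = None
        for t in taxa:
            ids = {id(n) for n in root_path_edges(tree, t)}
            shared = ids if shared is None else shared & ids
        if len(taxa) == 1:
            return 0.0
        edges -= shared
    total = 0.0
    for node in tree.tree.preorder_node_iter():
        if id(node) in edges:
            total += node.edge.length or 0.0
    return total


def brute_cell_metrics(tree, matrix, pdrel_s1="undefined"):
    """Per-cell SR, WE, CWE, PD, PD_rel, PE computed one cell at a time.

    Returns dict cell_id -> dict of metric values (NaN where undefined).
    """
    species = list(matrix.species)
    cells = list(matrix.cells)
    occupied = {
        s: {cells[k] for k in np.nonzero(matrix.incidence[i])[0]}
        for i, s in enumerate(species)
    }
    range_size = {s: len(v) for s, v in occupied.items()}

    # per-branch clade range: union of occupied cells over descendant leaves
    branch_cells = {}
    for node in tree.tree.postorder_node_iter():
        cellset = set()
        for leaf in node.leaf_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label in occupied:
                cellset |= occupied[label]
        branch_cells[id(node)] = cellset

    out = {}
    for j, cid in enumerate(cells):
        taxa = [s for i, s in enumerate(species) if matrix.incidence[i, j]]
        sr = len(taxa)
        if sr == 0:
            out[cid] = dict(SR=0, WE=math.nan, CWE_pct=math.nan, PD=math.nan,
                            PD_rel=math.nan, PE=0.0)
            continue
        we = sum(1.0 / range_size[s] for s in taxa)
        cwe = we / sr * 100.0
        # union of root-path edges of the cell's taxa
        edge_ids = set()
        for t in taxa:
            for node in root_path_edges(tree, t):
                edge_ids.add(id(node))
        pd_val = 0.0
        pe_val = 0.0
        for node in tree.tree.preorder_node_iter():
            if id(node) in edge_ids:
                length = node.edge.length or 0.0
                pd_val += length
                r_c = len(branch_cells[id(node)])
                if r_c:
                    pe_val += length / r_c
        if sr >= 2:
            pdrel = pd_val / math.log10(sr)
        elif pdrel_s1 == "zero":
            pdrel = 0.0
        else:
            pdrel = math.nan
        out[cid] = dict(SR=sr, WE=we, CWE_pct=cwe, PD=pd_val, PD_rel=pdrel,
                        PE=pe_val)
    return out
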