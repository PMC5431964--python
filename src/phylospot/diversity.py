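"""Per-cell diversity metrics: SR, WE/CWE, PD, PD_rel and PE.

For a grid cell with species set S (|S| = SR):

* WE  = Σ_{j∈S} 1/R_j, with R_j the species' range size in cells; summed
  over all cells each species contributes exactly 1, so Σ_cells WE equals
  the number of species (a conservation identity used as a self-check).
* CWE = WE / SR × 100, in percent — the mean range-restriction of the
  cell's species; 100% means every species is a single-cell endemic.
* PD  = Faith's phylogenetic diversity, the branch-length sum over the
  union of root paths of the cell's species (rooted convention, see
  :mod:`phylospot.phylogeny`).
* PD_rel = PD / log10(SR), which removes the first-order dependence of PD
  on richness; undefined at SR = 1 (log10 1 = 0).
* PE  = Σ_{c∈paths} L_c / R_c, branch length divided by the branch's clade
  range: endemism weighted by evolutionary heritage.  Each branch
  contributes L_c in total across cells, so Σ_cells PE = PD of the full
  species pool (second conservation identity).

Cells with no species carry an ``empty`` flag (PE = 0 is exact; the other
metrics are reported as NaN); SR = 1 cells carry ``pdrel_undefined`` unless
``pdrel_s1="zero"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .occurrences import DataError, OccurrenceMatrix
from .phylogeny import CladeRangeIndex, Phylogeny, _edge_arrays, clade_ranges

DIVERSITY_COLUMNS = ["cell_id", "SR", "WE", "CWE_pct", "PD", "PD_rel", "PE", "flags"]


def species_richness(matrix: OccurrenceMatrix) -> pd.Series:
    """SR: species count per cell (0 for empty cells)."""
    return matrix.richness


def corrected_weighted_endemism(matrix: OccurrenceMatrix) -> pd.DataFrame:
    """WE and CWE (percent) per cell; CWE is NaN for empty cells."""
    R = matrix.range_sizes.to_numpy(dtype=float)
    if (R < 1).any():
        raise DataError("every species must occupy at least one cell")
    weights = 1.0 / R
    we = weights @ matrix.incidence
    sr = matrix.incidence.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cwe = np.where(sr > 0, we / np.where(sr > 0, sr, 1) * 100.0, np.nan)
    return pd.DataFrame({"WE": we, "CWE_pct": cwe}, index=matrix.cells)


def relative_phylogenetic_diversity(
    tree: Phylogeny,
    matrix: OccurrenceMatrix,
    pdrel_s1: str = "undefined",
    rooted: bool = True,
) -> pd.DataFrame:
    """Per-cell Faith's PD and PD_rel = PD / log10(SR).

    ``pdrel_s1`` controls single-species cells: "undefined" (NaN, excluded
    from PD_rel hotspot ranking) or "zero".
    """
    _, lengths, counts = _edge_arrays(tree, matrix)
    sr = matrix.incidence.sum(axis=0)
    if rooted:
        pd_cell = lengths @ (counts > 0)
    else:
        on_path = (counts > 0) & (counts < sr[np.newaxis, :])
        pd_cell = lengths @ on_path
    pdrel = _pd_rel(pd_cell, sr, pdrel_s1)
    return pd.DataFrame({"PD": pd_cell, "PD_rel": pdrel}, index=matrix.cells)


def _pd_rel(pd_cell: np.ndarray, sr: np.ndarray, pdrel_s1: str) -> np.ndarray:
    if pdrel_s1 not in ("undefined", "zero"):
        raise DataError("pdrel_s1 must be 'undefined' or 'zero'")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_s = np.log10(np.where(sr > 0, sr, 1))
        pdrel = np.where(sr >= 2, pd_cell / np.where(log_s > 0, log_s, 1), np.nan)
    if pdrel_s1 == "zero":
        pdrel = np.where(sr == 1, 0.0, pdrel)
    return pdrel


def phylogenetic_endemism(
    tree: Phylogeny,
    matrix: OccurrenceMatrix,
    ranges: CladeRangeIndex | None = None,
) -> pd.Series:
    """PE per cell: Σ L_c / R_c over branches on the cell's spanning paths.

    Empty cells have PE = 0 exactly (no branch lies on their paths).
    """
    if ranges is None:
        ranges = clade_ranges(tree, matrix)
    weights = ranges.lengths / ranges.ranges
    pe = weights @ ranges.presence
    return pd.Series(pe, index=matrix.cells, name="PE")


def compute_diversity(
    tree: Phylogeny,
    matrix: OccurrenceMatrix,
    pdrel_s1: str = "undefined",
    rooted: bool = True,
) -> pd.DataFrame:
    """All per-cell metrics in one table (the order of species and cells in
    the inputs does not affect the values)."""
    sr = species_richness(matrix)
    endemism = corrected_weighted_endemism(matrix)
    phylo = relative_phylogenetic_diversity(tree, matrix, pdrel_s1=pdrel_s1, rooted=rooted)
    pe = phylogenetic_endemism(tree, matrix)

    flags = []
    for s in sr.to_numpy():
        f = []
        if s == 0:
            f.append("empty")
        elif s == 1 and pdrel_s1 == "undefined":
            f.append("pdrel_undefined")
        flags.append(";".join(f))

    table = pd.DataFrame(
        {
            "cell_id": matrix.cells,
            "SR": sr.to_numpy(),
            "WE": endemism["WE"].to_numpy(),
            "CWE_pct": endemism["CWE_pct"].to_numpy(),
            "PD": phylo["PD"].to_numpy(),
            "PD_rel": phylo["PD_rel"].to_numpy(),
            "PE": pe.to_numpy(),
            "flags": flags,
        }
    )
    empty = table["SR"] == 0
    table.loc[empty, ["WE", "CWE_pct", "PD", "PD_rel"]] = np.nan
    return table
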