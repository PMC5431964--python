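"""Occurrence matrices and grid-cell tables.

The analysis universe is a set of grid cells (with land and nature-reserve
areas in km²) and a binary species × cell incidence matrix.  Species range
size ``R_j`` is the number of occupied cells and is the quantity that weights
endemism metrics, so it is always recomputed on the *current* analysis grid
after any cell filtering.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_COLUMNS = ["cell_id", "row", "col", "land_area_km2", "reserve_area_km2"]

_WS_RUN = re.compile(r"\s+")


def normalize_species_id(name: str) -> str:
    """Trim and collapse internal whitespace; no synonym resolution."""
    return _WS_RUN.sub(" ", str(name).strip())


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class CellTable:
    """Grid-cell attribute table.

    Parameters
    ----------
    data : DataFrame
        Must contain ``cell_id`` and ``land_area_km2``; ``reserve_area_km2``
        defaults to 0 and ``row``/``col`` are optional integer grid
        coordinates (required only for region labeling).
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if "cell_id" not in df.columns or "land_area_km2" not in df.columns:
            raise DataError("cell table needs 'cell_id' and 'land_area_km2' columns")
        df["cell_id"] = df["cell_id"].astype(str)
        if df["cell_id"].duplicated().any():
            dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
            raise DataError(f"duplicate cell ids: {dupes[:5]}")
        if "reserve_area_km2" not in df.columns:
            df["reserve_area_km2"] = 0.0
        df["land_area_km2"] = df["land_area_km2"].astype(float)
        df["reserve_area_km2"] = df["reserve_area_km2"].astype(float)
        if (df["land_area_km2"] < 0).any() or (df["reserve_area_km2"] < 0).any():
            raise DataError("areas must be non-negative")
        # digitization slivers: clamp reserve_area to land_area with a warning
        over = df["reserve_area_km2"] > df["land_area_km2"]
        if over.any():
            logger.warning(
                "clamped reserve_area > land_area in %d cells", int(over.sum())
            )
            df.loc[over, "reserve_area_km2"] = df.loc[over, "land_area_km2"]
        self.data = df.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def cell_ids(self) -> pd.Index:
        return pd.Index(self.data["cell_id"])

    @property
    def has_coordinates(self) -> bool:
        return {"row", "col"}.issubset(self.data.columns)

    @property
    def total_land_area(self) -> float:
        return float(self.data["land_area_km2"].sum())

    @property
    def total_reserve_area(self) -> float:
        return float(self.data["reserve_area_km2"].sum())

    def coverage(self) -> pd.Series:
        """Per-cell reserve coverage fraction (0 where land area is 0)."""
        land = self.data["land_area_km2"].to_numpy()
        res = self.data["reserve_area_km2"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(land > 0, res / np.where(land > 0, land, 1.0), 0.0)
        return pd.Series(frac, index=self.cell_ids, name="coverage")

    def subset(self, cell_ids: Iterable[str]) -> "CellTable":
        keep = set(map(str, cell_ids))
        return CellTable(self.data[self.data["cell_id"].isin(keep)])

    def __len__(self) -> int:
        return len(self.data)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "CellTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        cols = [c for c in CELL_COLUMNS if c in self.data.columns]
        self.data[cols].to_csv(path, index=False)


class OccurrenceMatrix:
    """Binary species × cell incidence matrix.

    Stored dense boolean; rows are species (sorted ids), columns are cells in
    the order of the associated :class:`CellTable`.
    """

    def __init__(self, species: Sequence[str], cells: Sequence[str], incidence: np.ndarray):
        self.species = pd.Index(species, name="species_id")
        self.cells = pd.Index(cells, name="cell_id")
        inc = np.asarray(incidence, dtype=bool)
        if inc.shape != (len(self.species), len(self.cells)):
            raise DataError("incidence shape does not match species/cell ids")
        if self.species.duplicated().any():
            raise DataError("duplicate species ids")
        if self.cells.duplicated().any():
            raise DataError("duplicate cell ids")
        self.incidence = inc

    # -- derived quantities ------------------------------------------------
    @property
    def range_sizes(self) -> pd.Series:
        """R_j: number of occupied cells per species, on the current grid."""
        return pd.Series(self.incidence.sum(axis=1), index=self.species, name="R_j")

    @property
    def richness(self) -> pd.Series:
        """SR: number of species per cell."""
        return pd.Series(self.incidence.sum(axis=0), index=self.cells, name="SR")

    @property
    def n_incidences(self) -> int:
        return int(self.incidence.sum())

    def species_in_cells(self, cell_ids: Iterable[str]) -> pd.Index:
        idx = self.cells.get_indexer(pd.Index(map(str, cell_ids)))
        idx = idx[idx >= 0]
        mask = self.incidence[:, idx].any(axis=1)
        return self.species[mask]

    # -- restriction -------------------------------------------------------
    def restrict_cells(self, cell_ids: Sequence[str], drop_empty_species: bool = True):
        """Keep only the given cells; optionally drop species left with R_j = 0.

        Returns (matrix, n_species_dropped).
        """
        keep = pd.Index(map(str, cell_ids))
        idx = self.cells.get_indexer(keep)
        if (idx < 0).any():
            raise DataError("restrict_cells: unknown cell ids")
        inc = self.incidence[:, idx]
        dropped = 0
        species = self.species
        if drop_empty_species:
            alive = inc.any(axis=1)
            dropped = int((~alive).sum())
            inc = inc[alive]
            species = species[alive]
        return OccurrenceMatrix(species, keep, inc), dropped

    def restrict_species(self, species_ids: Sequence[str]) -> "OccurrenceMatrix":
        keep = pd.Index(species_ids)
        idx = self.species.get_indexer(keep)
        if (idx < 0).any():
            raise DataError("restrict_species: unknown species ids")
        return OccurrenceMatrix(keep, self.cells, self.incidence[idx])

    # -- construction / I/O ------------------------------------------------
    @classmethod
    def from_records(cls, records: pd.DataFrame, cells: CellTable) -> "OccurrenceMatrix":
        """Build from a long table with species_id, cell_id columns.

        Duplicated (species, cell) pairs collapse to one incidence; records
        for cells absent from `cells` are dropped with a logged count.
        """
        if not {"species_id", "cell_id"}.issubset(records.columns):
            raise DataError("occurrence records need 'species_id' and 'cell_id' columns")
        if len(records) == 0:
            raise DataError("empty occurrence table")
        rec = records.copy()
        rec["species_id"] = rec["species_id"].map(normalize_species_id)
        rec["cell_id"] = rec["cell_id"].astype(str)
        known = set(cells.cell_ids)
        unknown = ~rec["cell_id"].isin(known)
        if unknown.any():
            logger.warning(
                "dropped %d occurrence records referencing unknown cells",
                int(unknown.sum()),
            )
            rec = rec[~unknown]
        if len(rec) == 0:
            raise DataError("no occurrence records match the cell table")
        rec = rec.drop_duplicates(subset=["species_id", "cell_id"])
        species = pd.Index(sorted(rec["species_id"].unique()))
        cell_index = cells.cell_ids
        inc = np.zeros((len(species), len(cell_index)), dtype=bool)
        si = species.get_indexer(rec["species_id"])
        ci = cell_index.get_indexer(rec["cell_id"])
        inc[si, ci] = True
        return cls(species, cell_index, inc)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (species_id, cell_id) table of incidences."""
        si, ci = np.nonzero(self.incidence)
        return pd.DataFrame(
            {"species_id": self.species[si], "cell_id": self.cells[ci]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_occurrences(path, cells: CellTable) -> OccurrenceMatrix:
    """Read a long-format species_id,cell_id CSV restricted to `cells`."""
    try:
        records = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty occurrence file: {path}") from exc
    return OccurrenceMatrix.from_records(records, cells)


def filter_cells(
    cells: CellTable,
    matrix: OccurrenceMatrix,
    min_land_area: float = 1250.0,
) -> tuple[CellTable, OccurrenceMatrix]:
    """Drop cells with land area strictly below `min_land_area` km².

    Incomplete coastal/border cells bias per-cell diversity, so cells under
    half the nominal 2,500 km² cell area are excluded by default.  Range
    sizes are recomputed on the filtered grid and species left with no
    occupied cell are removed (logged).
    """
    if min_land_area < 0:
        raise DataError("min_land_area must be >= 0")
    keep = cells.data.loc[cells.data["land_area_km2"] >= min_land_area, "cell_id"]
    if len(keep) == 0:
        raise DataError("cell filtering removed every cell")
    n_removed = len(cells) - len(keep)
    if n_removed:
        logger.info("excluded %d cells with land area < %g km²", n_removed, min_land_area)
    filtered_cells = cells.subset(keep)
    filtered_matrix, n_dropped = matrix.restrict_cells(list(keep))
    if n_dropped:
        logger.warning(
            "dropped %d species occurring only in excluded cells", n_dropped
        )
    return filtered_cells, filtered_matrix


def align_taxa(matrix: OccurrenceMatrix, tree) -> tuple[OccurrenceMatrix, "object"]:
    """Restrict matrix and tree to their common species set.

    Returns the restricted matrix and pruned tree (see
    :meth:`phylospot.phylogeny.Phylogeny.prune_to`); drop counts on both
    sides are logged.
    """
    tree_taxa = set(tree.leaf_labels)
    matrix_taxa = set(matrix.species)
    common = sorted(tree_taxa & matrix_taxa)
    if not common:
        raise DataError("no species shared between occurrence matrix and tree")
    n_matrix_only = len(matrix_taxa - tree_taxa)
    n_tree_only = len(tree_taxa - matrix_taxa)
    if n_matrix_only:
        logger.warning("dropped %d matrix species absent from the tree", n_matrix_only)
    if n_tree_only:
        logger.warning("pruned %d tree leaves absent from the matrix", n_tree_only)
    new_matrix = matrix.restrict_species(common) if n_matrix_only else matrix
    new_tree = tree.prune_to(common) if n_tree_only else tree
    return new_matrix, new_tree
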