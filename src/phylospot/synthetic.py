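"""Synthetic grids, phylogenies, occurrences and reserve coverage.

The generator emulates the statistical structure a country-scale woody-plant
atlas analysis assumes, so every downstream stage can be exercised without
proprietary data:

* a rectangular grid of 50 × 50 km cells (2,500 km² nominal land area) where
  a configurable fraction of border cells is truncated, exercising the
  small-cell exclusion rule;
* a Yule (pure-birth) ultrametric phylogeny;
* species ranges drawn from a lognormal (heavy right tail: most species are
  narrow-ranged, a few are very widespread) and grown as spatially cohesive
  patches by seeded breadth-first accretion on rook adjacency, mimicking
  county-rasterized distribution maps;
* range placement biased by a monotone richness gradient along the row axis
  (the latitudinal richness gradient) with the narrowest-quantile species
  seeded at configurable endemism centers, so known hotspots can be planted
  and recovered;
* per-cell reserve coverage from a zero-inflated Beta distribution.

All randomness flows from explicit seeds; identical (config, seed) gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .occurrences import CellTable, DataError, OccurrenceMatrix
from .phylogeny import Phylogeny


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults are a desk-scale rendition of a national 50-km atlas analysis:
    a 40 × 40 grid, 400 species with lognormal range sizes whose median is
    ~12 cells (most species narrow-ranged), ten endemism centers, a strong
    row-axis richness gradient and zero-inflated Beta reserve coverage with
    mean coverage ≈ 10% overall.
    """

    n_rows: int = 40
    n_cols: int = 40
    cell_area: float = 2500.0            # km², 50 km × 50 km
    n_species: int = 400
    range_size_log_mean: float = 2.5     # lognormal median ≈ 12 cells
    range_size_log_sd: float = 1.5
    n_endemism_centers: int = 10
    endemism_center_cells: Sequence[str] | None = None
    n_planted_endemics: int = 0          # species forced to range size 1 at centers
    narrow_quantile: float = 0.25        # narrowest species start at centers
    richness_gradient_strength: float = 2.0
    richness_block_cells: Sequence[str] | None = None
    richness_block_bias: float = 0.8     # P(wide-ranged species starts in block)
    border_incomplete_prob: float = 0.3  # border cells with truncated land area
    reserve_coverage_beta_a: float = 0.8
    reserve_coverage_beta_b: float = 4.0
    reserve_zero_prob: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigError("grid dimensions must be positive")
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        for name in ("narrow_quantile", "richness_block_bias",
                     "border_incomplete_prob", "reserve_zero_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.cell_area <= 0:
            raise ConfigError("cell_area must be positive")
        if self.richness_gradient_strength < 0:
            raise ConfigError("richness_gradient_strength must be >= 0")


def cell_id(row: int, col: int) -> str:
    return f"c{row:03d}_{col:03d}"


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def generate_grid(config: SyntheticConfig) -> CellTable:
    """Grid-cell table with land and reserve areas (seeded by config.seed).

    Interior cells get the full nominal land area; border cells are
    truncated below it with probability ``border_incomplete_prob`` (uniform
    fraction of the nominal area, so some fall under the exclusion
    threshold).  Reserve area is a zero-inflated Beta coverage fraction of
    the land area.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.n_rows, config.n_cols
    rows, cols = np.divmod(np.arange(nr * nc), nc)
    land = np.full(nr * nc, config.cell_area)
    border = (rows == 0) | (rows == nr - 1) | (cols == 0) | (cols == nc - 1)
    truncate = border & (rng.random(nr * nc) < config.border_incomplete_prob)
    land[truncate] = rng.uniform(0.0, 1.0, truncate.sum()) * config.cell_area
    coverage = rng.beta(
        config.reserve_coverage_beta_a, config.reserve_coverage_beta_b, nr * nc
    )
    coverage[rng.random(nr * nc) < config.reserve_zero_prob] = 0.0
    return CellTable(pd.DataFrame({
        "cell_id": [cell_id(r, c) for r, c in zip(rows, cols)],
        "row": rows,
        "col": cols,
        "land_area_km2": land,
        "reserve_area_km2": coverage * land,
    }))


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def generate_phylogeny(n_species: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Ultrametric bifurcating tree under a Yule (pure-birth) process.

    Lineages split at exponential waiting times (rate = k·birth_rate with k
    extant lineages); after the n-th lineage appears, one more waiting time
    is appended so every terminal branch has positive length.  Leaves are
    labeled sp_0001… in left-to-right order.
    """
    if n_species < 1:
        raise ConfigError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node

    if n_species == 1:
        leaf = root.new_child(edge_length=float(rng.exponential(1.0 / birth_rate)))
        leaf.taxon = tns.new_taxon(label="sp_0001")
        return Phylogeny(tree)

    t = 0.0
    etime: dict[int, float] = {}
    active = [root]
    born = {id(root): 0.0}
    while len(active) < n_species:
        k = len(active)
        t += float(rng.exponential(1.0 / (k * birth_rate)))
        i = int(rng.integers(k))
        node = active.pop(i)
        etime[id(node)] = t
        for _ in range(2):
            child = node.new_child()
            born[id(child)] = t
            active.append(child)
    t_end = t + float(rng.exponential(1.0 / (n_species * birth_rate)))
    for leaf in active:
        etime[id(leaf)] = t_end

    for node in tree.preorder_node_iter():
        if node is not root:
            node.edge.length = etime[id(node)] - etime[id(node.parent_node)]
    width = max(4, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(label=f"sp_{i:0{width}d}")
    return Phylogeny(tree)


def generate_taxonomy(
    tree: Phylogeny,
    genus_age_frac: float = 0.3,
    family_age_frac: float = 0.6,
) -> pd.DataFrame:
    """Phylogenetically consistent taxonomy: genera and families are the
    clades subtended by branches crossing fixed fractions of the root age."""
    depths = tree.leaf_depths()
    height = max(depths.values())

    def clades_at(age: float) -> dict[str, int]:
        assign, next_id = {}, 0
        for node in tree.tree.preorder_node_iter():
            d_parent = node.parent_node.distance_from_root() if node.parent_node else 0.0
            d_node = node.distance_from_root()
            # branch crosses the age line (measured as depth from root)
            if d_parent <= height - age < d_node or (node.is_leaf() and d_node <= height - age):
                next_id += 1
                for lf in node.leaf_iter():
                    assign[lf.taxon.label if lf.taxon else lf.label] = next_id
        return assign

    genera = clades_at(genus_age_frac * height)
    families = clades_at(family_age_frac * height)
    rows = [
        {
            "species_id": sp,
            "genus": f"gen_{genera.get(sp, 0):04d}",
            "family": f"fam_{families.get(sp, 0):04d}",
        }
        for sp in sorted(tree.leaf_labels)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def _grow_range(start: int, size: int, neighbors: list[list[int]], rng) -> list[int]:
    """Spatially cohesive range by breadth-first accretion from `start`:
    repeatedly annex a uniformly chosen frontier cell."""
    occupied = {start}
    frontier = [n for n in neighbors[start] if n != start]
    in_frontier = set(frontier)
    while len(occupied) < size and frontier:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        cell = frontier.pop()
        in_frontier.discard(cell)
        occupied.add(cell)
        for n in neighbors[cell]:
            if n not in occupied and n not in in_frontier:
                frontier.append(n)
                in_frontier.add(n)
    return sorted(occupied)


def generate_occurrences(
    grid: CellTable,
    tree: Phylogeny,
    config: SyntheticConfig,
) -> OccurrenceMatrix:
    """Occurrence matrix with lognormal range sizes and cohesive ranges.

    Start cells: the first ``n_planted_endemics`` species are single-cell
    endemics at the endemism centers (cycled); the remaining
    narrowest-quantile species start at a random center; all others start
    at cells weighted by the row-axis richness gradient (or inside the
    planted richness block with probability ``richness_block_bias``).
    Seeded by ``config.seed + 2``.
    """
    if len(grid) == 0:
        raise DataError("empty grid")
    rng = np.random.default_rng(config.seed + 2)
    species = sorted(tree.leaf_labels)
    n_species = len(species)
    n_cells = len(grid)
    cell_index = grid.cell_ids
    rows = grid.data["row"].astype(int).to_numpy()
    cols = grid.data["col"].astype(int).to_numpy()

    pos = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    neighbors: list[list[int]] = []
    for r, c in zip(rows, cols):
        nb = [pos[rc] for rc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
              if rc in pos]
        neighbors.append(nb)

    sizes = np.rint(rng.lognormal(
        config.range_size_log_mean, config.range_size_log_sd, n_species
    )).astype(int)
    sizes = np.clip(sizes, 1, n_cells)

    n_planted = min(config.n_planted_endemics, n_species)
    sizes[:n_planted] = 1

    if config.endemism_center_cells is not None:
        centers = [int(cell_index.get_loc(c)) for c in config.endemism_center_cells]
    elif config.n_endemism_centers > 0:
        centers = sorted(rng.choice(
            n_cells, size=min(config.n_endemism_centers, n_cells), replace=False
        ).tolist())
    else:
        centers = []

    free_sizes = sizes[n_planted:]
    narrow_cut = (np.quantile(free_sizes, config.narrow_quantile)
                  if len(free_sizes) else 0)

    max_row = max(int(rows.max()), 1)
    grad = np.exp(config.richness_gradient_strength * rows / max_row)
    grad = grad / grad.sum()
    block = ([int(cell_index.get_loc(c)) for c in config.richness_block_cells]
             if config.richness_block_cells else [])

    incidence = np.zeros((n_species, n_cells), dtype=bool)
    for j in range(n_species):
        size = int(sizes[j])
        if j < n_planted and centers:
            start = centers[j % len(centers)]
        elif centers and j >= n_planted and sizes[j] <= narrow_cut:
            start = centers[int(rng.integers(len(centers)))]
        elif block and rng.random() < config.richness_block_bias:
            start = block[int(rng.integers(len(block)))]
        else:
            start = int(rng.choice(n_cells, p=grad))
        incidence[j, _grow_range(start, size, neighbors, rng)] = True
    return OccurrenceMatrix(species, cell_index, incidence)


# ---------------------------------------------------------------------------
# convenience bundle + mock reserves
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    cells: CellTable
    tree: Phylogeny
    matrix: OccurrenceMatrix
    taxonomy: pd.DataFrame = field(default=None, repr=False)

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cells": out / "cells.csv",
            "tree": out / "tree.nwk",
            "occurrences": out / "occurrences.csv",
            "taxonomy": out / "taxonomy.csv",
        }
        self.cells.to_csv(paths["cells"])
        self.tree.write_newick(paths["tree"])
        self.matrix.to_csv(paths["occurrences"])
        if self.taxonomy is not None:
            self.taxonomy.to_csv(paths["taxonomy"], index=False)
        return paths


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Grid, tree, occurrences and taxonomy from one config.

    Sub-generators use seeds config.seed (grid), config.seed + 1 (tree) and
    config.seed + 2 (occurrences) so each component is independently
    reproducible.
    """
    cells = generate_grid(config)
    tree = generate_phylogeny(config.n_species, config.seed + 1)
    matrix = generate_occurrences(cells, tree, config)
    taxonomy = generate_taxonomy(tree)
    return SyntheticDataset(config=config, cells=cells, tree=tree,
                            matrix=matrix, taxonomy=taxonomy)


def rasterize_rect_reserves(
    cells: CellTable,
    rects: Sequence[tuple[int, int, int, int, float]],
) -> CellTable:
    """Overwrite reserve areas from axis-aligned mock reserves.

    Each rect is (row0, col0, row1, col1, coverage) — inclusive bounds —
    assigning ``coverage × land_area`` as reserve area to covered cells
    (maximum coverage wins on overlap); other cells get 0.
    """
    if not cells.has_coordinates:
        raise DataError("rasterize_rect_reserves needs row/col coordinates")
    df = cells.data.copy()
    cov = np.zeros(len(df))
    r, c = df["row"].astype(int).to_numpy(), df["col"].astype(int).to_numpy()
    for r0, c0, r1, c1, frac in rects:
        inside = (r >= r0) & (r <= r1) & (c >= c0) & (c <= c1)
        cov = np.where(inside, np.maximum(cov, frac), cov)
    df["reserve_area_km2"] = cov * df["land_area_km2"].to_numpy()
    return CellTable(df)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    for key in ("endemism_center_cells", "richness_block_cells"):
        if d[key] is not None:
            d[key] = list(d[key])
    return d
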