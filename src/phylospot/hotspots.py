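"""Hotspot identification, multi-metric overlap accounting and regions.

A hotspot for a metric is a grid cell whose value falls in the configured
top fraction.  Two threshold readings are supported:

* ``mode="cells"`` (default): the top ``ceil(p · n_eligible)`` cells ranked
  by value, extended to every cell tied with the cutoff value — selection is
  deterministic and order-invariant;
* ``mode="range"``: cells whose value lies in the top ``p`` fraction of the
  metric's value range, i.e. value ≥ max − p·(max − min).

Cells whose metric is undefined (NaN flag, e.g. PD_rel at SR = 1) are not
eligible.  Overlap accounting mirrors the usual multi-metric bookkeeping:
union size and land area, per-n-metric intersections, species coverage per
metric, metric-distinct species, pairwise spatial overlap (reported both as
Jaccard and as intersection over the smaller set, since the literature's
"overlap percentage" denominator varies) and pairwise species-composition
similarity (Sørensen by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .occurrences import CellTable, DataError, OccurrenceMatrix

DEFAULT_METRICS = ["SR", "CWE_pct", "PD_rel", "PE"]


@dataclass(frozen=True)
class HotspotSet:
    """Cells selected as hotspots for one metric at one threshold."""

    metric: str
    p: float
    cells: frozenset[str]
    n_eligible: int
    cutoff: float
    mode: str = "cells"

    def __len__(self) -> int:
        return len(self.cells)


def select_hotspots(
    table: pd.DataFrame,
    metric: str,
    p: float,
    mode: str = "cells",
) -> HotspotSet:
    """Select the top-``p`` hotspot cells for one metric.

    ``table`` is a diversity table with a ``cell_id`` column (see
    :func:`phylospot.diversity.compute_diversity`).
    """
    if not 0 < p < 1:
        raise DataError("threshold fraction p must be in (0, 1)")
    if metric not in table.columns:
        raise DataError(f"metric {metric!r} not in diversity table")
    values = pd.Series(
        table[metric].to_numpy(dtype=float), index=table["cell_id"].astype(str)
    )
    eligible = values.dropna()
    if eligible.empty:
        raise DataError(f"no cells with a defined value for {metric!r}")
    if mode == "cells":
        k = math.ceil(p * len(eligible))
        # k-th largest value is the cutoff; ties at the cutoff all included
        cutoff = float(np.sort(eligible.to_numpy())[::-1][k - 1])
    elif mode == "range":
        vmax, vmin = float(eligible.max()), float(eligible.min())
        cutoff = vmax - p * (vmax - vmin)
    else:
        raise DataError("mode must be 'cells' or 'range'")
    selected = frozenset(eligible.index[eligible >= cutoff])
    return HotspotSet(
        metric=metric, p=p, cells=selected, n_eligible=len(eligible),
        cutoff=cutoff, mode=mode,
    )


def multi_metric_counts(sets: list[HotspotSet]) -> pd.Series:
    """Per-cell count of metrics that selected it (union cells only)."""
    counts: dict[str, int] = {}
    for hs in sets:
        for cid in hs.cells:
            counts[cid] = counts.get(cid, 0) + 1
    return pd.Series(counts, name="n_metrics").sort_index()


def hotspot_table(sets: list[HotspotSet]) -> pd.DataFrame:
    """Long-format table (cell_id, metric, p, n_metrics) of selections."""
    n = multi_metric_counts(sets)
    rows = []
    for hs in sets:
        for cid in sorted(hs.cells):
            rows.append((cid, hs.metric, hs.p, int(n[cid])))
    return pd.DataFrame(rows, columns=["cell_id", "metric", "p", "n_metrics"])


def overlap_summary(
    sets: list[HotspotSet],
    cells: CellTable,
    matrix: OccurrenceMatrix,
    species_similarity: str = "sorensen",
) -> dict:
    """Multi-metric overlap accounting over a common cell universe."""
    if len(sets) < 2:
        raise DataError("overlap_summary needs at least two hotspot sets")
    universe = set(cells.cell_ids)
    for hs in sets:
        if not hs.cells <= universe:
            raise DataError(f"hotspot set {hs.metric!r} has cells outside the cell table")

    area = cells.data.set_index("cell_id")["land_area_km2"]
    total_area = cells.total_land_area
    n_species = len(matrix.species)

    union = set().union(*(hs.cells for hs in sets))
    n_counts = multi_metric_counts(sets)
    union_area = float(area.loc[sorted(union)].sum())

    per_n = {}
    for n in range(1, len(sets) + 1):
        cids = sorted(n_counts.index[n_counts == n])
        per_n[n] = {
            "cells": len(cids),
            "fraction_of_union": len(cids) / len(union) if union else 0.0,
            "land_area_km2": float(area.loc[cids].sum()),
        }

    species_sets = {hs.metric: set(matrix.species_in_cells(hs.cells)) for hs in sets}
    union_species = set(matrix.species_in_cells(union))
    per_metric = {}
    for hs in sets:
        sp = species_sets[hs.metric]
        others = set().union(*(v for k, v in species_sets.items() if k != hs.metric))
        per_metric[hs.metric] = {
            "cells": len(hs.cells),
            "land_area_km2": float(area.loc[sorted(hs.cells)].sum()),
            "species": len(sp),
            "species_fraction": len(sp) / n_species if n_species else 0.0,
            "distinct_species": len(sp - others),
        }

    pairwise = {}
    for a, b in itertools.combinations(sets, 2):
        inter = a.cells & b.cells
        un = a.cells | b.cells
        spa, spb = species_sets[a.metric], species_sets[b.metric]
        sp_inter = len(spa & spb)
        if species_similarity == "sorensen":
            sp_sim = 2 * sp_inter / (len(spa) + len(spb)) if (spa or spb) else 0.0
        elif species_similarity == "jaccard":
            sp_sim = sp_inter / len(spa | spb) if (spa | spb) else 0.0
        else:
            raise DataError("species_similarity must be 'sorensen' or 'jaccard'")
        pairwise[f"{a.metric}|{b.metric}"] = {
            "jaccard_pct": 100.0 * len(inter) / len(un) if un else 0.0,
            "over_min_pct": 100.0 * len(inter) / min(len(a.cells), len(b.cells))
            if a.cells and b.cells else 0.0,
            "species_similarity_pct": 100.0 * sp_sim,
        }

    return {
        "n_sets": len(sets),
        "union_cells": len(union),
        "union_land_area_km2": union_area,
        "union_area_fraction": union_area / total_area if total_area else 0.0,
        "union_species": len(union_species),
        "union_species_fraction": len(union_species) / n_species if n_species else 0.0,
        "per_n_metrics": per_n,
        "per_metric": per_metric,
        "pairwise": pairwise,
    }


# ---------------------------------------------------------------------------
# contiguous regions
# ---------------------------------------------------------------------------

_STRUCTURES = {
    "queen": np.ones((3, 3), dtype=int),
    "rook": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
}


@dataclass
class HotspotRegion:
    """A maximal connected component of hotspot cells."""

    region_id: int
    cell_ids: list[str]
    land_area_km2: float
    n_species: int | None = None
    metric_means: dict = field(default_factory=dict)
    species_per_genus: float | None = None
    species_per_family: float | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def label_regions(
    union_cells: set[str] | frozenset[str],
    cells: CellTable,
    adjacency: str = "queen",
    matrix: OccurrenceMatrix | None = None,
    diversity: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> list[HotspotRegion]:
    """Group hotspot cells into maximal connected components.

    Queen adjacency (default) joins diagonal neighbours, which keeps
    diagonal mountain-chain cells in one region; rook joins edges only.
    Singleton regions are allowed.  Regions are numbered 1.. in order of
    decreasing land area (ties by smallest cell id) for deterministic
    output.  If `matrix`/`diversity`/`taxonomy` are given, per-region
    species counts, metric means and species/genus, species/family ratios
    are attached.
    """
    if adjacency not in _STRUCTURES:
        raise DataError("adjacency must be 'queen' or 'rook'")
    if not cells.has_coordinates:
        raise DataError("region labeling needs row/col coordinates in the cell table")
    sub = cells.data[cells.data["cell_id"].isin(set(union_cells))]
    missing = set(union_cells) - set(sub["cell_id"])
    if missing:
        raise DataError(f"hotspot cells absent from cell table: {sorted(missing)[:5]}")
    if sub.empty:
        return []
    r0, c0 = int(sub["row"].min()), int(sub["col"].min())
    rows = sub["row"].astype(int).to_numpy() - r0
    cols = sub["col"].astype(int).to_numpy() - c0
    raster = np.zeros((rows.max() + 1, cols.max() + 1), dtype=bool)
    raster[rows, cols] = True
    labels, n_regions = ndimage.label(raster, structure=_STRUCTURES[adjacency])
    area = cells.data.set_index("cell_id")["land_area_km2"]

    groups: dict[int, list[str]] = {}
    for cid, r, c in zip(sub["cell_id"], rows, cols):
        groups.setdefault(int(labels[r, c]), []).append(cid)

    regions = []
    for cids in groups.values():
        cids = sorted(cids)
        reg = HotspotRegion(
            region_id=0,
            cell_ids=cids,
            land_area_km2=float(area.loc[cids].sum()),
        )
        if matrix is not None:
            sp = matrix.species_in_cells(cids)
            reg.n_species = len(sp)
            if taxonomy is not None:
                ratios = region_taxon_ratios(cids, matrix, taxonomy)
                reg.species_per_genus = ratios["species_per_genus"]
                reg.species_per_family = ratios["species_per_family"]
        if diversity is not None:
            div = diversity[diversity["cell_id"].astype(str).isin(cids)]
            reg.metric_means = {
                m: float(div[m].mean()) for m in DEFAULT_METRICS if m in div.columns
            }
        regions.append(reg)
    regions.sort(key=lambda r: (-r.land_area_km2, r.cell_ids[0]))
    for i, reg in enumerate(regions, start=1):
        reg.region_id = i
    return regions


def region_taxon_ratios(
    region_cells: list[str],
    matrix: OccurrenceMatrix,
    taxonomy: pd.DataFrame,
) -> dict:
    """Species/genus and species/family ratios over a region's cell union.

    `taxonomy` maps species_id → genus, family; every region species must
    be mapped.
    """
    if not {"species_id", "genus", "family"}.issubset(taxonomy.columns):
        raise DataError("taxonomy needs species_id, genus, family columns")
    species = matrix.species_in_cells(region_cells)
    tax = taxonomy.drop_duplicates("species_id").set_index("species_id")
    unmapped = [s for s in species if s not in tax.index]
    if unmapped:
        raise DataError(f"species missing from taxonomy: {unmapped[:5]}")
    sub = tax.loc[list(species)]
    n_sp = len(species)
    return {
        "n_species": n_sp,
        "n_genera": int(sub["genus"].nunique()),
        "n_families": int(sub["family"].nunique()),
        "species_per_genus": n_sp / sub["genus"].nunique() if n_sp else float("nan"),
        "species_per_family": n_sp / sub["family"].nunique() if n_sp else float("nan"),
    }


def regions_table(regions: list[HotspotRegion]) -> pd.DataFrame:
    """Flat per-region summary table."""
    rows = []
    for r in regions:
        row = {
            "region_id": r.region_id,
            "n_cells": r.n_cells,
            "land_area_km2": r.land_area_km2,
            "n_species": r.n_species,
            "species_per_genus": r.species_per_genus,
            "species_per_family": r.species_per_family,
            "cell_ids": ";".join(r.cell_ids),
        }
        for m, v in r.metric_means.items():
            row[f"mean_{m}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
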