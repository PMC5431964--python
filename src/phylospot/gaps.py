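"""Conservation-gap classification of hotspot cells.

International conservation guidance puts 10–12% of each ecosystem's area
under protection; a hotspot cell is therefore a *conservation gap* when its
nature-reserve coverage (reserve_area / land_area) is below the threshold
(default 10%).  Cells split into three classes:

* ``uncovered``        — coverage exactly 0;
* ``under_protected``  — 0 < coverage < threshold;
* ``protected``        — coverage ≥ threshold (``strict_protected=True``
  demands coverage > threshold, resolving the ambiguous boundary the other
  way).

Gap cells are the union of ``uncovered`` and ``under_protected``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import CellTable, DataError

CLASSES = ["uncovered", "under_protected", "protected"]


@dataclass
class GapReport:
    """Per-cell coverage classes plus aggregate gap proportions."""

    threshold: float
    table: pd.DataFrame          # cell_id, coverage, gap_class, n_metrics
    summary: dict

    def class_counts(self) -> pd.Series:
        return self.table["gap_class"].value_counts().reindex(CLASSES, fill_value=0)


def classify_gaps(
    hotspot_cells,
    cells: CellTable,
    threshold: float = 0.10,
    strict_protected: bool = False,
    n_metrics: pd.Series | None = None,
) -> GapReport:
    """Classify hotspot cells by reserve coverage and summarize gaps.

    ``n_metrics`` (optional, per-cell count of metrics that selected the
    cell) enables the per-n-metric gap proportions: the fraction of the
    n-metric hotspot land area whose cells are gaps.
    """
    if not 0 < threshold < 1:
        raise DataError("gap threshold must be in (0, 1)")
    hotspot_cells = sorted(set(map(str, hotspot_cells)))
    known = set(cells.cell_ids)
    missing = [c for c in hotspot_cells if c not in known]
    if missing:
        raise DataError(f"hotspot cells absent from cell table: {missing[:5]}")

    coverage = cells.coverage().loc[hotspot_cells]
    cov = coverage.to_numpy()
    protected = cov > threshold if strict_protected else cov >= threshold
    gap_class = np.where(cov == 0, "uncovered",
                         np.where(protected, "protected", "under_protected"))

    table = pd.DataFrame({
        "cell_id": hotspot_cells,
        "coverage": cov,
        "gap_class": gap_class,
    })
    if n_metrics is not None:
        table["n_metrics"] = n_metrics.reindex(hotspot_cells).to_numpy()

    area = cells.data.set_index("cell_id")["land_area_km2"].loc[hotspot_cells]
    n = len(table)
    counts = pd.Series(gap_class).value_counts()
    proportions = {c: float(counts.get(c, 0)) / n for c in CLASSES} if n else {}
    is_gap = gap_class != "protected"
    summary = {
        "threshold": threshold,
        "n_hotspot_cells": n,
        "class_proportions": proportions,
        "gap_fraction_cells": float(is_gap.sum()) / n if n else 0.0,
        "gap_fraction_area": float(area.to_numpy()[is_gap].sum()) / float(area.sum())
        if n and area.sum() > 0 else 0.0,
    }
    if n_metrics is not None and n:
        per_n = {}
        nm = table["n_metrics"].to_numpy()
        for k in sorted(pd.unique(nm)):
            sel = nm == k
            a = area.to_numpy()[sel]
            per_n[int(k)] = {
                "cells": int(sel.sum()),
                "gap_fraction_area": float(a[is_gap[sel]].sum()) / float(a.sum())
                if a.sum() > 0 else 0.0,
            }
        summary["per_n_metrics_gap"] = per_n
    return GapReport(threshold=threshold, table=table, summary=summary)


def overlap_area(hotspot_cells, cells: CellTable) -> dict:
    """Reserve area inside hotspot cells and its fractions.

    Returns the summed reserve area within the hotspot cells, its fraction
    of the total study land area, and its fraction of the total reserve
    area.
    """
    hotspot_cells = sorted(set(map(str, hotspot_cells)))
    sub = cells.data.set_index("cell_id")
    missing = [c for c in hotspot_cells if c not in sub.index]
    if missing:
        raise DataError(f"hotspot cells absent from cell table: {missing[:5]}")
    reserve_in_hotspots = float(sub.loc[hotspot_cells, "reserve_area_km2"].sum())
    total_land = cells.total_land_area
    total_reserve = cells.total_reserve_area
    return {
        "reserve_area_in_hotspots_km2": reserve_in_hotspots,
        "fraction_of_study_area": reserve_in_hotspots / total_land if total_land else 0.0,
        "fraction_of_reserve_area": reserve_in_hotspots / total_reserve if total_reserve else 0.0,
    }
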