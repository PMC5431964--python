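import itertools

import numpy as np
import pandas as pd
import pytest

from phylospot import (
    DataError,
    HotspotSet,
    label_regions,
    multi_metric_counts,
    overlap_summary,
    region_taxon_ratios,
    select_hotspots,
)

from conftest import make_cells, make_matrix


def div_table(values, metric="SR"):
    return pd.DataFrame({"cell_id": [f"c{k}" for k in range(len(values))],
                         metric: values})


class TestSelection:
    def test_distinct_values_select_exact_top_fraction(self):
        table = div_table(list(range(1, 101)))
        hs = select_hotspots(table, "SR", 0.10)
        assert len(hs) == 10
        assert hs.cells == {f"c{k}" for k in range(90, 100)}

    def test_ties_at_cutoff_all_included(self):
        values = [5, 5, 5] + [1] * 97
        hs = select_hotspots(div_table(values), "SR", 0.01)
        assert hs.cells == {"c0", "c1", "c2"}

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 50, 200)
        table = div_table(values)
        shuffled = table.sample(frac=1.0, random_state=1)
        assert select_hotspots(table, "SR", 0.10).cells == \
            select_hotspots(shuffled, "SR", 0.10).cells

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        table = div_table(rng.random(300))
        prev = frozenset()
        for p in (0.02, 0.05, 0.10, 0.25, 0.5):
            cells = select_hotspots(table, "SR", p).cells
            assert prev <= cells
            prev = cells

    def test_nan_cells_ineligible(self):
        table = div_table([1.0, 2.0, np.nan, 4.0], metric="PD_rel")
        hs = select_hotspots(table, "PD_rel", 0.5)
        assert hs.n_eligible == 3
        assert "c2" not in hs.cells

    def test_range_mode(self):
        # values 0..100: top 10% of the value range means value >= 90
        table = div_table(list(range(101)))
        hs = select_hotspots(table, "SR", 0.10, mode="range")
        assert hs.cells == {f"c{k}" for k in range(90, 101)}

    def test_errors(self):
        table = div_table([1, 2, 3])
        with pytest.raises(DataError):
            select_hotspots(table, "SR", 0.0)
        with pytest.raises(DataError):
            select_hotspots(table, "missing", 0.1)
        with pytest.raises(DataError):
            select_hotspots(div_table([np.nan] * 3, metric="PD_rel"), "PD_rel", 0.1)


def _mk_sets(*cell_sets, p=0.1):
    return [
        HotspotSet(metric=f"m{i}", p=p, cells=frozenset(cs),
                   n_eligible=100, cutoff=0.0)
        for i, cs in enumerate(cell_sets)
    ]


class TestOverlapSummary:
    def _cells(self, n=200):
        return make_cells([f"c{k}" for k in range(n)])

    def _matrix(self, n=200):
        return make_matrix({"A": ["c0"], "B": ["c1"]},
                           cell_ids=[f"c{k}" for k in range(n)])

    def test_identical_sets(self):
        sets = _mk_sets({"c0", "c1"}, {"c0", "c1"})
        s = overlap_summary(sets, self._cells(), self._matrix())
        assert s["pairwise"]["m0|m1"]["jaccard_pct"] == 100.0
        assert s["per_n_metrics"][2]["cells"] == 2
        assert s["per_n_metrics"][1]["cells"] == 0

    def test_disjoint_sets(self):
        sets = _mk_sets({"c0", "c1"}, {"c2", "c3", "c4"})
        s = overlap_summary(sets, self._cells(), self._matrix())
        assert s["pairwise"]["m0|m1"]["jaccard_pct"] == 0.0
        assert s["union_cells"] == 5

    def test_random_sets_match_set_algebra_oracle(self):
        rng = np.random.default_rng(12)
        universe = [f"c{k}" for k in range(200)]
        raw = [set(rng.choice(universe, size=rng.integers(5, 60), replace=False))
               for _ in range(4)]
        sets = _mk_sets(*raw)
        s = overlap_summary(sets, self._cells(), self._matrix())
        union = set().union(*raw)
        assert s["union_cells"] == len(union)
        for n in range(1, 5):
            expect = sum(1 for c in union
                         if sum(c in r for r in raw) == n)
            assert s["per_n_metrics"][n]["cells"] == expect
        # per-n counts partition the union
        assert sum(s["per_n_metrics"][n]["cells"] for n in range(1, 5)) == len(union)
        for (i, a), (j, b) in itertools.combinations(enumerate(raw), 2):
            pw = s["pairwise"][f"m{i}|m{j}"]
            assert pw["jaccard_pct"] == pytest.approx(100 * len(a & b) / len(a | b))
            assert pw["over_min_pct"] == pytest.approx(
                100 * len(a & b) / min(len(a), len(b)))

    def test_distinct_species_accounting(self):
        cells = self._cells(10)
        matrix = make_matrix(
            {"A": ["c0"], "B": ["c1"], "C": ["c0", "c1"]},
            cell_ids=[f"c{k}" for k in range(10)],
        )
        sets = _mk_sets({"c0"}, {"c1"})
        s = overlap_summary(sets, cells, matrix)
        assert s["per_metric"]["m0"]["distinct_species"] == 1  # A only in m0
        assert s["per_metric"]["m1"]["distinct_species"] == 1
        assert s["union_species"] == 3

    def test_universe_mismatch_errors(self):
        sets = _mk_sets({"c0"}, {"zz"})
        with pytest.raises(DataError):
            overlap_summary(sets, self._cells(), self._matrix())


class TestRegions:
    def _grid_cells(self, coords, **kw):
        ids = [f"r{r}c{c}" for r, c in coords]
        return ids, make_cells(ids, coords=coords, **kw)

    def test_edge_neighbors_one_region(self):
        ids, cells = self._grid_cells([(0, 0), (0, 1)])
        regions = label_regions(set(ids), cells)
        assert len(regions) == 1

    def test_diagonal_queen_vs_rook(self):
        ids, cells = self._grid_cells([(0, 0), (1, 1)])
        assert len(label_regions(set(ids), cells, adjacency="queen")) == 1
        assert len(label_regions(set(ids), cells, adjacency="rook")) == 2

    def test_block_plus_singleton(self):
        coords = [(r, c) for r in range(3) for c in range(3)] + [(9, 9)]
        ids, cells = self._grid_cells(coords)
        regions = label_regions(set(ids), cells)
        sizes = sorted(r.n_cells for r in regions)
        assert sizes == [1, 9]
        # deterministic numbering: largest region first
        assert regions[0].n_cells == 9 and regions[0].region_id == 1

    def test_missing_coordinates_error(self):
        cells = make_cells(["c1", "c2"])
        with pytest.raises(DataError):
            label_regions({"c1"}, cells)


class TestTaxonRatios:
    def test_hand_counts(self):
        matrix = make_matrix({f"s{i}": ["c0"] for i in range(10)})
        tax = pd.DataFrame({
            "species_id": [f"s{i}" for i in range(10)],
            "genus": [f"g{i % 5}" for i in range(10)],
            "family": [f"f{i % 2}" for i in range(10)],
        })
        r = region_taxon_ratios(["c0"], matrix, tax)
        assert r["species_per_genus"] == pytest.approx(2.0)
        assert r["species_per_family"] == pytest.approx(5.0)

    def test_single_species(self):
        matrix = make_matrix({"s0": ["c0"]})
        tax = pd.DataFrame({"species_id": ["s0"], "genus": ["g"], "family": ["f"]})
        r = region_taxon_ratios(["c0"], matrix, tax)
        assert r["species_per_genus"] == 1.0 and r["species_per_family"] == 1.0

    def test_random_instance_matches_hand_count(self):
        rng = np.random.default_rng(5)
        species = [f"s{i}" for i in range(30)]
        matrix = make_matrix({s: ["c0", "c1"] for s in species})
        genera = rng.integers(0, 7, 30)
        fams = rng.integers(0, 3, 30)
        tax = pd.DataFrame({"species_id": species,
                            "genus": [f"g{g}" for g in genera],
                            "family": [f"f{f}" for f in fams]})
        r = region_taxon_ratios(["c0"], matrix, tax)
        assert r["n_genera"] == len(set(genera))
        assert r["species_per_family"] == pytest.approx(30 / len(set(fams)))

    def test_unmapped_species_error(self):
        matrix = make_matrix({"s0": ["c0"], "s1": ["c0"]})
        tax = pd.DataFrame({"species_id": ["s0"], "genus": ["g"], "family": ["f"]})
        with pytest.raises(DataError, match="s1"):
            region_taxon_ratios(["c0"], matrix, tax)


def test_multi_metric_counts_partition():
    sets = _mk_sets({"c0", "c1"}, {"c1", "c2"}, {"c1"})
    counts = multi_metric_counts(sets)
    assert counts["c1"] == 3 and counts["c0"] == 1 and counts["c2"] == 1
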