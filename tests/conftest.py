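import numpy as np
import pandas as pd
import pytest

from phylospot import CellTable, OccurrenceMatrix, Phylogeny
from phylospot.synthetic import generate_phylogeny


def make_cells(cell_ids, land=2500.0, reserve=0.0, coords=None):
    """Cell table helper; `land`/`reserve` may be scalars or sequences."""
    n = len(cell_ids)
    land = np.broadcast_to(np.asarray(land, dtype=float), n)
    reserve = np.broadcast_to(np.asarray(reserve, dtype=float), n)
    df = pd.DataFrame({
        "cell_id": list(cell_ids),
        "land_area_km2": land,
        "reserve_area_km2": reserve,
    })
    if coords is not None:
        df["row"] = [rc[0] for rc in coords]
        df["col"] = [rc[1] for rc in coords]
    return CellTable(df)


def make_matrix(occ: dict, cell_ids=None):
    """OccurrenceMatrix from {species: [cells]}."""
    if cell_ids is None:
        cell_ids = sorted({c for v in occ.values() for c in v})
    species = sorted(occ)
    inc = np.zeros((len(species), len(cell_ids)), dtype=bool)
    cpos = {c: k for k, c in enumerate(cell_ids)}
    for i, s in enumerate(species):
        for c in occ[s]:
            inc[i, cpos[c]] = True
    return OccurrenceMatrix(species, list(cell_ids), inc)


def random_instance(rng, max_species=10, max_cells=20):
    """Random Yule tree + occurrence matrix for oracle comparisons."""
    n_species = int(rng.integers(2, max_species + 1))
    n_cells = int(rng.integers(2, max_cells + 1))
    tree = generate_phylogeny(n_species, seed=int(rng.integers(2**31)))
    cell_ids = [f"c{k}" for k in range(n_cells)]
    inc = rng.random((n_species, n_cells)) < rng.uniform(0.1, 0.6)
    # every species occupies >= 1 cell
    for i in range(n_species):
        if not inc[i].any():
            inc[i, int(rng.integers(n_cells))] = True
    matrix = OccurrenceMatrix(sorted(tree.leaf_labels), cell_ids, inc)
    return tree, matrix


@pytest.fixture
def worked_tree():
    """The 3-taxon tree used in the hand-derived examples."""
    return Phylogeny.from_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def worked_matrix():
    """A in c1; B in c1, c2; C in c2."""
    return make_matrix({"A": ["c1"], "B": ["c1", "c2"], "C": ["c2"]})
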