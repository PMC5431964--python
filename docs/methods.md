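# Methods

## The analysis

`phylospot` implements a grid-based diversity-hotspot and conservation-gap
analysis. The analysis universe is a set of grid cells (nominally 50 × 50 km,
2,500 km²) carrying land and nature-reserve areas, a binary species × cell
occurrence matrix, and a rooted, dated phylogeny of the species pool. The
pipeline stages are: cell filtering → taxon alignment → per-cell metrics →
top-percentile hotspot selection per metric → multi-metric overlap accounting
and contiguous-region labeling → reserve-coverage gap classification.

### Cell filtering and range sizes

Cells with land area strictly below 1,250 km² (half the nominal cell) are
excluded; incomplete coastal or border cells otherwise bias per-cell values
downward. Species range size R_j — the incidence row sum — is recomputed
*after* filtering, so endemism weights refer to the analysis grid; the
1/R_j weights otherwise mix two universes. Callers who want pre-filter
ranges can compute `matrix.range_sizes` before calling `filter_cells`.
Species left with no occupied cell after filtering are dropped (logged).
`reserve_area > land_area` is clamped with a warning rather than rejected:
such slivers are routine digitization artifacts.

### Metrics and their conventions

Definitions are in the README. Conventions that were genuinely open:

- **PD rooting.** Faith's PD is computed over the union of *root paths* of
  the cell's species, so stem branches above the species' most recent
  common ancestor are included and a single species has PD equal to its
  root-path length. This choice makes the branch-wise bookkeeping of PE
  exact: every branch contributes its full length L_c exactly once across
  all cells, hence Σ_cells PE = PD(full pool) to machine precision. The
  unrooted variant (spanning paths among the taxa only, single taxon → 0)
  is available via `rooted=False` / `--unrooted-pd`.
- **PD_rel at S = 1.** log₁₀ 1 = 0, so PD_rel is undefined. Default policy
  is an explicit `pdrel_undefined` flag plus NaN, which removes such cells
  from PD_rel hotspot eligibility; `pdrel_s1="zero"` treats them as zero
  instead. We flag rather than impute because either imputation silently
  distorts the ranking tail.
- **Empty cells.** Flagged `empty`; SR = 0, PE = 0 (mathematically exact),
  all other metrics NaN — never silent zeros.
- **Polytomies** are kept as-is; supertrees are polytomy-rich and any
  arbitrary resolution would inject fake branch lengths. Zero-length
  branches are legal and contribute nothing.

All per-cell metrics come from a single post-order sweep that carries a
per-branch vector of descendant presence per cell; output is invariant to
species and cell ordering (tested).

### Age smoothing

`bladj_smooth` implements branch-length adjustment against a node-age
table: leaves sit at age 0, the root age must be constrained, and
unconstrained internal nodes on each path between consecutive constrained
nodes are spaced at equal age steps; branch lengths are recomputed as age
differences. Interpolation runs in deterministic pre-order; a node lying on
several constrained-to-constrained paths takes its first (pre-order)
assignment and then anchors deeper interpolation, which matches the
even-placement intent of the classic algorithm without claiming
bit-compatibility with any particular implementation. Constraint
violations (a fixed node older than its nearest fixed ancestor, or derived
negative branch lengths) raise; they are data errors, not cases to repair
silently.

### Hotspot selection

"Top p%" is read as the top fraction of *cells* ranked by metric value: the
cutoff is the ⌈p·n_eligible⌉-th largest value and every cell tied with the
cutoff is included, so selection is deterministic, order-invariant and
monotone in p. The alternative literal reading — the top p fraction of the
metric's *value range* — is implemented as `threshold_mode="range"` for
sensitivity analysis; on heavy-tailed metrics it selects far fewer cells.
Because published overlap percentages rarely state their denominator,
pairwise spatial overlap is reported under both conventions, labeled:
|A∩B|/|A∪B| (Jaccard) and |A∩B|/min(|A|,|B|). Species-composition
similarity defaults to Sørensen (Jaccard optional).

### Regions and gaps

Hotspot-union cells are grouped into maximal connected components with
queen adjacency by default (diagonal neighbours join, keeping diagonal
mountain-chain cells in one region; rook available), via
`scipy.ndimage.label` on the grid raster. Regions are numbered by
decreasing land area for stable output and carry species counts, metric
means, and species/genus and species/family ratios when a taxonomy is
supplied.

Gap classification follows the 10%-coverage guideline: a hotspot cell is a
*gap* when reserve coverage (reserve_area/land_area) is below the
threshold, split into `uncovered` (exactly 0) and `under_protected`
(0 < coverage < threshold); coverage exactly at the threshold counts as
protected by default (the boundary convention is ambiguous in common
usage; `strict_protected=True` gives the other reading).

## Synthetic data

The generator emulates the structure of a national woody-plant atlas
analysis, not any real flora:

- **Grid**: full rectangular grid; border cells are truncated below the
  nominal area with probability 0.3 (uniform fraction), exercising the
  exclusion rule the way coastal cells do.
- **Phylogeny**: Yule (pure-birth) process, one exponential waiting time
  per speciation event plus a final one so all branch lengths are positive;
  ultrametric and bifurcating by construction.
- **Ranges**: sizes are lognormal (defaults log-mean 2.5, log-sd 1.5 —
  median ≈ 12 cells with a heavy right tail, so most species are
  narrow-ranged, as in real endemic-rich floras), clamped to [1, n_cells],
  and grown as contiguous patches by seeded breadth-first accretion on rook
  adjacency from a start cell — the simplest mechanism that yields cohesive,
  county-map-like ranges.
- **Placement**: start cells follow an exponential weight in the row index
  (the latitudinal richness gradient); the narrowest quantile of species
  starts at configurable endemism-center cells, and a configurable number
  of species can be planted as exact single-cell endemics so recovery tests
  have ground truth. A planted high-richness block attracts wide-ranged
  species with configurable probability.
- **Reserves**: per-cell coverage is zero-inflated Beta (defaults: 40%
  zeros, Beta(0.8, 4) otherwise — overall mean coverage near 10%, with many
  unprotected cells).

Defaults are a desk-scale rendition of the study conditions: 40 × 40 cells
and 400 species (a national 50-km analysis has a few thousand cells and
thousands of species; the scaling preserves the cell-to-species ratio's
order of magnitude while keeping any test under seconds). All randomness
derives from one explicit seed per generator call (grid: seed, tree:
seed+1, occurrences: seed+2); identical config and seed give byte-identical
CSV/Newick outputs.

What the generator does *not* emulate: climate-driven niches, spatial
autocorrelation between species beyond shared start-cell bias,
phylogenetic signal in range size (range sizes are drawn independently of
the tree), real reserve-network spatial clustering, and polytomies.
Passing tests therefore demonstrate the correctness of the *computations*
and the recoverability of planted patterns — not that any particular real
flora would yield similar hotspot configurations.

## Numerical choices

- Conservation identities (Σ WE = n_species, Σ PE = PD of the pool) hold to
  1e-9 and are asserted on every property-test instance.
- Oracle equivalence: the vectorized sweep is tested against a deliberately
  naive per-cell path-enumeration/set-union oracle on random instances.
- Tie handling in hotspot selection keeps all cutoff ties (never an
  arbitrary subset); region numbering breaks area ties by smallest cell id.
- Pipeline outputs are byte-stable across reruns: CSVs use fixed float
  formatting, JSON keys are sorted, and the manifest records input/output
  SHA-256 hashes instead of timestamps.

## Known limitations

- PE/PD are presence-based; abundance weighting is out of scope.
- No null-model standardization (e.g. randomization-based significance of
  PD/PE); values are raw.
- The region labeling requires integer row/col coordinates; arbitrary
  polygonal neighbourhoods are not supported.
- GIS steps (polygon-to-grid rasterization, projections, cartography) are
  upstream of this package: reserve coverage enters as per-cell areas.
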