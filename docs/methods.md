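# Methods

## Model

The agent is the population occupying one raster cell. The landscape is an
ordered series of (binary suitability, cost class) raster pairs on one
lon-lat grid; each step represents a fixed span of `step_years` (default
100). Within a step the simulator applies, in a fixed order:

1. **Extinction.** Occupied cells that turned unsuitable are removed and
   their rows/columns dropped from the divergence matrix **D**. If nothing
   survives, the run stops with a global-extinction status naming the step.
2. **Colonization.** Every suitable empty cell whose least-cost path (LCP)
   from some occupied source *s* is strictly below *s*'s per-step dispersal
   distance becomes occupied. The colonist copies the divergence row of its
   minimal-cost source (ties resolve to the lowest source cell id, with
   sources within 1e-9 relative cost treated as tied to absorb float
   round-off in the shortest-path sums). Copying the full row means a
   colonist starts at divergence 0 from its own source and at the sources'
   mutual divergence from other colonists — a propagule carries its source
   population's history, so refugial signal survives expansion fronts.
   Zero-initializing colonists instead would erase that signal.
3. **Connection and divergence update.** Occupied cells *i, j* are
   connected when `max(dᵢ, dⱼ) · T > LCP(i, j)` with *T* =
   `dispersal_threshold_years` (strict inequality; equality does not
   connect). All pairs inside one connected component have **D** reduced by
   `delta_flow` (floored at exactly 0); pairs in different components gain
   `drift_multiplier × delta_flow`. The diagonal stays 0 and **D** stays
   symmetric and non-negative by construction.

The component-wide (transitive) application of gene flow — rather than only
between directly linked pairs — is deliberate: a persistent cluster must
relax to *exactly* zero internal divergence, which stepping-stone-only
reduction cannot guarantee. Consequently a pair isolated for *a* steps and
then connected for *b* steps sits at `max(0, a·3δ − b·δ)` exactly; the test
suite checks this closed form against the simulator.

A **burn-in** repeats the oldest landscape for `burn_in_steps` full cycles
(default 50) before the dynamic phase, so refugia that are isolated in the
oldest step enter the dynamic run already differentiated. Because every
suitable cell of the oldest step starts occupied, colonization is a no-op
during burn-in and the phase purely accumulates divergence.

### Assumptions and knowingly omitted processes

* Divergence is abstract beta diversity in free units; only the
  accumulation:reduction ratio (default 3:1) is meaningful, `delta_flow`
  sets the unit. **D** is unbounded above (no saturation).
* No alleles, mutation, recombination, selection, carrying capacities or
  within-population (alpha) diversity; no coalescent machinery.
* Landscape classes modulate movement cost but never block it: any path is
  traversable at a price, so barriers are soft.

## Connectivity

The cost graph has one node per grid cell (all classes) and 8-connected
edges by default (4-connected available); 8-connectivity reduces grid-axis
artifacts in least-cost paths. An edge weighs its great-circle length
(haversine, Earth radius 6371.0 km — no projection, since the intended
extents are continental where planar distances fail) times the arithmetic
mean of the endpoint cells' class cost factors; the mean-of-endpoints rule
is the standard symmetric composition in cost-surface tooling. Suitable
habitat has factor 1 by definition; all non-suitable factors default to
1.25 (within the plausible range for ice/unsuitable land, and the value
used for the reference run; sea crossings can be penalized up to ~3×).
All-pairs LCP distances come from Dijkstra runs over the full grid
(scipy.sparse.csgraph), so optimal paths may cross cells outside the query
set; the result is symmetrized to cancel per-source round-off.
NODATA raster cells read as unsuitable land, which keeps the graph fully
connected.

Least-cost matrices are memoized per unique raster content within a run:
a landscape repeated across steps (burn-in, frozen glacial phases) costs a
single Dijkstra sweep.

## Dispersal

Per-cell dispersal is Weibull with shape *k* and median *m* km/year; the
scale λ = m/(ln 2)^(1/k) is derived so the kernel's median is exact, because
field estimates report medians and upper quantiles, never scales. Shape 1
is exponential (frequent long-distance dispersal, which tends to wash out
structure); shape 2.5 concentrates draws near the median. Defaults (k =
2.5, m = 4.3 km/yr, 95 % quantile ≈ 7.8 km/yr) correspond to the
caribou-calibrated setting of the reference experiment; medians worth
exploring span roughly 2–26 km/yr.

A km/year draw is compared against an LCP after multiplying by
`dispersal_threshold_years` (default = `step_years`): a 100-year step
represents a century of movement opportunity. This reconciliation of
per-year draws with century steps is a genuine modeling choice and is
config-exposed rather than hidden.

Draws are realized as the kernel quantile transform of one uniform per
*grid cell*, drawn once from the run seed. This makes draws (a) attached to
a cell once, never redrawn while it stays occupied, (b) independent of
colonization order, and (c) monotone in the kernel median at a fixed seed,
which underpins the dispersal-monotonicity property (more dispersal never
yields more clusters). A `redraw_each_step` flag replaces the table each
step from per-step child seeds for sensitivity analysis.

## Empirical estimators

* **Chord distance**: Dc(X,Y) = 2/(πL) · Σ_loci √(2(1 − Σ_a √(x_a y_a))),
  bounded by 2√2/π ≈ 0.9003. The 2/(πL) normalization is included (several
  published variants omit it); only relative structure matters for the
  Mantel/PCoA stage.
* **F_ST**: Weir & Cockerham (1984) θ, pairwise over populations,
  multi-locus as ratio of summed a/(a+b+c) variance components from sample
  sizes, allele frequencies and observed heterozygote frequencies — the
  de-facto standard for microsatellites. Negative pairwise estimates are
  retained in the matrix; the CLI clamps them to 0 only when feeding
  dissimilarity consumers (UPGMA, PCoA). The implementation is verified to
  1e-9 against an independent nested-ANOVA (sums-of-squares) computation.
* **Missing data**: available-allele counting per population × locus;
  undefined loci drop from a pair's locus count, individuals are never
  dropped globally. Genepop codes 0/000 are missing.

## Comparison pipeline

* **Site assignment**: nearest occupied cell center within a 200-km
  great-circle buffer (monotone in the buffer; ties to the lowest cell id);
  unassigned sites are excluded from both matrices.
* **PCoA**: Gower double-centering of −D²/2, symmetric eigendecomposition,
  coordinates scaled by √ of the positive eigenvalues. No Cailliez/Lingoes
  correction: negative eigenvalues are reported as-is and variance shares
  are computed over positive eigenvalues only.
* **Trees**: UPGMA (average linkage) with node heights at half the merge
  distance and alphabetical tie-breaks — the standard rooted dendrogram
  from a distance matrix; neighbor joining is available behind a flag.
* **Mantel**: Spearman's rho on strictly-lower-triangle entries; the null
  permutes rows/columns of the second matrix jointly; two-sided p =
  (#{|rho_perm| ≥ |rho_obs|} + 1)/(n_perm + 1) with n_perm = 999 by
  default. A squared Pearson correlation of the same two vectors is
  reported as a convenience R²; which regression a given study means by R²
  varies, so the symmetric correlation-based quantity is used.
* **Colors**: PCoA axes 1–2 are min-max scaled; axis 1 drives a red-blue
  gradient and axis 2 perturbs the green channel around mid-gray, giving a
  deterministic, translation-invariant coloring of maps by genetic
  distinctiveness.

## Synthetic study systems

`two_refugia_scenario` is the canonical experiment: a 30×30 grid of
1-degree cells centered on the equator (cell spacing ≈ 111 km, so km-scale
dispersal keeps its meaning), two 8-column suitable refugia at the west and
east edges, a 14-column glacier band between them for 100 glacial steps,
then the band turns suitable (the corridor) for 50 postglacial steps. The
barrier's LCP (≈ 2000 km at factor 1.25) comfortably exceeds any plausible
per-step dispersal reach of the default kernel, so the glacial phase holds
exactly two components; with default durations the final divergence matrix
is two-block (0 within refugial lineages, 400 units between), and PCoA
axis 1 carries 100 % of the positive variance. `corridor_rows` narrows the
corridor to a row band for contact-zone experiments.

`synthetic_genotypes` uses a hierarchical Balding–Nichols frequency model:
per locus, an ancestral frequency vector from a flat Dirichlet, population
frequencies from Dirichlet(ancestral · (1−F)/F) with F = `divergence_level`
(expected F_ST ≈ F, exact fixation at F = 1), then diploid genotypes
sampled from population frequencies. This gives monotone, tunable
structure for testing the estimators without coalescent machinery. It
deliberately omits linkage, mutation models, and isolation-by-distance, so
tests passing on it say nothing about those features of real data.
`random_scenario` provides persistence-correlated random landscapes for
property tests.

What the synthetic scenarios do *not* emulate: real coastline/topography,
continuous suitability, SDM error, uneven sampling. Passing the packaged
experiments demonstrates the mechanics of the model — refugial isolation,
contact, homogenization, and their statistical fingerprints — not the fit
of any particular empirical system.

## Numerical choices and problem sizes

* Grid/indexing convention: 0-based row-major linear cell ids from the
  north-west corner; rasters are ESRI ASCII with cell-center origins.
* Strict inequalities for connection and colonization thresholds; exact 0
  floor in the gene-flow update (no drift toward tiny negatives).
* Shortest-path exactness is verified against a dense Floyd–Warshall
  oracle on hundreds of random ≤ 5×5 grids (relative tolerance 1e-9).
* The packaged experiments run on 30×30 grids with 200 dynamic steps;
  divergence updates are O(n²) per step over ≤ 900 occupied cells and the
  whole reference run completes in a few seconds, which makes the scale a
  comfortable default for exploration while preserving all qualitative
  regimes (two-cluster isolation, merge, homogenization).

## Known limitations

* Gene-flow homogenization is component-wide and instantaneous in rate δ;
  there is no isolation-by-distance *within* a connected component, so
  within-cluster substructure of real data is not reproduced.
* The dispersal-threshold reconciliation (km/year × years-per-step) makes
  effective reach linear in step length; halving `step_years` is not
  equivalent to doubling the number of steps.
* Cost factors are cell-class constants; no anisotropy, seasonal ice, or
  continuous resistance surfaces.
* Mantel tests on matrices whose labels were matched through site
  assignment inherit the assignment's buffer arbitrariness; report `n`
  alongside rho and p.
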