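# Methods

This note documents the models, parameter choices and numerical conventions
behind `genescape`, and what the synthetic study design does and does not
show about real landscapes.

## Synthetic landscapes

The generator emulates the statistical structure of empirical
habitat-suitability maps for a rare, habitat-selective territorial raptor,
without reproducing any real geography.

A Gaussian random field is synthesized by convolving white noise with a
Gaussian kernel whose standard deviation equals `aggregation_length`
(meters); the field is then rank-transformed to [0, 1]. The rank map is
piecewise: the top `habitat_fraction_target` of cells map linearly onto
(`suitability_threshold`, 1], which pins the binary habitat fraction exactly
(to one cell) for every seed; the remaining cells map onto
[0, `suitability_threshold`] through a power law whose exponent is set so the
background mean equals `background_mean_suitability`. The background mean
(default 0.02) encodes that most of the landscape is near-zero suitability
for a species whose habitat covers ~1.5–2% of the area; it also determines
how strongly node placement concentrates in and around habitat. A uniform
background marginal would spread node-placement weight almost entirely into
the matrix and erase the structural contrast between aggregation levels,
which is the object of study.

`aggregation_length` is the fragmentation dial: at matched habitat amount,
10,000 m produces few, large, spatially extensive patches ("low
fragmentation") and 1,500 m produces many small scattered patches ("high
fragmentation"). This control is asserted behaviorally (NP/PD down, LPI and
GYRATE up in ≥90% of seeded pairs), not tied to the synthesis route.
Generation fails if the grid's shorter extent is below four correlation
lengths, where too few independent patches exist for the contrast to be
meaningful.

Default geometry is desk-scale: 200×200 cells at 500 m (a 100×100 km
landscape) with 200 territory nodes; larger extents are configuration, not
code, changes.

Suitability maps to resistance through the bounded negative exponential
`R = r_min + (r_max − r_min)(e^(−cS) − e^(−c))/(1 − e^(−c))`, a strictly
decreasing bijection of [0,1] onto [1,10]. The shape `c` (default 2)
controls how quickly permeability improves with suitability; larger `c`
lowers resistance at every intermediate suitability.

Habitat binarization uses a strict inequality (suitability exactly at the
0.2 threshold is non-habitat); the tie case is measure-zero for the
continuous generator but the convention is fixed and tested.

Node placement draws cells without replacement with probability proportional
to suitability and rejects candidates closer than `min_spacing` (default two
cell sizes) to an accepted node — a simple operationalization of "spatially
balanced" placement. Low-suitability cells are down-weighted, not excluded.

## Gene-flow simulator

The simulator is a cost-distance population model with discrete,
nonoverlapping generations: territory nodes of capacity 2, monogamous
nearest-neighbor mating, Poisson fecundity (mean 3.8 offspring per pair per
generation, ≈ 0.76 young/pair/year over five breeding seasons), 50:50 sex
ratio, 30 unlinked neutral loci with 10 alleles, no mutation and no
sex-biased dispersal. Founders receive uniform random alleles, so expected
initial heterozygosity is 1 − 1/k = 0.9.

Conventions the model fixes where the biology leaves freedom:

- **"Nearest" mate** is measured in the scenario's cost distance (so the
  IBD/IBR switch affects mating as well as dispersal); females are processed
  in seeded random order, ties break to the lower node id and then lower
  individual id. No maximum mating distance is imposed — the dispersal limit
  carries the distance constraint — but unreachable (infinite-cost) pairs
  never mate.
- **Settlement** is sequential in seeded random order with immediate slot
  decrement (a reproducible serialization of the settlement lottery).
  Destination probability is ∝ exp(−λd) truncated at the dispersal limit,
  over nodes with a free slot; staying home is allowed; offspring with no
  reachable free slot die.
- **Natal node** is the mother's node (territorial convention).
- **Extinct runs** are retained in the output, flagged, and excluded from
  final-generation summaries with the count reported.
- Per-run RNG streams derive from `SeedSequence((scenario_seed, run_index))`,
  so runs are independent and the whole scenario is reproducible bit-for-bit.

The dispersal kernel's rate λ is calibrated by bracketed root finding
(relative tolerance 1e-12) so that F(50,000)/F(d_max) = 0.9 for the
exponential CDF F — i.e., ~90% of dispersal movements fall below 50 km. For
d_max = 300,000 the truncation correction is ~1e-6 and λ ≈ ln(10)/50,000 ≈
4.6×10⁻⁵ per cost unit. Distances are sampled by inverse CDF.

## Cost distances and connectivity

Least-cost distances are computed by multi-source Dijkstra on the
8-connected grid graph; an edge costs the mean of its endpoint resistances
times the cell size, times √2 for diagonal moves. This makes one cost unit
equal one meter at resistance 1, so the 200/300 km dispersal limits
correspond to 200,000/300,000 cost units on a uniform surface exactly.
Unreachable or over-limit pairs carry an infinity sentinel; Mantel tests and
regressions drop such pairs pairwise and report the count used.

The cumulative resistant kernel sums, over source nodes, the truncated
exponential dispersal weight of the least-cost distance to every cell —
an expected relative density of dispersers. The summation is unnormalized
(each source contributes weight 1 at distance 0); per-node connectivity is
the kernel value of the node's cell.

## Genetic summaries

Neighborhoods pool individuals at all nodes within a Euclidean radius
(default 20 km) of the focal node. `Ns` is the neighborhood census size —
a census proxy for effective population size, not an LD-based estimator.
`He` is 1 − Σp² from pooled neighborhood allele frequencies, `Ho` the mean
heterozygote indicator, `Ar` the mean count of distinct alleles per locus
without rarefaction (neighborhood sizes vary; values are comparable within,
not across, radically different designs). Empty neighborhoods are flagged
missing rather than zero-filled.

`Dps` between two individuals is the per-locus multiset overlap of allele
pairs divided by 2, averaged over loci (AB–AB → 1, AA–AB → 0.5, AA–BB → 0);
implemented as 1 − cityblock(allele-count vectors)/(4L). Node-pair `Dps`
averages all cross-node individual pairs; diagonals are defined as 1. `Dps`
is a similarity, so isolation appears as *negative* Mantel correlations with
distance.

Moving-window surfaces average node values within the radius of each output
cell center (default output resolution 4× the input cell), masking cells
with fewer than `min_n` (default 5) contributing nodes.

## Statistics

The Mantel statistic is the Pearson correlation of strict upper triangles;
the null jointly permutes rows and columns of one matrix; the two-sided
p-value uses the add-one correction (c+1)/(m+1) over m permutations
(default 1000). The three regression forms are fitted by OLS (logarithmic on
ln x, exponential as OLS of ln y on x) and compared by adjusted R² computed
from predictions back on the original response scale, so the forms compete
on equal footing; each fit's p-value is the slope test on its own fitting
scale.

## Study design and problem sizes

The packaged study runs at desk scale: 200×200 cells, 200 nodes, 10 Monte
Carlo runs of 50 generations per scenario, chosen as the package's default
experimental grain; the full factorial is fragmentation (aggregation
10,000 vs 1,500 m at matched PLAND 1.75%) × isolation (IBD/IBR) × dispersal
limit (200/300 km). The paired-landscape comparison uses ten seed pairs
under IBR with the 300 km limit (the two limits behave very similarly at
this extent, which spans only 100 km).

## What the synthetic design does and does not show

The generator reproduces the *structure* relevant to the question —
autocorrelated suitability, rare habitat, matched habitat amount across
fragmentation levels, suitability-weighted territory placement — but not
real terrain, anisotropic canyon networks, temporal habitat change, or
empirical dispersal behavior. Results are therefore directional statements
about the mechanism (aggregation concentrates nodes, shortens resistance
paths, sustains denser neighborhoods and slows local allele loss), not
quantitative predictions for any real landscape. Heterozygosity contrasts
at 50 generations and a 100 km extent are small (≈0.01); they grow with
extent, generations and binding dispersal limits. Known limitations: no
mutation (diversity can only decline), census-based `Ns`, Euclidean
neighborhood membership (a cost-distance neighborhood would tighten the
IBR coupling), and unnormalized kernel connectivity.
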