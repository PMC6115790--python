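# genescape

Individual-based landscape-genetics simulation of a territorial, monogamous
raptor (modeled on a forest owl occupying ~2% of a large landscape), asking
how habitat **fragmentation** and landscape **connectivity** shape gene flow,
effective population size and genetic diversity.

The package is organised as an analysis project: every computation lives in
the importable library under `src/genescape/`, and the numbered scripts under
`analysis/` are thin narrative drivers that run the study and write tables
under `results/`.

## The model

Territory nodes (capacity 2 — one monogamous pair) are placed on a synthetic
habitat-suitability raster by suitability-weighted, minimum-spacing sampling.
Movement cost comes from a resistance surface `R ∈ [1, 10]` obtained from
suitability `S ∈ [0, 1]` by a bounded negative-exponential transform

```
R = 1 + 9 · (e^(−cS) − e^(−c)) / (1 − e^(−c)),      c > 0  (default 2)
```

so `R(1) = 1`, `R(0) = 10`. Between-node distances are least-cost paths on the
8-connected grid graph (edge cost = mean endpoint resistance × cell size,
×√2 on diagonals), making 1 cost unit = 1 meter at resistance 1; the
isolation-by-distance (IBD) null uses the same machinery on a uniform
resistance-1 surface, isolation-by-resistance (IBR) uses the transformed
surface.

Generations are discrete and nonoverlapping. Each cycle:

1. **Pairing** — each female mates with the nearest unpaired male by the
   scenario's cost distance (monogamous territorial mating).
2. **Reproduction** — offspring per pair ~ Poisson(3.8) (≈0.76 young/pair/year
   over ~5 breeding seasons); independent Mendelian segregation at 30 neutral
   loci with 10 alleles each; no mutation, no linkage, no selection.
3. **Dispersal** — all adults die; each offspring settles at a node with a
   free slot with probability ∝ `e^(−λ·d)` for least-cost distance `d` up to
   the dispersal limit (200 or 300 km ≡ 200,000 / 300,000 cost units), where
   λ is calibrated so that ~90% of dispersal movements are below 50 km.

Summaries follow standard landscape-genetics practice: neighborhood (20 km)
census size `Ns`, allelic richness `Ar`, observed/expected heterozygosity
`Ho`/`He = 1 − Σp²`; pairwise proportion of shared alleles `Dps` between
nodes; Mantel tests (1000 permutations) of `Dps` against cost distance;
linear / logarithmic / exponential fits of each diversity index against
cumulative resistant-kernel connectivity, ranked by adjusted R² on the
original response scale. Fragmentation is quantified with FRAGSTATS-style
class metrics (PLAND, NP, PD, LPI, AREA_MN, GYRATE) on the binary habitat
map (suitability > 0.2).

## Worked example

```
$ python analysis/01_build_landscapes.py
low_fragmentation: PLAND=1.75%  NP=2  PD=0.0002/100ha  LPI=1.24%  AREA_MN=8750 ha  GYRATE=3607 m
high_fragmentation: PLAND=1.75%  NP=32  PD=0.0032/100ha  LPI=0.16%  AREA_MN=547 ha  GYRATE=806 m
```

Both landscapes carry the same habitat amount (PLAND 1.75%), but the long
autocorrelation range (10,000 m) concentrates it into 2 large patches while
the short range (1,500 m) scatters it into 32 small ones — the
single-large-vs-several-small contrast.

```
$ python analysis/03_compare_fragmentation.py
...
Low fragmentation wins on mean He in 8/10 pairs
Low fragmentation wins on max Ns in 10/10 pairs
Mantel r (Dps vs resistance distance) negative in 20/20 scenarios
```

Across ten matched-PLAND seed pairs simulated under IBR (200 nodes, 10 runs ×
50 generations), the aggregated landscape retains higher expected
heterozygosity (mean He 0.801 vs 0.792) and supports far larger 20-km
neighborhood populations (mean of per-pair maximum Ns 195 vs 82): aggregated
habitat acts as a genetic refuge, and genetic similarity decays with
resistance distance everywhere (paired Mantel r ≈ −0.53 vs −0.47).

`analysis/02_run_factorial.py` runs the full 2×2×2 factorial (fragmentation ×
IBD/IBR × dispersal limit) and writes per-scenario node summaries, Mantel
tests and connectivity–diversity regressions under `results/experiment/`.
A `genescape` command-line interface exposes the individual stages
(`generate-landscape`, `metrics`, `distances`, `kernel`, `simulate`, `stats`,
`run-all`).

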