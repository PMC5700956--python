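# skyisland

Tools for asking a classic sky-island question about tropical stream
invertebrates: is it **elevation** — rather than which volcano or which
watershed a site sits on — that structures both *species composition of
communities* and *SNP variation within species*?

The package is written for community ecologists and population
geneticists working on elevation gradients. It bundles the full analysis
chain such a study needs, plus a synthetic-data generator with known
ground truth so every stage can be validated without field or RADseq
data:

* **Simulation** (`skyisland.simulate`) — volcano/watershed/stream/station
  landscapes; communities from a unimodal (Gaussian-in-elevation)
  occupancy niche model with negative-binomial abundances; biallelic SNP
  genotypes from a nested Balding–Nichols hierarchy with a known
  between-zone divergence F_RT and within-zone F_SR.
* **Dissimilarities** (`skyisland.distances`) — Bray–Curtis (= Sørensen on
  presence/absence), pairwise elevation differences, volcano/watershed
  membership matrices, planar or haversine geographic distance.
* **Ordination** (`skyisland.ordination`) — Kruskal NMDS (stress-1,
  isotonic regression with primary tie-breaking, SMACOF updates, multiple
  starts) and environmental vector fitting with permutation P values.
* **Permutation tests** (`skyisland.permtests`) — sequential-SS PERMANOVA
  on distance matrices (McArdle–Anderson), Mantel, partial Mantel, and the
  Mantel correlogram with progressive Holm correction.
* **Diversity** (`skyisland.diversity`) — additive per-site partition of
  species richness, γᵢ = αᵢ + βᵢ with Σγᵢ = total richness, and OLS
  regressions of each component on elevation.
* **Population genetics** (`skyisland.popgen`) — Smouse–Peakall squared
  genotype distances, hierarchical AMOVA (regions / populations /
  individuals) with permutational F_RT, F_SR, F_ST, pairwise FST, and
  isolation by distance on linearized FST, FST/(1−FST), vs ln(km + 1).
* **Cutoff detection** (`skyisland.cutoff`) — the two lowland/highland
  boundary sweeps: an ordination-based 50-m scan of binary
  above-threshold vectors (argmax envfit R², abundance tie-break) and an
  F_RT-maximizing scan over midpoints between population elevations with
  the "at least two populations per zone" fallback rule.
* **IO + CLI** (`skyisland.io`, `skyisland.cli`) — delimited-text readers
  and writers for all containers, GenAlEx-style codominant tables, VCF
  input, and a `skyisland` command with one subcommand per stage plus a
  combined `pipeline`.

## The statistics at the core

For a community matrix **X** (sites × species) the chain is: Bray–Curtis
dissimilarity d(x, y) = Σ|xₖ−yₖ| / Σ(xₖ+yₖ); PERMANOVA partitions the
Gower-centred matrix G = −½C(d∘d)C over model terms with pseudo-F tested
by permuting rows/columns of d; NMDS minimizes Kruskal stress-1
√(Σ(θ(dᵢⱼ)−δᵢⱼ)² / Σδᵢⱼ²); a threshold t on a 50-m grid is scored by the
envfit R² of the binary vector 1[elevationᵢ ≥ t] on the ordination.

For genotypes, the three-level AMOVA partitions allele-level squared
distances into σ²ₐ (among elevation zones / volcanoes / watersheds), σ²_b
(among populations within regions) and σ²_c (within populations), with

    F_RT = σ²ₐ / (σ²ₐ + σ²_b + σ²_c),   F_SR = σ²_b / (σ²_b + σ²_c),
    F_ST = (σ²ₐ + σ²_b) / (σ²ₐ + σ²_b + σ²_c),

and the genetic cutoff is the candidate midpoint between successive
population elevations that maximizes F_RT among splits keeping ≥ 2
populations per zone.

## Worked example

```python
from skyisland import SimulationConfig, run_pipeline
from skyisland.io import RunConfig
from skyisland.pipeline import summarize

sim = SimulationConfig(seed=4)          # 35 species, F_RT = 0.3, cutoff 850 m
run = RunConfig(seed=4, n_perm_manova=199, n_perm_mantel=199,
                n_perm_ibd=199, n_perm_amova=99, n_perm_envfit=99)
report = summarize(run_pipeline(sim, run))
for key in ("permanova_elevation_R2", "community_cutoff_m",
            "genetic_cutoff_m", "amova_elevation_F_RT",
            "amova_elevation_P", "diversity_beta_slope"):
    print(f"{key:28s} {report[key]:.4f}")
```

prints

```
permanova_elevation_R2       0.3674
community_cutoff_m           950.0000
genetic_cutoff_m             851.1290
amova_elevation_F_RT         0.2792
amova_elevation_P            0.0100
diversity_beta_slope         0.0003
```

Reading: elevation explains ~37 % of the community dissimilarity
(sequential PERMANOVA R²); for this draw the community sweep places the
boundary at 950 m and the genetic sweep at 851 m (the simulated truth is
850 m — both sweeps are noisy at 31 sites / 8 populations, which is
exactly what the recovery suites quantify); the elevation AMOVA F_RT is
0.28 (target 0.3) and significant while volcano and watershed are not;
and β diversity rises with elevation (highland communities are more
distinctive).

The same pipeline is available from the shell:

```sh
skyisland pipeline --seed 4 --out-dir results/
skyisland simulate --seed 4 --out-dir synthetic/
skyisland amova --sites synthetic/sites.csv --genotypes synthetic/genotypes.csv \
    --grouping elevation --cutoff 850 --out results/amova.csv
```

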