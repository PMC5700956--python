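# Methods

This note documents the models, estimators and numerical choices behind
`skyisland`, and what the synthetic-data suites do and do not demonstrate
about field data.

## The study design being emulated

The package targets a sky-island design: several isolated volcanoes, one
to two streams per watershed, sampling stations spanning the elevation
gradient, a sites × species community table, and SNP genotypes for
populations of a few widespread species. Two spatial hypotheses compete:
sites/populations could resemble each other because they share a volcano
or watershed (isolation in space), or because they share an elevation
belt (ecological zonation). All analyses are built to separate these.

Zone convention throughout: *lowland* strictly below a cutoff elevation,
*highland* at or exactly above it.

## Synthetic data

### Landscape

Volcano centres sit on a ring (default spacing 45 km, matching the tens
of kilometres that separate real volcano massifs); each watershed is a
sector with one or more streams; stations are spaced evenly over the
configured elevation range (defaults 45–1830 m), positioned nearer the
summit the higher they are. Coordinates are planar km — at desk scale no
geodesy is needed; real longitude/latitude tables instead go through the
haversine distance (mean Earth radius 6371 km). A 31-site "field design"
variant emulates the practical layout (16 streams sampled at lower/upper
sections, three unreachable upper sections replaced by two extra
stations).

### Community

Species *j* occupies site *i* with probability

    p_ij = p_max,j * exp(-0.5 ((e_i - opt_j) / breadth_j)^2),

a unimodal niche curve in elevation; conditional on presence, abundance
is 1 + NegBin(size, mean) so present species always have a positive
count. The dispersion default (size = 1, geometric-tailed counts) is a
free choice exposed in the config; nothing downstream depends on it
because the headline analyses use presence/absence.

Species come in two guilds with optima drawn uniformly below and above
the true cutoff. Three calibration targets shaped the preset defaults
(35 species, breadth U(250, 400) m, highland occupancy ceiling 0.55 of
the lowland 0.9, guild sizes weighted by band width / (breadth ×
occupancy)):

* roughly half the species pool occurs in both zones (mean shared
  fraction 0.47 over 100 seeds);
* per-site richness is flat in elevation (no significant Pearson
  correlation in 95/100 seeds) — turnover without a richness gradient;
* β diversity rises with elevation (positive regression slope in 100/100
  seeds), because highland species are patchier, i.e. each occupies fewer
  sites.

The patchiness mechanism is a modelling choice: lowering the occupancy
ceiling of highland species while enlarging their number keeps expected
richness flat but makes high-elevation communities more distinctive from
one another, which is the qualitative behaviour the design requires.

### Genotypes

Per locus: ancestral allele frequency p ~ U(0.1, 0.9); each elevation
zone draws its frequency from a Beta with mean p and variance
p(1−p)·F_RT (the Balding–Nichols "F-model"); populations nest inside
zones the same way with F_SR; individuals are Hardy–Weinberg binomial
draws. Frequencies that fix at 0 or 1 stay fixed. F_RT + F_SR ≥ 1 is
rejected. Defaults: 8 populations × 10 individuals, 500 loci,
F_RT = 0.3, F_SR = 0.05.

This hierarchy was chosen because the allele-level AMOVA F-statistics
have closed expectations under it — E[F_RT-hat] = F_RT independent of
F_SR — which is what makes honest parameter-recovery tests possible.

What the generator does **not** emulate: linkage, missing-data structure,
coverage/allele-dropout artefacts of RAD data, migration or
isolation-by-distance (pairwise FST between same-zone populations is flat
in geographic distance by construction), and read-level error. Passing
recovery suites therefore demonstrates estimator correctness under the
stated model, not robustness to RAD artefacts.

### Seeding

One root seed; each generator stage derives an independent stream keyed
by a CRC of the stage name, so adding a stage never perturbs the draws of
existing ones. All results are bit-reproducible for a fixed seed.

## Estimators

### Distance-based PERMANOVA

McArdle–Anderson: G = −½C(d∘d)C, sequential (Type I) sums of squares via
hat matrices of the accumulated design columns (categorical terms
treatment-coded, continuous terms as given), pseudo-F per term against
the residual, P by jointly permuting rows and columns of d. Term order is
the caller's, as in any Type I decomposition. Identical results to the
standard community-ecology implementation were verified on a fixture
(sums of squares and exhaustive-permutation P equal to 12 digits). A
numerically zero residual (perfect separation) yields an infinite F by
convention rather than a 0/0.

### Mantel family

r is the Pearson correlation of the n(n−1)/2 upper-triangle pairs; the
partial statistic is the first-order partial correlation r(AB·C);
significance permutes rows/columns of the first matrix only. The
alternative defaults to one-sided "greater" (the standard similarity
hypothesis); two-sided is a flag. P values use the add-one estimator
(1 + exceedances)/(1 + permutations) — never exactly zero — or exact
enumeration over all n! permutations when requested (used by the oracle
tests at n ≤ 6). Both r and r² are reported, since published "R²" values
for Mantel tests are ambiguous between the two.

### Mantel correlogram

Per distance class of the predictor, a Mantel test between the response
matrix and the 0/1 indicator "pair falls in this class". With this coding
a **negative** r means within-class pairs are more similar than average;
no sign flip is applied, and the interpretation is stated in the result.
Classes beyond the one that carries the cumulative 50 % of pairs are
reported but untested by default; corrected P values use the progressive
Holm procedure (class k corrected within classes 1..k). Default class
width 200 m, configurable — published applications rarely state theirs.

### NMDS and envfit

Kruskal stress-1 with primary tie-breaking: disparities are the isotonic
(PAVA) regression of configuration distances on dissimilarities, pairs
pre-sorted by (dissimilarity, distance) so tied dissimilarities impose no
order constraint. Configuration updates are SMACOF (Guttman transform).
One metric-scaling (PCoA) start plus random starts (default 20); within a
start, a step that would increase stress reverts and stops, so the stress
trace is non-increasing by construction; convergence is declared when the
two best solutions agree under Procrustes (correlation ≥ 0.99 by
default). The best solution is centred, rotated to principal axes, and
sign-fixed (largest-|score| entry of each axis positive), making reported
axes reproducible.

Vector fitting regresses the centred variable on the site scores;
R² = 1 − SS_res/SS_tot; the direction is the unit coefficient vector; P
permutes the variable across sites (add-one, or exact enumeration).

### Diversity partition

Richness-index contribution diversity: with m_j sites occupied by species
j and n sites, γᵢ = Σ_{j at i} 1/m_j, αᵢ = Sᵢ/n, βᵢ = γᵢ − αᵢ. Additivity
is exact and Σγᵢ equals total richness — both are property-tested on
every generated community. Values were verified against the reference
implementation in the community-ecology toolchain on a fixture.
Abundance-weighted variants are deliberately not implemented.

### AMOVA and FST

Sums of squares use the pairwise identity SS_group = Σ_pairs d²/N_group;
the three-level nesting (regions / populations within regions / within
populations) is solved for variance components through the
expected-mean-square linear system with unequal-sample-size coefficients,
in allele copies.

Two distance scales coexist deliberately. The Smouse–Peakall squared
**genotype** distance (AA–AB = 1, AB–CD = 2, AA–BC = 3, AA–BB = 4;
equivalently half the squared Euclidean distance between allele-count
vectors, summed over loci scored in both individuals) serves
individual-level ordinations and environmental fitting. The AMOVA and
pairwise FST instead partition **allele-copy** mismatches — the
codominant allele-frequency mode of the classical method — because the
genotype-level metric counts between-individual variation twice relative
to within-individual variation and would report F_RT ≈ 2F/(1+F) instead
of F under the generator; the allele-level statistics recover the
Balding–Nichols parameters exactly in expectation, and the recovery
suites confirm it empirically (±0.05 at F_RT ∈ {0.1, 0.3, 0.5}).

Permutation tests: F_RT permutes whole populations among regions; F_SR
permutes individuals among populations within regions; F_ST permutes
individuals among all populations. Populations of one individual are
discarded (logged) before analysis. Negative variance components are
reported raw in the table but truncated to zero for the F ratios by
default (a flag restores raw-component ratios); pairwise FST clamps
negatives to zero and lists the clamped pairs, keeping the downstream
ln-regression defined. With every population its own region the
among-populations level vanishes and the decomposition degrades cleanly
to two levels (σ²_b = 0).

Missing genotypes are handled per locus (a locus missing in an individual
simply contributes no allele copies there); degrees of freedom use
individual counts, which is exact for complete data and approximate under
missingness.

### Isolation by distance

FST is linearized as f/(1−f) (an FST of 1 is an error, not a clamp);
geographic distance in km is transformed as ln(d + 1) — the unit choice
affects the intercept, not the Mantel P. The Mantel test supplies r and
P; an OLS fit over the upper-triangle pairs supplies slope and intercept.

### Cutoff detection

*Community sweep*: one NMDS of the presence/absence Bray–Curtis matrix
serves every threshold of a 50-m grid (origin: minimum elevation rounded
up to the step, configurable); each threshold's binary at-or-above vector
is fitted onto the ordination and scored by R². Thresholds bounded by the
same pair of stations define the same split; the scan groups them and
reports the lowest grid value of the winning group. When two *distinct*
splits score within tie_tol = 0.01 in R² (the order of the near-tie seen
in practice), the scan is re-run on the abundance matrix and the tied
split with the higher abundance R² wins; the runner-up is reported as the
secondary threshold.

*Genetic sweep*: candidate thresholds are the medians between successive
distinct population elevations; each candidate is scored by the two-zone
AMOVA F_RT. Candidates leaving fewer than two populations in a zone are
inadmissible ("fell at one end"); if the global maximum is inadmissible
the best admissible value is selected and the rule is flagged.

Multiple-testing helper: Bonferroni α/m (α/3 for the three regional
factors, α/2 for the paired lowland/highland IBD tests).

## Problem sizes in the validation suites

Chosen as the smallest sizes at which the targeted properties are
statistically decidable: type-I calibration uses 1000 null replicates of
12 samples with 99 permutations each (the [0.03, 0.07] band is ±2.9
binomial SD around 0.05); AMOVA recovery uses 8 populations × 10
individuals × 500 loci × 20 seeds; the genetic sweep recovery uses 8
stations every 200 m; the community sweep recovery uses 48 sites (3
volcanoes × 16 stations every 100 m) and 60 narrow-niche species
(breadth U(100, 160) m, 150 m guild gap) — a boundary the community
actually expresses, since no estimator can recover a cutoff that leaves
no compositional signal. Exhaustive-permutation oracles run at n ≤ 6
(≤ 720 permutations).

## Known limitations

* PERMANOVA accepts sample-level predictors (factors and covariates),
  not predictor distance matrices; matrix-vs-matrix questions belong to
  the Mantel family.
* No restricted/stratified permutations.
* The AMOVA assumes Hardy–Weinberg within populations and does not report
  an inbreeding (within-individual) level.
* The correlogram's untested-beyond-half rule and class width follow the
  common default, both configurable; results near the rule boundary
  should be read qualitatively.
* The NMDS convergence flag compares the best two starts only; with very
  few starts a false "converged" is possible.
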