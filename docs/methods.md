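# Methods

This note documents the models, estimators, numerical choices and known
limitations of `achconnect`, in the order the pipeline runs them.

## Coastal domains and synthetic currents

Coordinates are decimal degrees on a spherical Earth (radius 6371 km);
local distances use the equirectangular approximation
(Δx = R cosφ Δλ, Δy = R Δφ), which is accurate to well under 1 % at the
sub-100-km scales where it matters (point spacing, capture radii).  The
seaward side of a land polygon is *declared* (a pair of exterior-ring
vertex indices), not inferred; source/sink points are placed by arc-length
resampling of that stretch with the actual spacing L/round(L/s), so the
spacing is exact and the point count equals boundary length / spacing.

Velocity fields are kinematic, not dynamical: per day,
u = jet + eddy + barrier + noise.  The eddy field derives from a
travelling streamfunction (u = A sin(kx − ωt) cos(ky),
v = −A cos(kx − ωt) sin(ky)), hence is divergence-free; barriers are
Gaussian cross-shore jets that also damp the alongshore jet locally,
creating the flow discontinuities that partition a coast into weakly
connected regions.  Noise is white per cell per day.  Land cells carry
exactly zero velocity, the recipe is a frozen named dataclass, and the
whole series is reproducible bit-for-bit from (domain, recipe, seed).
There is no geostrophy or bathymetry by design — the target is the
*statistical* structure (meanders, eddies, retention, barriers) that
shapes dispersal kernels, not oceanographic realism.

Defaults: grid spacing 0.08° (matching the resolution class of
eddy-resolving ocean products, ~6–9 km), point spacing 1 km, jet 0.2 m/s,
eddy amplitude 0.05 m/s with 60-km wavelength and 10-day period.

## Lagrangian stage

Hourly forward-Euler steps with bilinear spatial interpolation of the
current day's field; fields are piecewise-constant within a day.  Euler at
1-h steps is a deliberate choice: positions are defined by hourly updates,
and with |u| ≤ ~0.5 m/s an hourly step moves less than a grid cell, so a
higher-order integrator would change trajectories by less than the eddy
noise.  The uniform-field test pins the integration error: displacement
matches |v|·t to < 0.5 % over 30 days.

Settlement has three config-exposed rules, because beaching behaviour is
the genuinely underdetermined part of any such model:

* capture zone: a disc of radius r_c (default 2 km) around every coastal
  point, checked each hour after an optional pre-competency period
  (default 0 d);
* beaching: a track that enters the land polygon settles at the nearest
  coastal point (alternative: counts as lost); the inside-land position is
  never recorded, so tracks stay strictly in water;
* loss: leaving the grid, or exceeding the PLD (default 30 d).

Note the interaction of the first rule with its default: with
pre-competency 0 and r_c ≥ the distance moved per hour, a larva settles at
its own origin immediately (the zero-flow retention benchmark).  Runs that
are meant to show dispersal therefore set a positive pre-competency
(the scaled studies use 1.5 d).  Advection is fully deterministic; the
optional sub-grid random walk (km/√day) is the only seeded randomness.

## Connectivity, stepping stones, clusters

P(i→j) is the exact arrivals/releases ratio; lost particles contribute to
no destination, so row sums are ≤ 1 with the remainder the lost fraction.
Multi-year matrices are element-wise arithmetic means of annual matrices
(not pooled counts: years are weighted equally regardless of release
totals).

Stepping-stone connectivity maximises the product of single-step
probabilities over paths through *all* coastal points (sampled sites are
only query endpoints).  Equivalently it minimises Σ −ln P; natural log, a
pure convention since any base gives the same argmin.  Zero-probability
edges are treated as absent (infinite weight), never as a small epsilon —
epsilon choices would reorder paths.  Retention (the diagonal) is not a
stepping stone; the i→i entry reports direct retention only.  The
Floyd–Warshall scan updates only on strict improvement with intermediates
in ascending index order, so results are deterministic; among exactly
tied paths the first found (through the lowest-indexed intermediates)
is reported.  Equivalence with brute-force max-product enumeration is
tested to 1e−10 on hundreds of random graphs.

Clustering maximises weighted directed Newman modularity
Q = (1/m) Σ_{c_i=c_j} [w_ij − s_out(i)s_in(j)/m].  Self-loop *edge
weights* (retention) are excluded from w; the i = j null-model term is
kept, so the one-cluster partition scores exactly 0 and a uniform
complete graph never rewards splitting.  Up to 14 locations the search is
exhaustive over all set partitions (restricted-growth enumeration; a
numba-compiled scan takes over above 10 nodes), guaranteeing the global
optimum; larger sets fall back to greedy agglomerative merging, flagged
as `method="greedy"` in the result.

## Genetic estimators

* **h** — Nei's unbiased estimator n/(n−1)(1 − Σp²) with its sampling
  variance for the SD.
* **π** — mean pairwise *proportion* of differing sites over all C(n,2)
  pairs; no multiple-hit correction (none is assumed by the downstream
  contrasts); positions with N or '-' in either sequence are excluded for
  that pair (gaps are treated as missing, a documented choice).
* **Φ_PT** — two-population AMOVA on the matrix of pairwise difference
  *counts* used as squared distances: SS_total = Σ_{i<j} d²/N,
  SS_within = Σ_g Σ_{i<j∈g} d²/n_g, σ²_a = (MS_a − MS_w)/n0 with
  n0 = N − (n1² + n2²)/N, Φ = σ²_a/(σ²_a + MS_w).  Negative values are
  reported as computed.
* **F_ST** — the frequency-based H_T/H_S ratio form: per locus
  H_S = mean within-site expected heterozygosity, H_T from unweighted mean
  allele frequencies; H_S and H_T are averaged over loci *before* the
  ratio (Nei's convention), not per-locus ratios averaged.  A monomorphic
  pair (H_T = 0) reports 0.  A Weir–Cockerham θ estimator is a possible
  future addition; the ratio form matches the frequency-based outputs of
  the standard spreadsheet tools this workflow mirrors.
* **G″_ST** — k(H_T − H_S)/[(kH_T − H_S)(1 − H_S)] with k = 2 pairwise;
  undefined (NaN) when H_S = 1.  Always ≥ F_ST on polymorphic data, and
  exactly 1 when the pair shares no alleles with H_S < 1.
* **A_r** — mean distinct alleles per locus after standardising every site
  to a common sample size by dropping the individuals with the most
  missing genotypes (ties broken by input order); 95 % CIs are percentile
  intervals over 1000 bootstrap resamples of individuals within sites.
  Standardising by exclusion (rather than rarefaction) is what makes the
  bootstrap CI well-defined at a fixed n.
* **Permutation tests** — the diversity-difference test pools two sites,
  reallocates individuals to the original sizes and recomputes |Δh|,
  |Δπ|; p = (count ≥ observed + 1)/(iterations + 1), 1000 iterations by
  default for this test, 999 (+1) for the differentiation matrices.
  Individuals (not alleles) are shuffled in the differentiation
  permutations.  Bonferroni is min(1, m·p).
* **Bruvo's distance** — alleles in repeat units, d = 1 − 2^−|x−y|;
  diploid genotypes compared under minimum-weight pairing of the two
  alleles; a single missing allele is handled by the averaged genome
  addition/loss model (impute from the other genotype's alleles, and from
  the own remaining allele, average the two model distances); fully
  missing loci drop out of the per-pair mean.  The minimum spanning
  network is Kruskal's MST processed in classes of equal weight, keeping
  every tied edge that connected distinct components when its class began.

Missing microsatellite data use pairwise-available frequencies for all
heterozygosity statistics.

## Synthetic genetic data

The generator reproduces the *sampling design* of a two-lineage coastal
study (default: 2 edge + 2 centre western sites, 1 + 3 eastern plus one
more edge, 45 individuals per site, 500-bp sequences, 10 loci) without
coalescent machinery — frequency-draw models are exactly calibratable to
target diversities, which is what the centre-vs-edge contrasts actually
test.

Haplotypes: each lineage has a base sequence (lineages separated by 12
diagnostic substitutions by default) plus a star-like pool of 15 variants
carrying Poisson-distributed private mutations.  A site's dominant
haplotype frequency p solves p² + (1−p)²/(K−1) = 1 − h_target exactly, so
the expected sample h matches the target (tested to ±0.05); the dominant
variant rotates across sites so that sites differ compositionally, and a
migration parameter mixes each site's frequency vector with its
neighbours'.

Genotypes: per locus a lineage-level Dirichlet frequency vector over a
pool of 12 repeat-length alleles; each site mixes that shared vector
(weight = migration) with a private Dirichlet vector over a site-specific
sub-pool.  Individuals are two independent draws per locus, so
Hardy–Weinberg holds by construction (tested against 1 − Σp²).  Missing
data are injected uniformly at random at 2 %.

The switchable ACH effect multiplies edge sites' diversity target, allele
sub-pool size and migration rate by a common factor (default 0.5),
jointly producing the predicted pattern: lower edge h/π/A_r and elevated
edge divergence.  What the generator does *not* emulate: genealogical
correlation between loci, isolation-by-distance gradients within regions,
selection, null alleles and genotyping error.  Passing tests therefore
show the *statistics and decision logic* behave correctly under the
stated sampling models — not that any field system satisfies those
models.

## The verdict

For sequence statistics sites are grouped by lineage; allelic richness is
evaluated across all sites jointly (microsatellite lineages are rarely as
clean as mtDNA ones).  An edge site counts as "significantly lower" than
a centre site by the permutation-test p-value when one is supplied,
otherwise by CI non-overlap (point ± 1.96 SD when only an SD exists).
A statistic's verdict is *supported* iff (a) strictly more than half of
the edge sites are significantly lower than strictly more than half of
the centre sites, and (b) the mean differentiation of pairs involving an
edge site exceeds the mean of centre–centre pairs, read from the matching
matrix (Φ_PT for h/π, G″_ST or F_ST for A_r).  Without a usable
differentiation matrix or centre–centre pair the verdict is
*inconclusive*.  The scenario-level call is a strict majority of the
decisive per-group verdicts; under effect-free data the conjunction keeps
false support well below the nominal α (measured ≈ 0 over 100
replicates), and with the default effect (multiplier 0.5, n = 45,
10 loci) recovery is ≈ 98–100 %.

Clustering agreement between genetic groupings and connectivity clusters
is summarised by the adjusted Rand index (computed via scikit-learn,
cross-checked against the closed-form contingency formula), chosen
because it is chance-corrected and insensitive to label permutations.

## Scaled problem sizes

The desk-scale studies run a 300-km coast at 5-km point spacing (61
points), 12 release days × 2 years × 1 particle per point per day
(1464 particles), 30-day PLD, 2.5-km capture radius, 1.5-day
pre-competency and a 6 km/√day sub-grid walk; nine sampled locations
(three per flow region) feed the stepping-stone and modularity stages.
These sizes were chosen as the smallest at which the dispersal kernel
spans several point spacings and the three-region structure is stable
across seeds.  Genetic studies use the full default design (9 sites × 45
individuals).

## Known limitations

* The flow model cannot represent return circulations, so upstream
  connectivity exists only through eddies and the random walk.
* Φ_PT treats difference counts as squared distances (the convention of
  the standard AMOVA tools); substitution-model distances are out of
  scope.
* The exhaustive modularity scan is factorially expensive; beyond 14
  locations only the greedy merge is available, which does not guarantee
  the optimum (it is sanity-bounded against random partitions in tests).
* Permutation p-values are discrete; with very few distinct haplotypes
  the diversity-difference test is conservative.
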