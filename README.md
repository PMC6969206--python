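# achconnect

Tools for testing the genetic predictions of the **Abundant-Centre
Hypothesis (ACH)** in high-dispersal coastal species: the expectation that
range-edge populations are sparser, genetically less diverse
(lower haplotype diversity *h*, nucleotide diversity *π*, allelic richness
*A*r) and more divergent from one another (higher Φ_PT, F_ST, G″_ST) than
range-centre populations.  The package is aimed at marine population
geneticists who want to couple that test with an independent, physical
estimate of larval connectivity — and to rehearse the whole analysis on
fully synthetic data before touching field samples.

It chains two stages:

**Biophysical stage.**  A coastline polygon is resampled into source/sink
points at fixed along-shore spacing; daily surface-velocity fields (a
kinematic recipe: alongshore jet + divergence-free eddies + cross-shore
barrier jets + noise) drive hourly forward-Euler advection of passive
larvae with bilinear velocity interpolation, a maximum pelagic larval
duration (PLD, 30 d), capture-zone settlement and beaching.  Trajectories
aggregate into the connectivity matrix

P(i→j) = Σ(i→j) / Σ(i),

the probability that a larva released at point *i* settles at point *j*;
annual matrices are averaged.  Multi-generation "stepping-stone"
connectivity between sampled sites is the maximum product of single-step
probabilities over any path, found by Floyd–Warshall on edge weights
−ln P; sites are grouped by exhaustively maximising weighted directed
Newman modularity Q.

**Genetic stage.**  Nei's unbiased *h* (with sampling variance), *π* with
pairwise deletion, AMOVA-based pairwise Φ_PT, Nei-style
F_ST = (H_T − H_S)/H_T, Meirmans–Hedrick
G″_ST = k(H_T − H_S)/[(kH_T − H_S)(1 − H_S)], allelic richness at a
standardised sample size with bootstrap CIs, permutation tests for
diversity differences, Bonferroni correction, Bruvo's stepwise distance
(d = 1 − 2^−x in repeat units) with a minimum spanning network — plus a
seeded generator producing COI-like haplotype sets and microsatellite
tables with a switchable ACH effect.  `evaluate_ach` renders the verdict:
a statistic supports the ACH only when a majority of edge sites is
significantly lower *and* edge-involving pairs are more differentiated
than centre–centre pairs.

## Worked example

`examples/` holds one short script per capability.  The end-to-end
dispersal run (`python examples/07_full_pipeline.py`) prints:

```
year-1 release: 580 settled / 152 lost, mean drift 9.4 km in 0.24 d
connectivity matrix over 61 coastal points, max row sum 1.00
stepping stones improve 6/72 sampled pairs
modularity clusters (Q = 0.666, exhaustive):
   [3, 9, 15]
   [23, 29, 35]
   [43, 49, 55]
adjusted Rand index vs geographic regions: 1.00
```

A 300-km synthetic coast with two cross-shore flow discontinuities is
seeded with larvae at 61 coastal points; row sums ≤ 1 confirm that every
larva either settles somewhere or is lost.  The nine sampled locations
fall into exactly three modularity clusters that coincide (ARI = 1.0) with
the three flow-defined regions — the structural analogue of regional
genetic clusters matching oceanographic regions.  On the genetic side,
`python examples/06_ach_verdict.py` shows the verdict flipping from
`SUPPORTED` (every edge site significantly poorer, edge divergence
elevated) to `not supported` when the generator's ACH effect is switched
off.

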