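"""Synthetic mtDNA haplotype sets and microsatellite genotype tables.

The generator emulates the sampling design of a two-lineage coastal mussel
study: a string of sites, each labelled with a lineage (west/east) and an a
priori centre/edge category, ~45 individuals per site, COI-like sequences
and ~10 microsatellite loci.  No coalescent machinery is involved:
frequency-draw models are exactly calibratable to target diversities, which
is what the downstream centre-vs-edge contrasts test.

Haplotypes: each lineage has a base sequence (lineages separated by a fixed
number of diagnostic differences) and a star-like pool of mutated variants.
A site draws individuals from its lineage pool with a dominant-haplotype
frequency solved in closed form so that the population heterozygosity
1 − Σp² equals the site's target h; migration mixes the frequency vectors of
adjacent sites.

Genotypes: per locus, a lineage-level frequency vector over a pool of
repeat-length alleles (Dirichlet); each site mixes that shared vector with a
private Dirichlet vector restricted to a site-specific sub-pool, with the
mixing weight set by the migration rate.  Individuals are two independent
draws per locus (Hardy–Weinberg by construction) with missing data injected
uniformly at random.

The switchable ACH effect multiplies the target diversity (haplotypes), the
allele sub-pool size (genotypes) and the migration rate of *edge* sites by a
factor < 1, producing the reduced-diversity / elevated-divergence pattern
the Abundant-Centre Hypothesis predicts.  Everything is deterministic per
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .popgen import GenotypeTable, HaplotypeSet

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SiteSpec:
    code: str
    lineage: str  # e.g. 'west' | 'east'
    category: str  # 'centre' | 'edge'
    n: int = 45

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"site {self.code}: n must be >= 2")
        if self.category not in ("centre", "edge"):
            raise ValueError(f"site {self.code}: category must be centre|edge")


@dataclass(frozen=True)
class PopulationScenario:
    """Study design plus generator parameters.

    ``target_h`` is the population haplotype heterozygosity aimed for at
    centre sites; edge sites get ``target_h * ach_multiplier`` when
    ``ach_effect`` is on.  ``migration`` in [0, 1] is the weight pulling a
    site's frequencies toward its neighbourhood/lineage mean; edges get
    ``migration * ach_multiplier`` when the effect is on.
    """

    sites: tuple[SiteSpec, ...]
    seq_length: int = 500
    hap_pool_size: int = 15
    target_h: float = 0.85
    mutations_per_variant: float = 2.0
    lineage_divergence: int = 12
    microsat_loci: int = 10
    allele_pool: int = 12
    repeat_unit: int = 2
    allele_base: int = 100
    dirichlet_alpha: float = 0.8
    migration: float = 0.2
    missing_rate: float = 0.02
    ach_effect: bool = False
    ach_multiplier: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.ach_multiplier <= 1):
            raise ValueError("ach_multiplier must lie in (0, 1]")
        if not (0 <= self.migration <= 1):
            raise ValueError("migration must lie in [0, 1]")

    def site_target_h(self, site: SiteSpec) -> float:
        if self.ach_effect and site.category == "edge":
            return self.target_h * self.ach_multiplier
        return self.target_h

    def site_migration(self, site: SiteSpec) -> float:
        if self.ach_effect and site.category == "edge":
            return self.migration * self.ach_multiplier
        return self.migration

    def sites_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "code": s.code,
                    "lineage": s.lineage,
                    "category": s.category,
                    "n": s.n,
                }
                for s in self.sites
            ]
        )


def default_scenario(**overrides) -> PopulationScenario:
    """The reference two-lineage design: 2 edge + 2 centre sites in the west,
    1 edge + 3 centre sites in the east (mirrors a coastline whose lineage
    contact zone forms the shared range edge)."""
    sites = (
        SiteSpec("P1", "west", "edge"),
        SiteSpec("P2", "west", "edge"),
        SiteSpec("P3", "west", "centre"),
        SiteSpec("P4", "west", "centre"),
        SiteSpec("P5", "east", "edge"),
        SiteSpec("P6", "east", "edge"),
        SiteSpec("P7", "east", "centre"),
        SiteSpec("P8", "east", "centre"),
        SiteSpec("P9", "east", "centre"),
    )
    return replace(PopulationScenario(sites=sites), **overrides)


def _dominant_frequency(target_h: float, pool: int) -> float:
    """Frequency p of the dominant haplotype so that 1 − Σp² = target_h when
    the remaining mass is spread evenly over the other pool − 1 variants."""
    if pool < 1:
        raise ValueError("pool size must be >= 1")
    h_max = 1.0 - 1.0 / pool
    if target_h > h_max + 1e-12:
        raise ValueError(
            f"target h={target_h:.3f} unattainable with pool of {pool} "
            f"(max {h_max:.3f})"
        )
    if pool == 1:
        return 1.0
    s = 1.0 - target_h  # required sum of squared frequencies
    K = pool
    a = K / (K - 1)
    b = -2.0 / (K - 1)
    c = 1.0 / (K - 1) - s
    disc = max(b * b - 4 * a * c, 0.0)
    p = (-b + math.sqrt(disc)) / (2 * a)
    return min(max(p, 1.0 / K), 1.0)


def _mutate(seq: np.ndarray, positions: np.ndarray, rng) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        choices = BASES[BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def _haplotype_pools(sc: PopulationScenario, rng) -> dict[str, np.ndarray]:
    """Per lineage, a (pool, L) array: base haplotype + star-like variants."""
    lineages = list(dict.fromkeys(s.lineage for s in sc.sites))
    L = sc.seq_length
    base = rng.choice(BASES, L)
    pools = {}
    div_pos = rng.choice(L, size=min(sc.lineage_divergence, L), replace=False)
    for li, lineage in enumerate(lineages):
        lin_base = base if li == 0 else _mutate(base, div_pos, rng)
        pool = [lin_base]
        attempts = 0
        while len(pool) < sc.hap_pool_size and attempts < 50 * sc.hap_pool_size:
            attempts += 1
            k = 1 + rng.poisson(max(sc.mutations_per_variant - 1, 0.0))
            var = _mutate(lin_base, rng.choice(L, size=min(k, L), replace=False), rng)
            if not any(np.array_equal(var, p) for p in pool):
                pool.append(var)
        if len(pool) < sc.hap_pool_size:
            raise ValueError("could not build a unique haplotype pool; "
                             "increase seq_length or mutations_per_variant")
        pools[lineage] = np.array(pool)
    return pools


def simulate_haplotypes(
    sc: PopulationScenario, seed: int | None = None
) -> dict[str, HaplotypeSet]:
    """One HaplotypeSet per site, deterministic in (scenario, seed)."""
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    pools = _haplotype_pools(sc, rng)
    K = sc.hap_pool_size

    # raw per-site frequency vectors over the lineage pool: dominant variant
    # rotates with the site's position so sites differ compositionally
    raw: dict[str, np.ndarray] = {}
    for si, site in enumerate(sc.sites):
        p = _dominant_frequency(sc.site_target_h(site), K)
        freqs = np.full(K, (1.0 - p) / (K - 1) if K > 1 else 0.0)
        freqs[si % K] = p
        raw[site.code] = freqs

    out: dict[str, HaplotypeSet] = {}
    for si, site in enumerate(sc.sites):
        neighbours = [
            sc.sites[j]
            for j in (si - 1, si + 1)
            if 0 <= j < len(sc.sites) and sc.sites[j].lineage == site.lineage
        ]
        freqs = raw[site.code]
        if neighbours:
            m = 0.5 * sc.site_migration(site)
            nb = np.mean([raw[nb.code] for nb in neighbours], axis=0)
            freqs = (1.0 - m) * freqs + m * nb
        freqs = freqs / freqs.sum()
        draws = rng.choice(K, size=site.n, p=freqs)
        seqs = ["".join(pools[site.lineage][d]) for d in draws]
        out[site.code] = HaplotypeSet(
            site=site.code, sequences=seqs, lineages=[site.lineage] * site.n
        )
    return out


def simulate_genotypes(
    sc: PopulationScenario, seed: int | None = None
) -> GenotypeTable:
    """A GenotypeTable over all sites, Hardy–Weinberg within sites."""
    if sc.microsat_loci < 1:
        raise ValueError("need at least one locus")
    if sc.allele_pool < 1:
        raise ValueError("allele pool size must be >= 1")
    rng = np.random.default_rng(sc.seed + 1 if seed is None else seed)
    lineages = list(dict.fromkeys(s.lineage for s in sc.sites))
    A = sc.allele_pool
    allele_values = sc.allele_base + sc.repeat_unit * np.arange(A)

    # shared lineage-level frequencies per locus
    shared = {
        lineage: rng.dirichlet(np.full(A, 1.0), size=sc.microsat_loci)
        for lineage in lineages
    }

    site_freqs: dict[str, np.ndarray] = {}
    for si, site in enumerate(sc.sites):
        pool = A
        if sc.ach_effect and site.category == "edge":
            pool = max(1, int(round(A * sc.ach_multiplier)))
        start = si % max(A - pool + 1, 1)  # site-specific sub-pool slice
        private = np.zeros((sc.microsat_loci, A))
        private[:, start : start + pool] = rng.dirichlet(
            np.full(pool, sc.dirichlet_alpha), size=sc.microsat_loci
        )
        m = sc.site_migration(site)
        f = m * shared[site.lineage] + (1.0 - m) * private
        site_freqs[site.code] = f / f.sum(axis=1, keepdims=True)

    rows_sites = []
    geno = []
    for site in sc.sites:
        f = site_freqs[site.code]
        g = np.empty((site.n, sc.microsat_loci, 2), dtype=int)
        for l in range(sc.microsat_loci):
            g[:, l, :] = allele_values[
                rng.choice(A, size=(site.n, 2), p=f[l])
            ]
        if sc.missing_rate > 0:
            miss = rng.random((site.n, sc.microsat_loci)) < sc.missing_rate
            g[miss] = 0
        geno.append(g)
        rows_sites.extend([site.code] * site.n)

    return GenotypeTable(
        sites=np.array(rows_sites),
        loci=[f"L{l + 1}" for l in range(sc.microsat_loci)],
        alleles=np.vstack(geno),
        repeat_units=np.full(sc.microsat_loci, sc.repeat_unit),
    )
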