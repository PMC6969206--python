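"""Population-genetic diversity and differentiation statistics.

Implements the statistics used to compare centre and edge populations:

* Nei's unbiased haplotype diversity h = n/(n−1)·(1 − Σ p_k²) with its
  sampling variance, and nucleotide diversity π (mean pairwise proportion of
  differing sites, pairwise deletion of N/gap positions, no multiple-hit
  correction);
* pairwise Φ_PT from an AMOVA on the matrix of inter-haplotype difference
  counts, with permutation significance (individuals shuffled across the
  pair, +1 correction);
* pairwise F_ST in Nei's G_ST-style H_T/H_S form and the standardised
  G″_ST = k(H_T − H_S) / [(k·H_T − H_S)(1 − H_S)] for microsatellites, with
  H_S and H_T averaged over loci before forming ratios;
* allelic richness A_r at a standardised sample size (individuals with the
  most missing data excluded) with bootstrap confidence intervals;
* a permutation test for diversity differences |Δh| and |Δπ| between two
  sites, and Bonferroni correction;
* Bruvo's stepwise-mutation distance between diploid microsatellite
  genotypes (averaged addition/loss model for missing alleles) and a
  minimum spanning network.

Negative Φ_PT/F_ST values are reported as computed, not truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

VALID_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeSet:
    """Aligned mtDNA sequences sampled at one site.

    All sequences must have equal length over the alphabet {A,C,G,T,N,-};
    N and '-' are treated as missing at that position (pairwise deletion).
    """

    site: str
    sequences: list[str]
    lineages: list[str] | None = None

    def __post_init__(self):
        if len(self.sequences) == 0:
            raise ValueError(f"site {self.site}: no sequences")
        L = len(self.sequences[0])
        for s in self.sequences:
            if len(s) != L:
                raise ValueError(f"site {self.site}: unequal sequence lengths")
            if set(s) - set("ACGTN-"):
                raise ValueError(
                    f"site {self.site}: invalid characters {set(s) - set('ACGTN-')}"
                )
        if self.lineages is not None and len(self.lineages) != len(self.sequences):
            raise ValueError("lineages must match sequences")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def as_array(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n, self.length)


@dataclass
class GenotypeTable:
    """Diploid microsatellite genotypes (repeat-length integer alleles).

    ``alleles`` has shape (n_individuals, n_loci, 2) with 0 denoting missing
    data; ``repeat_units`` gives each locus's repeat motif length (>= 1),
    needed for Bruvo's distance.
    """

    sites: np.ndarray
    loci: list[str]
    alleles: np.ndarray
    repeat_units: np.ndarray

    def __post_init__(self):
        self.sites = np.asarray(self.sites)
        self.alleles = np.asarray(self.alleles, dtype=int)
        self.repeat_units = np.asarray(self.repeat_units, dtype=int)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, loci, 2)")
        if self.alleles.shape[1] != len(self.loci):
            raise ValueError("allele array does not match locus names")
        if len(self.repeat_units) != len(self.loci):
            raise ValueError("repeat_units must match loci")
        if np.any(self.repeat_units < 1):
            raise ValueError("repeat unit lengths must be >= 1")
        if np.any(self.alleles < 0):
            raise ValueError("alleles must be non-negative (0 = missing)")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def site_codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(str(s), None)
        return list(seen)

    def site_indices(self, code: str) -> np.ndarray:
        return np.flatnonzero(self.sites == code)

    def subset(self, indices) -> "GenotypeTable":
        idx = np.asarray(indices)
        return GenotypeTable(
            sites=self.sites[idx],
            loci=list(self.loci),
            alleles=self.alleles[idx],
            repeat_units=self.repeat_units.copy(),
        )


@dataclass
class DiversityEstimate:
    """Point estimate of a per-site diversity statistic with uncertainty."""

    site: str
    statistic: str  # 'h' | 'pi' | 'A_r'
    value: float
    sd: float | None = None
    ci: tuple[float, float] | None = None
    n: int = 0


@dataclass
class DiffMatrix:
    """Pairwise differentiation matrix with permutation p-values."""

    statistic: str  # 'PhiPT' | 'Fst' | 'G''st'
    ids: list[str]
    values: np.ndarray
    p_raw: np.ndarray | None = None
    p_adj: np.ndarray | None = None
    permutations: int = 0

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def pairs_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.ids)), 2):
            rows.append(
                {
                    "a": self.ids[i],
                    "b": self.ids[j],
                    "value": self.values[i, j],
                    "p_raw": None if self.p_raw is None else self.p_raw[i, j],
                    "p_adj": None if self.p_adj is None else self.p_adj[i, j],
                }
            )
        return pd.DataFrame(rows)

    def mean_over(self, pair_filter) -> float:
        vals = [
            self.values[i, j]
            for i, j in combinations(range(len(self.ids)), 2)
            if pair_filter(self.ids[i], self.ids[j])
        ]
        return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------


def _unique_codes(hs_list: list[HaplotypeSet]):
    """Pool sequences from several sites; return per-site integer codes and
    the unique-haplotype pairwise (difference count, comparable sites)."""
    arrs = [hs.as_array() for hs in hs_list]
    full = np.vstack(arrs)
    uniq, inverse = np.unique(full, axis=0, return_inverse=True)
    valid = np.isin(uniq, VALID_BASES)
    k = uniq.shape[0]
    diffs = np.zeros((k, k))
    comp = np.zeros((k, k))
    for i in range(k):
        both = valid[i] & valid
        ne = (uniq[i] != uniq) & both
        diffs[i] = ne.sum(axis=1)
        comp[i] = both.sum(axis=1)
    codes = []
    start = 0
    for hs in hs_list:
        codes.append(inverse[start : start + hs.n])
        start += hs.n
    return codes, diffs, comp


def _nei_h_from_counts(counts: np.ndarray, n: int) -> float:
    p = counts / n
    return n / (n - 1) * (1.0 - float((p**2).sum()))


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def haplotype_diversity(hs: HaplotypeSet) -> DiversityEstimate:
    """Nei's unbiased haplotype diversity with its sampling SD.

    h = n/(n−1)·(1 − Σ p_k²);
    V(h) = 2/(n(n−1)) · { 2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)² }.
    """
    n = hs.n
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    _, inverse = np.unique(hs.as_array(), axis=0, return_inverse=True)
    counts = np.bincount(inverse)
    p = counts / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return DiversityEstimate(
        site=hs.site, statistic="h", value=h, sd=float(np.sqrt(max(var, 0.0))), n=n
    )


def nucleotide_diversity(hs: HaplotypeSet) -> DiversityEstimate:
    """Mean pairwise proportion of differing sites over all C(n,2) pairs."""
    n = hs.n
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2")
    codes, diffs, comp = _unique_codes([hs])
    c = codes[0]
    total, pairs = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            if comp[c[i], c[j]] == 0:
                raise ValueError("a pair of sequences shares no comparable sites")
            total += diffs[c[i], c[j]] / comp[c[i], c[j]]
            pairs += 1
    return DiversityEstimate(site=hs.site, statistic="pi", value=total / pairs, n=n)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p) for each of the p-values."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# Phi_PT (AMOVA on inter-haplotype distances)
# ---------------------------------------------------------------------------


def _phi_from_d2(D2: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    """Two-population Φ from a squared-distance matrix and index groups."""
    n1, n2 = len(idx_a), len(idx_b)
    N = n1 + n2
    allidx = np.concatenate([idx_a, idx_b])
    sub = D2[np.ix_(allidx, allidx)]
    ss_total = sub.sum() / (2.0 * N)
    ss_w = (
        D2[np.ix_(idx_a, idx_a)].sum() / (2.0 * n1)
        + D2[np.ix_(idx_b, idx_b)].sum() / (2.0 * n2)
    )
    ss_a = ss_total - ss_w
    df_w = N - 2
    ms_w = ss_w / df_w
    n0 = (N - (n1**2 + n2**2) / N) / 1.0
    sigma_a = (ss_a / 1.0 - ms_w) / n0
    denom = sigma_a + ms_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def phi_pt(
    sets: list[HaplotypeSet], permutations: int = 999, seed: int | None = None
) -> DiffMatrix:
    """Pairwise Φ_PT between sites from an AMOVA on difference counts.

    The squared inter-individual distance is the number of differing
    nucleotide sites (pairwise deletion).  The permutation p-value is the
    fraction of relabellings (individuals shuffled across the two sites)
    with Φ at least the observed value, with +1 correction.  Sites with
    n < 2 are dropped with a warning.
    """
    keep = []
    for hs in sets:
        if hs.n < 2:
            warnings.warn(f"site {hs.site} dropped from PhiPT (n < 2)")
        else:
            keep.append(hs)
    if len(keep) < 2:
        raise ValueError("PhiPT needs at least two sites with n >= 2")

    codes, diffs, _ = _unique_codes(keep)
    rng = np.random.default_rng(seed)
    k = len(keep)
    ids = [hs.site for hs in keep]
    values = np.zeros((k, k))
    p_raw = np.ones((k, k))
    offsets = np.cumsum([0] + [hs.n for hs in keep])
    all_codes = np.concatenate(codes)
    D2 = diffs[np.ix_(all_codes, all_codes)]

    for i, j in combinations(range(k), 2):
        idx_a = np.arange(offsets[i], offsets[i + 1])
        idx_b = np.arange(offsets[j], offsets[j + 1])
        obs = _phi_from_d2(D2, idx_a, idx_b)
        values[i, j] = values[j, i] = obs
        if permutations > 0:
            pool = np.concatenate([idx_a, idx_b])
            n1 = len(idx_a)
            count = 0
            for _ in range(permutations):
                perm = rng.permutation(pool)
                if _phi_from_d2(D2, perm[:n1], perm[n1:]) >= obs - 1e-12:
                    count += 1
            p_raw[i, j] = p_raw[j, i] = (count + 1) / (permutations + 1)

    m = k * (k - 1) // 2
    p_adj = np.minimum(1.0, m * p_raw)
    np.fill_diagonal(p_raw, 1.0)
    np.fill_diagonal(p_adj, 1.0)
    return DiffMatrix(
        statistic="PhiPT",
        ids=ids,
        values=values,
        p_raw=p_raw if permutations > 0 else None,
        p_adj=p_adj if permutations > 0 else None,
        permutations=permutations,
    )


# ---------------------------------------------------------------------------
# microsatellite F_ST / G''_ST
# ---------------------------------------------------------------------------


def _locus_indicators(gt: GenotypeTable):
    """Per locus: (N, n_alleles) copy counts and (N,) valid-slot counts."""
    out = []
    for l in range(gt.n_loci):
        a = gt.alleles[:, l, :]
        alleles = np.unique(a[a > 0])
        M = np.zeros((gt.n, len(alleles)))
        for k, al in enumerate(alleles):
            M[:, k] = (a == al).sum(axis=1)
        out.append((M, (a > 0).sum(axis=1).astype(float)))
    return out


def _het_pair(indicators, idx_a, idx_b):
    """Mean-over-loci (H_S, H_T) for two index groups (pairwise-available)."""
    hs_vals, ht_vals = [], []
    for M, valid in indicators:
        ca = M[idx_a].sum(axis=0)
        cb = M[idx_b].sum(axis=0)
        ta, tb = valid[idx_a].sum(), valid[idx_b].sum()
        if ta == 0 or tb == 0 or M.shape[1] == 0:
            continue
        pa, pb = ca / ta, cb / tb
        h_a = 1.0 - float((pa**2).sum())
        h_b = 1.0 - float((pb**2).sum())
        pbar = 0.5 * (pa + pb)
        hs_vals.append(0.5 * (h_a + h_b))
        ht_vals.append(1.0 - float((pbar**2).sum()))
    if not hs_vals:
        raise ValueError("no usable loci for the pair")
    return float(np.mean(hs_vals)), float(np.mean(ht_vals))


def _fst_from_het(h_s: float, h_t: float) -> float:
    if h_t == 0:
        return 0.0  # monomorphic pair: no differentiation measurable
    return (h_t - h_s) / h_t


def _gppst_from_het(h_s: float, h_t: float, k: int = 2) -> float:
    if h_s >= 1.0:
        return float("nan")  # undefined when all individuals are heterozygous
    denom = (k * h_t - h_s) * (1.0 - h_s)
    if denom == 0:
        return 0.0
    return k * (h_t - h_s) / denom


def _pairwise_microsat(
    gt: GenotypeTable, stat_fn, name: str, permutations: int, seed
) -> DiffMatrix:
    sites = gt.site_codes()
    k = len(sites)
    if k < 2:
        raise ValueError("need at least two sites")
    indicators = _locus_indicators(gt)
    rng = np.random.default_rng(seed)
    values = np.zeros((k, k))
    p_raw = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        idx_a = gt.site_indices(sites[i])
        idx_b = gt.site_indices(sites[j])
        obs = stat_fn(*_het_pair(indicators, idx_a, idx_b))
        values[i, j] = values[j, i] = obs
        if permutations > 0 and np.isfinite(obs):
            pool = np.concatenate([idx_a, idx_b])
            n1 = len(idx_a)
            count = 0
            for _ in range(permutations):
                perm = rng.permutation(pool)
                val = stat_fn(*_het_pair(indicators, perm[:n1], perm[n1:]))
                if val >= obs - 1e-12:
                    count += 1
            p_raw[i, j] = p_raw[j, i] = (count + 1) / (permutations + 1)
    m = k * (k - 1) // 2
    p_adj = np.minimum(1.0, m * p_raw)
    np.fill_diagonal(p_raw, 1.0)
    np.fill_diagonal(p_adj, 1.0)
    return DiffMatrix(
        statistic=name,
        ids=sites,
        values=values,
        p_raw=p_raw if permutations > 0 else None,
        p_adj=p_adj if permutations > 0 else None,
        permutations=permutations,
    )


def fst_microsat(
    gt: GenotypeTable, permutations: int = 999, seed: int | None = None
) -> DiffMatrix:
    """Pairwise Nei-style F_ST = (H_T − H_S)/H_T with H averaged over loci.

    H_S is the mean within-site expected heterozygosity of the pair, H_T the
    expected heterozygosity of the unweighted mean allele frequencies.  A
    monomorphic pair (H_T = 0) is reported as 0.
    """
    return _pairwise_microsat(gt, _fst_from_het, "Fst", permutations, seed)


def g_double_prime_st(
    gt: GenotypeTable, permutations: int = 999, seed: int | None = None
) -> DiffMatrix:
    """Pairwise G″_ST = k(H_T − H_S)/[(kH_T − H_S)(1 − H_S)], k = 2.

    Standardised differentiation suited to highly polymorphic markers;
    undefined (NaN) when H_S = 1.
    """
    return _pairwise_microsat(gt, _gppst_from_het, "G''st", permutations, seed)


# ---------------------------------------------------------------------------
# allelic richness
# ---------------------------------------------------------------------------


def standardize_sample_size(gt: GenotypeTable, standard_n: int) -> GenotypeTable:
    """Reduce every site to ``standard_n`` individuals by dropping those with
    the most missing genotypes (ties broken by input order)."""
    keep: list[int] = []
    for code in gt.site_codes():
        idx = gt.site_indices(code)
        if len(idx) < standard_n:
            raise ValueError(
                f"site {code} has {len(idx)} individuals < standard_n={standard_n}"
            )
        missing = (gt.alleles[idx] == 0).sum(axis=(1, 2))
        order = np.argsort(missing, kind="stable")  # fewest missing first
        keep.extend(sorted(idx[order[:standard_n]]))
    return gt.subset(np.array(sorted(keep)))


def _richness(alleles: np.ndarray) -> float:
    """Mean over loci of the number of distinct non-missing alleles."""
    counts = []
    for l in range(alleles.shape[1]):
        a = alleles[:, l, :]
        counts.append(len(np.unique(a[a > 0])))
    return float(np.mean(counts))


def allelic_richness(
    gt: GenotypeTable,
    standard_n: int | None = None,
    bootstraps: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> list[DiversityEstimate]:
    """Per-site allelic richness at a standardised sample size with
    bootstrap percentile confidence intervals.

    ``standard_n`` defaults to the smallest site sample size.  The CI is the
    percentile interval of A_r over ``bootstraps`` resamples of individuals
    (with replacement) within each standardised site.
    """
    sizes = [len(gt.site_indices(c)) for c in gt.site_codes()]
    if standard_n is None:
        standard_n = min(sizes)
    if standard_n < 2:
        raise ValueError("standard_n must be >= 2")
    std = standardize_sample_size(gt, standard_n)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    out = []
    for code in std.site_codes():
        idx = std.site_indices(code)
        arr = std.alleles[idx]
        point = _richness(arr)
        ci = None
        if bootstraps > 0:
            # vectorised bootstrap: per locus, one-hot presence of each
            # allele per individual, resampled rows OR-ed together
            boots = rng.integers(0, len(idx), size=(bootstraps, len(idx)))
            stats = np.zeros(bootstraps)
            for l in range(arr.shape[1]):
                a = arr[:, l, :]
                alleles = np.unique(a[a > 0])
                if len(alleles) == 0:
                    continue
                present = (a[:, :, None] == alleles[None, None, :]).any(axis=1)
                stats += present[boots].any(axis=1).sum(axis=1)
            stats /= arr.shape[1]
            ci = (
                float(np.quantile(stats, alpha)),
                float(np.quantile(stats, 1.0 - alpha)),
            )
        out.append(
            DiversityEstimate(
                site=code, statistic="A_r", value=point, ci=ci, n=standard_n
            )
        )
    return out


# ---------------------------------------------------------------------------
# diversity-difference permutation test
# ---------------------------------------------------------------------------


def diversity_diff_test(
    a: HaplotypeSet,
    b: HaplotypeSet,
    iterations: int = 1000,
    seed: int | None = None,
) -> dict[str, float]:
    """Permutation p-values for |Δh| and |Δπ| between two sites.

    Individuals are pooled and randomly reallocated to the original sample
    sizes; p = (count of |Δ| at least observed + 1)/(iterations + 1).
    Bonferroni across pairs is left to the caller.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both sites need n >= 2")
    codes, diffs, comp = _unique_codes([a, b])
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(comp > 0, diffs / np.maximum(comp, 1), 0.0)
    ca, cb = codes
    K = diffs.shape[0]
    nA, nB = a.n, b.n
    N = nA + nB

    def stats_for(code_a, code_b):
        """(h_A, h_B, pi_A, pi_B) for batches of code rows."""
        code_a = np.atleast_2d(code_a)
        code_b = np.atleast_2d(code_b)
        R = code_a.shape[0]
        rows = np.repeat(np.arange(R), code_a.shape[1])
        cnt_a = np.zeros((R, K))
        np.add.at(cnt_a, (rows, code_a.ravel()), 1)
        rows_b = np.repeat(np.arange(R), code_b.shape[1])
        cnt_b = np.zeros((R, K))
        np.add.at(cnt_b, (rows_b, code_b.ravel()), 1)
        h_a = nA / (nA - 1) * (1 - ((cnt_a / nA) ** 2).sum(axis=1))
        h_b = nB / (nB - 1) * (1 - ((cnt_b / nB) ** 2).sum(axis=1))
        pi_a = ((cnt_a @ prop) * cnt_a).sum(axis=1) / 2.0 / (nA * (nA - 1) / 2.0)
        pi_b = ((cnt_b @ prop) * cnt_b).sum(axis=1) / 2.0 / (nB * (nB - 1) / 2.0)
        return h_a, h_b, pi_a, pi_b

    h_a, h_b, pi_a, pi_b = stats_for(ca, cb)
    obs_h = abs(float(h_a[0] - h_b[0]))
    obs_pi = abs(float(pi_a[0] - pi_b[0]))

    rng = np.random.default_rng(seed)
    pool = np.concatenate([ca, cb])
    perms = rng.permuted(np.tile(pool, (iterations, 1)), axis=1)
    h_pa, h_pb, pi_pa, pi_pb = stats_for(perms[:, :nA], perms[:, nA:])
    dh = np.abs(h_pa - h_pb)
    dpi = np.abs(pi_pa - pi_pb)
    p_h = (int((dh >= obs_h - 1e-12).sum()) + 1) / (iterations + 1)
    p_pi = (int((dpi >= obs_pi - 1e-12).sum()) + 1) / (iterations + 1)
    return {"h": p_h, "pi": p_pi, "obs_h": obs_h, "obs_pi": obs_pi}


# ---------------------------------------------------------------------------
# Bruvo's distance and minimum spanning network
# ---------------------------------------------------------------------------


def _bruvo_allele(x: float, y: float) -> float:
    return 1.0 - 2.0 ** (-abs(x - y))


def _bruvo_genotype(ga: np.ndarray, gb: np.ndarray, unit: int) -> float:
    """Bruvo distance between two diploid genotypes at one locus.

    Alleles are converted to repeat units; the two pairings of alleles are
    compared and the cheaper one taken.  A single missing allele is handled
    by the averaged addition/loss model: the missing slot is imputed with
    each allele of the other genotype (genome addition) and with the
    genotype's own remaining allele (genome loss), and the two model
    distances are averaged.  Returns NaN when either genotype is entirely
    missing.
    """
    a = [v / unit for v in ga if v > 0]
    b = [v / unit for v in gb if v > 0]
    if len(a) == 0 or len(b) == 0:
        return float("nan")

    def complete(a2, b2):
        d11 = _bruvo_allele(a2[0], b2[0])
        d22 = _bruvo_allele(a2[1], b2[1])
        d12 = _bruvo_allele(a2[0], b2[1])
        d21 = _bruvo_allele(a2[1], b2[0])
        return min((d11 + d22) / 2.0, (d12 + d21) / 2.0)

    if len(a) == 2 and len(b) == 2:
        return complete(a, b)

    def resolve(short, other):
        # addition: impute with each of the other genotype's alleles
        add = np.mean([complete(short + [x], other) for x in other])
        # loss: impute with the genotype's own remaining allele
        loss = complete(short + [short[0]], other)
        return 0.5 * (add + loss)

    if len(a) == 1 and len(b) == 2:
        return resolve(a, b)
    if len(b) == 1 and len(a) == 2:
        return resolve(b, a)
    return _bruvo_allele(a[0], b[0])  # both half-missing


def bruvo_distance(gt: GenotypeTable) -> np.ndarray:
    """Pairwise individual Bruvo distance, averaged over computable loci."""
    n = gt.n
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = [
                _bruvo_genotype(
                    gt.alleles[i, l], gt.alleles[j, l], int(gt.repeat_units[l])
                )
                for l in range(gt.n_loci)
            ]
            vals = [v for v in vals if not np.isnan(v)]
            D[i, j] = D[j, i] = float(np.mean(vals)) if vals else np.nan
    return D


def minimum_spanning_network(
    distances: np.ndarray, ids=None, tie_tol: float = 1e-9
) -> pd.DataFrame:
    """Minimum spanning network: an MST with tied-weight edges collapsed in.

    Kruskal's algorithm processed in classes of equal weight (within
    ``tie_tol``): every edge of a class that connects two components that
    were distinct when the class began is retained, so alternative
    equally-short links survive as network loops.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if ids is None:
        ids = np.arange(n)
    edges = [
        (D[i, j], i, j)
        for i, j in combinations(range(n), 2)
        if np.isfinite(D[i, j])
    ]
    edges.sort()
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rows = []
    k = 0
    while k < len(edges):
        w = edges[k][0]
        cls = []
        while k < len(edges) and edges[k][0] <= w + tie_tol:
            cls.append(edges[k])
            k += 1
        snapshot = [find(x) for x in range(n)]
        for wt, i, j in cls:
            if snapshot[i] != snapshot[j]:
                rows.append({"a": ids[i], "b": ids[j], "distance": wt})
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return pd.DataFrame(rows)
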