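"""Naive, independent reference implementations used to cross-check the
package's statistics.  Everything here is deliberately written as plain
double loops over pairs, dictionaries and exhaustive enumeration — slow but
transparently correct on small inputs."""

from itertools import combinations

import numpy as np

VALID = set("ACGT")


def naive_h(seqs):
    n = len(seqs)
    counts = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    ssq = sum((c / n) ** 2 for c in counts.values())
    return n / (n - 1) * (1 - ssq)


def naive_pair_diff(s1, s2):
    diff = comp = 0
    for a, b in zip(s1, s2):
        if a in VALID and b in VALID:
            comp += 1
            if a != b:
                diff += 1
    return diff, comp


def naive_pi(seqs):
    n = len(seqs)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            d, c = naive_pair_diff(seqs[i], seqs[j])
            total += d / c
            pairs += 1
    return total / pairs


def naive_phi_pt(seqs_a, seqs_b):
    """Two-population AMOVA Phi from squared distances = difference counts."""
    seqs = list(seqs_a) + list(seqs_b)
    n1, n2 = len(seqs_a), len(seqs_b)
    N = n1 + n2
    d2 = [[naive_pair_diff(x, y)[0] for y in seqs] for x in seqs]
    ss_total = sum(d2[i][j] for i in range(N) for j in range(i + 1, N)) / N
    ss_w = (
        sum(d2[i][j] for i in range(n1) for j in range(i + 1, n1)) / n1
        + sum(d2[i][j] for i in range(n1, N) for j in range(i + 1, N)) / n2
    )
    ss_a = ss_total - ss_w
    ms_w = ss_w / (N - 2)
    n0 = N - (n1 * n1 + n2 * n2) / N
    sigma_a = (ss_a - ms_w) / n0
    denom = sigma_a + ms_w
    return 0.0 if denom == 0 else sigma_a / denom


def _freqs(genos, locus):
    """Allele frequency dict for one locus of a list of (a1, a2) genotype
    tuples per individual (0 = missing)."""
    counts = {}
    tot = 0
    for g in genos:
        for a in g[locus]:
            if a > 0:
                counts[a] = counts.get(a, 0) + 1
                tot += 1
    return {a: c / tot for a, c in counts.items()} if tot else {}


def naive_het_stats(genos_a, genos_b, n_loci):
    hs_list, ht_list = [], []
    for l in range(n_loci):
        pa, pb = _freqs(genos_a, l), _freqs(genos_b, l)
        if not pa or not pb:
            continue
        ha = 1 - sum(p * p for p in pa.values())
        hb = 1 - sum(p * p for p in pb.values())
        alleles = set(pa) | set(pb)
        ht = 1 - sum(
            ((pa.get(a, 0) + pb.get(a, 0)) / 2) ** 2 for a in alleles
        )
        hs_list.append((ha + hb) / 2)
        ht_list.append(ht)
    return sum(hs_list) / len(hs_list), sum(ht_list) / len(ht_list)


def naive_fst(genos_a, genos_b, n_loci):
    hs, ht = naive_het_stats(genos_a, genos_b, n_loci)
    return 0.0 if ht == 0 else (ht - hs) / ht


def naive_gppst(genos_a, genos_b, n_loci, k=2):
    hs, ht = naive_het_stats(genos_a, genos_b, n_loci)
    if hs >= 1:
        return float("nan")
    denom = (k * ht - hs) * (1 - hs)
    return 0.0 if denom == 0 else k * (ht - hs) / denom


def naive_ar(genos, n_loci):
    counts = []
    for l in range(n_loci):
        alleles = {a for g in genos for a in g[l] if a > 0}
        counts.append(len(alleles))
    return sum(counts) / n_loci


def naive_bruvo(g1, g2, units):
    """Mean Bruvo distance over loci for two complete diploid genotypes."""
    dist = lambda x, y: 1 - 2 ** (-abs(x - y))
    vals = []
    for l, u in enumerate(units):
        a = [v / u for v in g1[l]]
        b = [v / u for v in g2[l]]
        p1 = (dist(a[0], b[0]) + dist(a[1], b[1])) / 2
        p2 = (dist(a[0], b[1]) + dist(a[1], b[0])) / 2
        vals.append(min(p1, p2))
    return sum(vals) / len(vals)


def brute_max_product(P, src, dst):
    """Maximum product of edge probabilities over all simple src→dst paths."""
    n = P.shape[0]
    best = 0.0
    stack = [(src, 1.0, {src})]
    while stack:
        node, prob, seen = stack.pop()
        for nxt in range(n):
            if nxt in seen or P[node, nxt] <= 0:
                continue
            p = prob * P[node, nxt]
            if nxt == dst:
                best = max(best, p)
            else:
                stack.append((nxt, p, seen | {nxt}))
    return best


def all_partitions(items):
    """Every set partition of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield [[first]] + part


def naive_modularity(W, labels):
    """Directed weighted Newman Q, self-loop edges removed, by double loop."""
    n = len(labels)
    W = np.asarray(W, dtype=float).copy()
    for i in range(n):
        W[i, i] = 0.0
    m = W.sum()
    s_out = W.sum(axis=1)
    s_in = W.sum(axis=0)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += (W[i, j] - s_out[i] * s_in[j] / m) / m
    return q


def brute_best_partition(W):
    n = W.shape[0]
    best_q, best = -np.inf, None
    for part in all_partitions(list(range(n))):
        labels = [0] * n
        for c, block in enumerate(part):
            for i in block:
                labels[i] = c
        q = naive_modularity(W, labels)
        if q > best_q:
            best_q, best = q, labels
    return best, best_q


def naive_ari(a, b):
    """Adjusted Rand index from the contingency-table formula."""
    from math import comb

    la, lb = sorted(set(a)), sorted(set(b))
    table = [[sum(1 for x, y in zip(a, b) if x == u and y == v) for v in lb] for u in la]
    n = len(a)
    sum_ij = sum(comb(table[i][j], 2) for i in range(len(la)) for j in range(len(lb)))
    sum_a = sum(comb(sum(row), 2) for row in table)
    sum_b = sum(comb(sum(table[i][j] for i in range(len(la))), 2) for j in range(len(lb)))
    expected = sum_a * sum_b / comb(n, 2)
    maxi = (sum_a + sum_b) / 2
    if maxi == expected:
        return 0.0
    return (sum_ij - expected) / (maxi - expected)
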