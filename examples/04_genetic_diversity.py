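"""Per-site genetic diversity and permutation tests on synthetic mtDNA data.

A two-lineage scenario with the ACH effect switched on: edge sites are
generated with half the centre diversity target.  Haplotype diversity (h)
and nucleotide diversity (pi) per site, then a permutation test for the
difference between one edge and one centre site.
"""

from achconnect import (
    bonferroni,
    default_scenario,
    diversity_diff_test,
    haplotype_diversity,
    nucleotide_diversity,
    simulate_haplotypes,
)

sc = default_scenario(ach_effect=True, ach_multiplier=0.5)
haps = simulate_haplotypes(sc, seed=2)
cats = {s.code: s.category for s in sc.sites}

print(f"{'site':>4} {'cat':>7} {'n':>3} {'h':>6} {'pi':>8}")
for code, hs in haps.items():
    h = haplotype_diversity(hs)
    pi = nucleotide_diversity(hs)
    print(f"{code:>4} {cats[code]:>7} {hs.n:>3} {h.value:6.3f} {pi.value:8.5f}")

res = diversity_diff_test(haps["P1"], haps["P3"], iterations=1000, seed=2)
p_adj = bonferroni([res["h"]], m=16)[0]
print(f"\nP1 (edge) vs P3 (centre): |dh| = {res['obs_h']:.3f}, "
      f"p = {res['h']:.4g} (Bonferroni x16: {p_adj:.4g})")
# Edge sites show clearly lower h; the permutation test pools the two
# samples, reshuffles 1000 times, and the observed gap is never matched.
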