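"""Contingency statistics for gene-set and protein-domain questions.

Reproduces two worked one-sided Fisher tests on a 487-affected vs
22,482-background gene split: a domain whose only two carriers are both
affected (infinite fold enrichment), and a domain with 2 of 6 carriers
affected. Also shows Benjamini-Hochberg adjustment and the
subset-vs-complement chi-square comparison of high-impact rates.
"""

from svatlas.enrichment import (
    bh_adjust,
    fisher_domain_enrichment,
    subset_proportion_test,
)

affected = {f"a{i}" for i in range(487)}
background = {f"b{i}" for i in range(22_482)}
domain_map = {
    "receptor_domain": {"a0", "a1"},                      # K = k = 2
    "protease_inhibitor_domain": {"a0", "a1", "b0", "b1", "b2", "b3"},  # K=6, k=2
}
rows = fisher_domain_enrichment(affected, background, domain_map)
for r in sorted(rows, key=lambda r: r.p):
    fold = "inf" if r.fold == float("inf") else f"{r.fold:.1f}"
    print(f"{r.term:<28} k={r.k} K={r.K}  p={r.p:.3g}  "
          f"p_adj={r.p_adj:.3g}  fold={fold}")
print("A domain whose every carrier is affected has infinite fold "
      "enrichment; p is the upper hypergeometric tail P(X >= k).\n")

print("BH step-up on p = {0.01, 0.02, 0.03}:",
      [round(float(x), 4) for x in bh_adjust([0.01, 0.02, 0.03])])

test = subset_proportion_test(17, 366, 494, 21_428)
print(f"\nHigh-impact rate in a 366-SV subset: {100 * test.prop_subset:.1f}% "
      f"vs {100 * test.prop_all:.2f}% overall; "
      f"chi-square = {test.statistic:.2f}, p = {test.p:.4f}")
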