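"""Subfamily age and element length effects on PQS abundance.

On the demo genome, older (more diverged) SVA-like subfamilies retain fewer
planted PQS, giving a positive age trend (Kendall tau of age rank vs PQS per
element, permutation-tested); full-length L1-like copies carry more PQS than
5'-truncated ones because truncation removes the 5' planted segment.
"""

from tequadscan.cohort import SVA_AGE, age_trend, element_table, length_activity_contrast, percent_with_pqs
from tequadscan.context import assign_zones
from tequadscan.scanner import scan_genome
from tequadscan.simulate import demo_spec, make_genome

genome, annotations, _ = make_genome(demo_spec(seed=7))
hits = scan_genome(genome)
assignments = assign_zones(hits, annotations, flank=200)
elements = element_table(annotations, assignments)

print("Percent of elements containing >=1 inside PQS, by family:")
print(percent_with_pqs(elements, ("family",))[
    ["family", "n_elements", "pct_elements_with_pqs", "pqs_per_element"]
].to_string(index=False))

table, trend = age_trend(elements, SVA_AGE, n_permutations=999, seed=7)
print("\nSVA-like subfamilies, oldest (A) to youngest (F):")
print(table[["age_group", "n_elements", "pqs_per_element"]].to_string(index=False))
print(f"age trend: tau={trend['tau']:.2f}, one-sided permutation p={trend['p_value']:.4f}")

l1, ratios = length_activity_contrast(elements)
sel = l1[(l1.group == "all") & (l1.chrom_class == "all")]
print("\nL1-like length classes:")
print(sel[["length_class", "n_elements", "pqs_per_element"]].to_string(index=False))
print(f"full-length vs truncated ratio: {ratios['full_vs_truncated']:.2f}")
print(f"active (L1HS/L1PA2) full-length vs all full-length: {ratios['active_full_vs_full']:.2f}")
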