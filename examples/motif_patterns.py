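"""Most common PQS motif patterns per family.

Groups the inside-assigned PQS of the demo genome by canonical run/loop
signature (runs capped at 5+, loops bucketed short/long) and prints the top
patterns with their representative sequences — the step that surfaces
candidate oligos for conformational work.
"""

from tequadscan.context import assign_zones
from tequadscan.motifs import cluster_and_rank
from tequadscan.scanner import scan_genome
from tequadscan.simulate import demo_spec, make_genome

genome, annotations, _ = make_genome(demo_spec(seed=7))
hits = scan_genome(genome)
assignments = assign_zones(hits, annotations, flank=200)

by_family: dict[str, list] = {}
seen = set()
for za in assignments:
    if za.zone != "inside" or za.family_key is None:
        continue
    key = (za.hit.chrom, za.hit.start, za.hit.end, za.hit.strand_label)
    if (za.family_key, key) not in seen:
        seen.add((za.family_key, key))
        by_family.setdefault(za.family_key, []).append(za.hit)

for family in ("L1", "SVA", "Alu"):
    clusters = cluster_and_rank(by_family.get(family, []), family)[:3]
    print(f"\n{family}: top {len(clusters)} motif patterns "
          f"({sum(c.count for c in cluster_and_rank(by_family.get(family, []), family))} hits)")
    for c in clusters:
        rep = c.representative if len(c.representative) <= 40 else c.representative[:37] + "..."
        print(f"  {c.count:>4}x  {c.signature_key:<28} {rep}")

print("\nSignature keys read run/loop-bucket per unit (e.g. '4/1-3' = 4-G run,")
print("short loop); identical architectures group regardless of loop bases.")
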