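"""Scan the bundled oligonucleotide set for PQS clusters.

Each of the twelve oligos carries a sense-strand cluster of >=4 G-runs with
1-7 nt loops; the printed signature is the run/loop architecture the scanner
parsed (e.g. "4-4,3-4,3-3,3" = a 4-G run, 4 nt loop, then 3-G runs).  Note
that three oligos contain only three literal GGG tracts: their fourth run is
carved out of a longer tract because loops may contain G.
"""

from tequadscan import scan_plus
from tequadscan.simulate import table1_fixture

for rec in table1_fixture():
    hits = scan_plus(rec.seq, source_id=rec.record_id)
    sig = hits[0].signature_str() if hits else "-"
    span = f"[{hits[0].start},{hits[0].end})" if hits else ""
    print(f"{rec.record_id:<12} len={len(rec.seq):>2}  PQS3+={len(hits)}  {span:>8}  {sig}")

print("\nEvery oligo has >=1 sense-strand PQS; span is the cluster interval,")
print("signature lists run-loop lengths (final run stands alone).")
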