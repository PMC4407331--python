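"""Expected PQS density under the window-local Markov null.

A G-rich tandem repeat region holds far more PQS than random sequence of
the same local composition: the null (order-2 chain fitted in 150 bp
windows) preserves GC and trinucleotide content but scatters the G-runs,
so the observed density should clear the null's 97.5th percentile.  A
GC-matched random control should not.
"""

import numpy as np

from tequadscan import expected_pqs_density
from tequadscan.simulate import _SVA_VNTR_UNIT  # the VNTR-like repeat unit

rng = np.random.default_rng(0)

# a VNTR-like region: 30 tandem copies of a 36 bp G-rich unit
vntr = _SVA_VNTR_UNIT * 30
# control: random sequence with the same GC content
gc = sum(c in "GC" for c in vntr) / len(vntr)
p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
control = "".join(np.array(list("ACGT"))[rng.choice(4, size=len(vntr), p=p)])

for name, seq in [("VNTR-like repeat", vntr), ("GC-matched random", control)]:
    est = expected_pqs_density(seq, n_replicates=100, seed=42)
    exceeds = est.observed_pqs_per_kb > est.ci_high
    print(
        f"{name:<18} observed={est.observed_pqs_per_kb:6.2f}/kb  "
        f"null={est.expected_pqs_per_kb:5.2f}/kb  "
        f"95% CI=[{est.ci_low:.2f},{est.ci_high:.2f}]  "
        f"{'EXCEEDS null' if exceeds else 'within null'}"
    )

print("\nThe repeat's PQS density is real sequence structure, not GC content:")
print("only the tandem-repeat region exceeds the randomized baseline.")
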