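# Methods

## PQS detection

A potential quadruplex sequence (PQS) is modelled as a chain of guanine
runs and loops: at least `min_runs` runs (default 4) of at least `min_run`
consecutive G (default 3), separated by loops of `loop_min`–`loop_max` nt
(defaults 1–7). Both strands are scanned; minus-strand hits (`PQS3-`) are
detected on the reverse complement and reported in plus-strand coordinates,
with the run/loop signature describing the reverse-complement strand.

**Cluster semantics.** The pattern admits overlapping placements, so
"one hit" needs a deterministic definition. A cluster is *leftmost-maximal*:
scanning left to right, it is anchored at the earliest position where any
valid chain can start, its end is the maximal end over all valid chains
starting at that anchor (additional loop+run units are appended while
possible), and scanning resumes at the cluster end — so clusters on one
strand are pairwise disjoint. The production scanner computes maximal chain
ends with a right-to-left dynamic program over run-start positions; a
separate exhaustive enumeration (`brute_force_oracle`, inputs ≤1000 bp)
implements the same definition by listing every chain placement and is used
in tests to verify the scanner exactly.

**Loops and N.** Loops may contain G (default), so a single long G tract
can be carved into run–loop–run; this is not an edge case but a necessity —
several naturally occurring PQS (e.g. three of the twelve bundled
oligonucleotides) contain only three literal GGG tracts and satisfy the
four-run pattern only through such carving. `allow_g_loops=False`
(`--strict-loops`) disables it for sensitivity analysis. N never counts
toward a run; N in loops is tolerated by default (masked-genome input) and
switchable. Soft-masked lower-case input is upper-cased before scanning.

**Signature parse.** Within a fixed cluster span, the reported run/loop
signature is the regex-greedy parse: each run consumes maximally, then each
loop consumes maximally, both constrained so the parse can still complete
at the cluster end with enough runs (backtracking only to rescue the
match). This makes `n_runs` and the signature deterministic.

## Markov null

The expected PQS frequency of a region is estimated from randomized
sequence generated by a Markov chain of order 2 fitted in consecutive
150 bp windows of the observed sequence (window-local models; contexts
never span window boundaries; a final fragment shorter than order+1 is
merged into the preceding window so total length is conserved). Counts are
smoothed with a pseudocount of 1/4 per transition so sparse windows define
a proper chain; slices containing N contribute nothing. Per replicate,
every window is replaced by a same-length sample from its own chain (the
initial context drawn from observed context frequencies) and the
concatenation is scanned on both strands. The estimate reports the mean
density per kb over `n_replicates` (default 100) with 2.5/97.5 percentile
bounds. Randomness is split deterministically: replicate r, window w uses
`default_rng([seed, r, w])`, so evaluation order cannot change results.

## TE context

Hits are related to repeat annotations with 200 bp flanks (the window used
when repeats are exported with flanking sequence). A hit is **inside** an
element only if at least one of its ends lies within the element proper;
otherwise it is **upstream**/**downstream** if it intersects the respective
flank window, with directions relative to the element's own strand
(upstream = 5'). A hit near two elements is assigned once per (hit,
element) pair; a hit spanning a whole element without an end inside goes to
the flank with the larger overlap (ties 5'). Zone densities are
`100 × count / zone bp` per family × hit-strand × length-class stratum;
flank bp truncated at chromosome ends are excluded from denominators.

**Full length** means element length ≥ two thirds of a typical
representative: L1 4700, Alu 250, SVA 1600, HERV LTR 300, HERV internal
2000 bp. The comparison is inclusive (≥) — the boundary convention is
documented here because the thresholds are stated as minima. HERV rows are
split LTR vs internal by the RepeatMasker `-int` rep_name suffix
(remappable); annotations resolving to no rule are excluded from
full-length analyses (lenient mode) or raise (strict mode).

## Consensus profiles

Inside hits are projected by cluster midpoint into family consensus
coordinates: linear interpolation within the annotation's
`repStart/repEnd` consensus interval when present, otherwise linear
scaling of the element-relative position to a configured consensus length.
Copies on the genome minus strand are reflected so position 0 is always
the element 5' end, and hit strand labels are flipped so `PQS3+` always
means element-sense. The midpoint anchor is robust to cluster length; the
projection is order-preserving within an element. Profiles count projected
midpoints in sliding windows; the window defaults to consensus_length/50
clamped to 40–120 bp with stride window/2 (stride = window gives the tiled
variant whose counts sum exactly to the hit total). Strata are strand ×
chromosome class (autosome/X/Y, a pure function of chromosome name). Each
profile can carry a Markov-null expectation and a dataset-wide reference
density (hits per bp × window × contributing elements) per window.

## Cohort summaries

Element-level abundance uses inside hits only; counts are element-sense
(labels flipped for minus-strand copies). "Abundance" is PQS per element,
with a per-kb variant emitted alongside, since either normalization is
defensible. The subfamily age trend is summarized by Kendall's tau between
age rank (SVA A→F oldest→youngest; AluJ/S/Y) and per-subfamily abundance,
with a one-sided permutation p-value obtained by shuffling subfamily
labels across elements (default 999 permutations, seeded). The trend test
is an extension of this package — the output metadata marks it as such —
chosen because it gives the age effect an assertable statistical surface.
The length/activity contrast reports all / full-length / truncated strata
and the transpositionally active set (L1HS, L1PA2) with ratio summaries.

## Motif clustering

Hits are grouped by canonical signature key: run lengths capped at "5+",
loop lengths bucketed 1–3 vs 4–7, e.g. `4/1-3,4/1-3,4/1-3,3`. Grouping is
exact on the key, so clustering is a partition and invariant to input
order; clusters rank by count (ties: key). Each cluster exports its most
frequent exact sequence as representative (ties: lexicographically
smallest) and per-loop majority strings. A comparison mode clusters by
ungapped full-sequence identity ≥80% (greedy centroid).

## Synthetic genomes

The generator emulates the statistical structure the pipeline targets, at
desk scale (defaults: 2 Mb over chr1/chr2/chrX/chrY, GC 0.41, ~350 copies,
minimum 500 bp between insertions). Four family archetypes carry planted
PQS segments at fixed consensus positions:

| family (consensus) | planted segments | subfamily series (divergence) |
|---|---|---|
| L1-like (6000 bp) | 5'-UTR one sense PQS (100–220); 3'-terminal four sense PQS (5640–6000) | L1HS .004, L1PA2 .010, L1PA7 .050, L1MA4 .120 |
| SVA-like (2000 bp) | 5' CCCTCT hexamer, antisense PQS (0–180); central VNTR, sense PQS (700–1060) | SVA_A .13 → SVA_F .008 |
| Alu-like (300 bp) | sense PQS near the 5' end (35–75) | AluJb .13, AluSx .09, AluY .03, AluYa5 .01 |
| HERV-like (LTR 400 / internal 3000 bp) | LTR sense PQS; internal antisense PQS | one subfamily, .08 |

The non-segment consensus is kept PQS-free on both strands (accidental
matches are overwritten with A/T) so planted segments are the only
consensus PQS sources. Copies are 5'-truncated with per-family
probabilities (keeping a uniform consensus-suffix fraction; annotations
carry the matching consensus coordinates), mutated by i.i.d. substitutions
at the subfamily divergence rate (uniform over alternative bases — older
subfamilies therefore lose more planted PQS), strand-assigned at random,
and inserted without overlap. Copy numbers (L1 120, Alu 120, SVA 90, HERV
24) follow the realistic family ranking and give adequate per-stratum
sample sizes.

The **truth table** re-scans each mutated copy and lists every surviving
PQS with genome coordinates, genome-strand label and the planted segment
containing its midpoint (`background` otherwise). Hits within
loop_max+1 bp of a copy boundary are flagged `edge`: cluster maximality
lets genomic context extend such clusters, so their exact coordinates are
context-dependent — recall is therefore checked exactly for interior hits
and by same-strand overlap for edge hits.

**What the generator does not model:** indels, nested insertions,
transduction, CpG-biased mutation, GC isochores, fragment joining across
annotation rows. Passing the planted-truth tests shows the pipeline
recovers positional, zone, age and length structure under these
assumptions; it does not calibrate absolute genome-wide counts, which
depend on assembly and annotation versions and on the repeat landscape of
real genomes.

## Numerical and procedural choices

- Coordinates are 0-based half-open everywhere internally; BED out,
  rmsk in as documented; 1-based dialects converted on load by flag.
- Each annotation row is one element; no fragment joining by default.
- The 12 bundled oligonucleotides are stored verbatim with their recorded
  lengths as metadata; the fixture is regenerated programmatically, never
  parsed from documents.
- Pipeline null estimates are computed per family on the first 20 kb of
  inside-element sequence (configurable), a sample size chosen to keep a
  full run in tens of seconds while giving stable percentile bounds.
- Percentile CIs use 100 replicates by default; the replicate count and
  whether the baseline is read as mean or quantile are reported side by
  side since either reading is defensible.
- Empty strata are emitted with density 0 and flagged, never dropped or
  divided through.
- All run outputs carry a version-stamped comment header; the pipeline
  manifest stores parameters, input checksums and per-stage counts and
  contains no timestamps, so identical inputs and seeds reproduce
  byte-identical output directories.

## Known limitations

- The scanner's cluster definition is one of several defensible readings
  of "PQS cluster"; absolute counts are comparable only within one
  definition (overlapping-match counting would give larger totals).
- The DP scanner is quadratic in the length of uninterrupted G-rich
  blocks; pathological inputs (tens of kb of near-pure G) would be slow.
  Natural and simulated sequences are far from this regime.
- Thermodynamic scoring (G4Hunter-style), RNA quadruplexes and
  two-quartet patterns are out of scope; the two-quartet form is reachable
  via `min_run=2` but is not a tested default.
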