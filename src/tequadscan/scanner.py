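"""Detection of potential quadruplex sequences (PQS) as clusters of spaced G-runs.

The canonical pattern scanned for is the three-quartet motif

    GGG - N(1-7) - GGG - N(1-7) - GGG - N(1-7) - GGG

i.e. at least four runs of at least three guanines separated by loops of one
to seven nucleotides, on both strands of the input.  Hits on the scanned
(sense) strand are labelled ``PQS3+``; hits whose G-runs lie on the reverse
complement are labelled ``PQS3-``.

Cluster semantics
-----------------
The pattern admits overlapping placements, so a deterministic notion of a
*cluster* is needed.  A cluster is defined as follows: scanning left to
right, a cluster is anchored at the leftmost position where any valid
run/loop chain can start, and its end is the maximal end over all valid
chains starting at that anchor (additional loop+run units are appended while
possible).  Scanning resumes after the cluster, so reported clusters on one
strand never overlap.

Loops may by default contain G (so a long G tract such as ``GGGGGGG`` can be
carved into run-loop-run) and may contain N.  Both are switchable through
:class:`ScanParams`.  N never counts towards a G-run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScanParams",
    "PQSCluster",
    "revcomp",
    "scan_plus",
    "scan_minus",
    "scan_record",
    "scan_genome",
    "brute_force_oracle",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PLUS_LABEL = "PQS3+"
MINUS_LABEL = "PQS3-"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the PQS pattern.

    min_run
        Minimum G-run length (default 3, the three-quartet pattern).
    min_runs
        Minimum number of runs per cluster (default 4).
    loop_min, loop_max
        Loop length bounds in nt (defaults 1 and 7).
    allow_g_loops
        Whether loops may contain G.  On by default; a long G tract can then
        satisfy the pattern by itself (run-loop-run carving).
    allow_n_loops
        Whether loops may contain N (masked-genome tolerance).  On by default.
    """

    min_run: int = 3
    min_runs: int = 4
    loop_min: int = 1
    loop_max: int = 7
    allow_g_loops: bool = True
    allow_n_loops: bool = True

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if self.min_runs < 2:
            raise ValueError("min_runs must be >= 2")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError("require 0 <= loop_min <= loop_max")


@dataclass
class PQSCluster:
    """One detected PQS cluster.

    Coordinates are 0-based half-open in plus-strand space of the scanned
    source (a chromosome or an arbitrary sequence record).  ``signature`` is
    the canonical run/loop parse as ``((run_len, loop_len), ...)`` with the
    final run paired with loop length 0.  For ``PQS3-`` hits the signature
    describes the reverse-complement strand while ``start``/``end``/
    ``matched_seq`` stay in plus-strand space.
    """

    source_id: str
    start: int
    end: int
    strand_label: str
    matched_seq: str
    n_runs: int
    signature: tuple[tuple[int, int], ...]
    chrom: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def signature_str(self) -> str:
        parts = []
        for run, loop in self.signature[:-1]:
            parts.append(f"{run}-{loop}")
        parts.append(str(self.signature[-1][0]))
        return ",".join(parts)


def _run_lengths(seq: str) -> np.ndarray:
    """runlen[i] = number of consecutive 'G' starting at i (0 if seq[i] != G)."""
    n = len(seq)
    runlen = np.zeros(n + 1, dtype=np.int64)
    if n == 0:
        return runlen
    g = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("G")
    nong = np.nonzero(~g)[0]
    idx = np.arange(n)
    if len(nong) == 0:
        runlen[:n] = n - idx
        return runlen
    j = np.searchsorted(nong, idx)
    nxt = np.where(j < len(nong), nong[np.minimum(j, len(nong) - 1)], n)
    runlen[:n] = np.where(g, nxt - idx, 0)
    return runlen


def _loop_disallowed_prefix(seq: str, params: ScanParams) -> np.ndarray:
    """Prefix sums of positions whose base may NOT appear inside a loop."""
    pre = np.zeros(len(seq) + 1, dtype=np.int64)
    if not seq:
        return pre
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bad = np.zeros(len(seq), dtype=bool)
    if not params.allow_g_loops:
        bad |= arr == ord("G")
    if not params.allow_n_loops:
        bad |= arr == ord("N")
    np.cumsum(bad, out=pre[1:])
    return pre


class _ChainDP:
    """Right-to-left DP over run-start positions.

    ``best_end(p, r)`` is the maximal end of any chain (run, then any number
    of loop+run units) starting with a run at ``p`` and containing at least
    ``r`` runs, or -1 if none exists.  ``r`` is clamped to ``min_runs``.
    """

    def __init__(self, seq: str, params: ScanParams):
        self.seq = seq
        self.params = params
        self.runlen = _run_lengths(seq)
        self.badpre = _loop_disallowed_prefix(seq, params)
        self.run_starts = np.nonzero(self.runlen[:-1] >= params.min_run)[0].tolist()
        self._best: dict[tuple[int, int], int] = {}
        self._fill()

    def loop_ok(self, a: int, b: int) -> bool:
        return self.badpre[b] - self.badpre[a] == 0

    def _fill(self) -> None:
        P = self.params
        runlen = self.runlen
        best = self._best
        n = len(self.seq)
        for p in reversed(self.run_starts):
            # successor candidates: (next run start, max downstream r available)
            succ: list[int] = []
            for k in range(P.min_run, int(runlen[p]) + 1):
                for l in range(P.loop_min, P.loop_max + 1):
                    q = p + k + l
                    if q >= n or runlen[q] < P.min_run:
                        continue
                    if l > 0 and not self.loop_ok(p + k, q):
                        continue
                    succ.append(q)
            bare_end = p + int(runlen[p])
            for r in range(1, P.min_runs + 1):
                cand = bare_end if r <= 1 else -1
                r_next = max(1, r - 1)
                for q in succ:
                    e = best.get((q, r_next), -1)
                    if e > cand:
                        cand = e
                best[(p, r)] = cand

    def best_end(self, p: int, r: int) -> int:
        return self._best.get((p, min(r, self.params.min_runs)), -1)


def _parse_cluster(
    dp: _ChainDP, start: int, end: int
) -> tuple[tuple[tuple[int, int], ...], int]:
    """Canonical run/loop parse of a cluster span.

    Greedy left-to-right: each run consumes maximally, then each loop
    consumes maximally, both constrained so the parse can still complete at
    exactly ``end`` with at least ``min_runs`` runs (regex-style greedy with
    backtracking only to rescue the match).
    """
    P = dp.params
    runlen = dp.runlen

    memo: dict[tuple[int, int], bool] = {}

    def feasible(p: int, r: int) -> bool:
        """Chain starting with run at p can end exactly at ``end`` with >= r runs."""
        r = min(r, P.min_runs)
        key = (p, r)
        if key in memo:
            return memo[key]
        memo[key] = False  # guards (no cycles: positions strictly increase)
        ok = False
        maxk = min(int(runlen[p]), end - p)
        for k in range(P.min_run, maxk + 1):
            if p + k == end and r <= 1:
                ok = True
                break
            for l in range(P.loop_min, P.loop_max + 1):
                q = p + k + l
                if q >= end or runlen[q] < P.min_run:
                    continue
                if l > 0 and not dp.loop_ok(p + k, q):
                    continue
                if feasible(q, max(1, r - 1)):
                    ok = True
                    break
            if ok:
                break
        memo[key] = ok
        return ok

    sig: list[tuple[int, int]] = []
    pos = start
    need = P.min_runs
    while True:
        maxk = min(int(runlen[pos]), end - pos)
        chosen = None
        for k in range(maxk, P.min_run - 1, -1):
            if pos + k == end and need <= 1:
                chosen = (k, 0)
                break
            for l in range(P.loop_max, P.loop_min - 1, -1):
                if l == 0:
                    continue
                q = pos + k + l
                if q >= end or runlen[q] < P.min_run:
                    continue
                if not dp.loop_ok(pos + k, q):
                    continue
                if feasible(q, max(1, need - 1)):
                    chosen = (k, l)
                    break
            if chosen:
                break
        if chosen is None:  # pragma: no cover - guarded by construction
            raise RuntimeError(f"unparseable cluster [{start},{end})")
        sig.append(chosen)
        k, l = chosen
        if l == 0 and pos + k == end:
            break
        pos = pos + k + l
        need = max(1, need - 1)
    return tuple(sig), len(sig)


def _scan_spans(seq: str, params: ScanParams) -> list[tuple[int, int, _ChainDP]]:
    if not seq:
        return []
    dp = _ChainDP(seq, params)
    spans: list[tuple[int, int, _ChainDP]] = []
    pos = 0
    for p in dp.run_starts:
        if p < pos:
            continue
        e = dp.best_end(p, params.min_runs)
        if e >= 0:
            spans.append((p, e, dp))
            pos = e
    return spans


def scan_plus(
    seq: str, params: ScanParams | None = None, source_id: str = ""
) -> list[PQSCluster]:
    """Scan the given strand for PQS3+ clusters.

    Returns leftmost-maximal non-overlapping clusters with coordinates in
    ``seq`` space.  Empty input yields an empty list.
    """
    params = params or ScanParams()
    seq = seq.upper()
    out = []
    for s, e, dp in _scan_spans(seq, params):
        sig, n_runs = _parse_cluster(dp, s, e)
        out.append(
            PQSCluster(
                source_id=source_id,
                start=s,
                end=e,
                strand_label=PLUS_LABEL,
                matched_seq=seq[s:e],
                n_runs=n_runs,
                signature=sig,
            )
        )
    return out


def scan_minus(
    seq: str, params: ScanParams | None = None, source_id: str = ""
) -> list[PQSCluster]:
    """Scan the reverse complement; report hits in plus-strand coordinates.

    Definitionally ``scan_minus(seq)`` equals ``scan_plus(revcomp(seq))``
    with intervals reflected back (``[s,e) -> [n-e, n-s)``) and the label set
    to ``PQS3-``.  ``matched_seq`` is the plus-strand sequence of the span;
    the signature describes the reverse-complement strand.
    """
    params = params or ScanParams()
    seq = seq.upper()
    n = len(seq)
    rc = revcomp(seq)
    out = []
    for hit in scan_plus(rc, params, source_id=source_id):
        out.append(
            PQSCluster(
                source_id=source_id,
                start=n - hit.end,
                end=n - hit.start,
                strand_label=MINUS_LABEL,
                matched_seq=seq[n - hit.end : n - hit.start],
                n_runs=hit.n_runs,
                signature=hit.signature,
            )
        )
    out.reverse()  # ascending plus-strand start
    return out


def scan_both(
    seq: str, params: ScanParams | None = None, source_id: str = ""
) -> list[PQSCluster]:
    """Both strands, sorted by (start, strand label)."""
    hits = scan_plus(seq, params, source_id) + scan_minus(seq, params, source_id)
    hits.sort(key=lambda h: (h.start, h.strand_label))
    return hits


def scan_record(rec, params: ScanParams | None = None) -> list[PQSCluster]:
    """Scan a :class:`~tequadscan.annotation.SequenceRecord` on both strands.

    When the record carries a genome origin, hits are lifted to genome
    coordinates (records from the genome minus strand are first oriented to
    the genome plus strand, so ``PQS3+`` always refers to the genome plus
    strand) and tagged with the chromosome.  Otherwise hits stay in sequence
    space with ``source_id = record_id``.
    """
    params = params or ScanParams()
    if rec.origin is None:
        return scan_both(rec.seq, params, source_id=rec.record_id)
    chrom, gstart, gend, strand = rec.origin
    seq = rec.seq if strand == "+" else revcomp(rec.seq)
    hits = scan_both(seq, params, source_id=rec.record_id)
    for h in hits:
        h.start += gstart
        h.end += gstart
        h.chrom = chrom
    return hits


def scan_genome(
    genome: dict[str, str], params: ScanParams | None = None
) -> list[PQSCluster]:
    """Scan every chromosome of ``genome`` on both strands."""
    params = params or ScanParams()
    hits: list[PQSCluster] = []
    for chrom in genome:
        for h in scan_both(genome[chrom], params, source_id=chrom):
            h.chrom = chrom
            hits.append(h)
    return hits


# ---------------------------------------------------------------------------
# Brute-force oracle (test-time verification only)
# ---------------------------------------------------------------------------

_ORACLE_MAX_LEN = 1000


def brute_force_oracle(
    seq: str, params: ScanParams | None = None, source_id: str = ""
) -> list[PQSCluster]:
    """Exhaustive reference implementation of :func:`scan_plus`.

    Enumerates *every* legal placement of >= ``min_runs`` runs with legal
    loops (all run lengths, all loop lengths) as explicit (start, end) chain
    spans, then applies the leftmost-maximal non-overlapping selection rule.
    Independent of the DP used by the production scanner; intended for tests
    on short inputs only.
    """
    params = params or ScanParams()
    seq = seq.upper()
    if len(seq) > _ORACLE_MAX_LEN:
        raise ValueError(f"oracle refuses sequences longer than {_ORACLE_MAX_LEN}")
    n = len(seq)
    bad = set()
    if not params.allow_g_loops:
        bad.add("G")
    if not params.allow_n_loops:
        bad.add("N")

    def is_run(a: int, b: int) -> bool:
        return b <= n and all(seq[i] == "G" for i in range(a, b))

    def loop_ok(a: int, b: int) -> bool:
        return all(seq[i] not in bad for i in range(a, b))

    # ends[(p, r)] = set of ends of chains starting with a run at p, >= r runs
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def ends(p: int, r: int) -> frozenset[int]:
        found: set[int] = set()
        k = params.min_run
        while is_run(p, p + k):
            if r <= 1:
                found.add(p + k)
            for l in range(params.loop_min, params.loop_max + 1):
                if l == 0:
                    continue
                q = p + k + l
                if q + params.min_run > n or not loop_ok(p + k, q):
                    continue
                found |= ends(q, max(1, r - 1))
            k += 1
        return frozenset(found)

    chains: dict[int, int] = {}  # start -> max end
    for p in range(n):
        es = ends(p, params.min_runs)
        if es:
            chains[p] = max(es)

    out: list[PQSCluster] = []
    pos = 0
    for p in sorted(chains):
        if p < pos:
            continue
        e = chains[p]
        dp = _ChainDP(seq[p:e], params)
        sig, n_runs = _parse_cluster(dp, 0, e - p)
        out.append(
            PQSCluster(
                source_id=source_id,
                start=p,
                end=e,
                strand_label=PLUS_LABEL,
                matched_seq=seq[p:e],
                n_runs=n_runs,
                signature=sig,
            )
        )
        pos = e
    return out
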