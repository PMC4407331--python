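"""Grouping detected PQS into recurring motif patterns.

Clustering is by canonical run/loop signature: run lengths capped at "5+"
and loop lengths bucketed into short (1-3) and long (4-7) classes, so hits
sharing the same guanine architecture group together regardless of loop
base composition.  Clusters are ranked by frequency; each exports its most
common exact sequence as representative.  An optional identity mode groups
by full-sequence similarity (greedy centroid at a configurable identity
threshold) for comparison.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .scanner import PQSCluster

__all__ = ["MotifCluster", "signature_key", "cluster_and_rank", "cluster_by_identity"]

_RUN_CAP = 5


def _loop_bucket(l: int) -> str:
    return "1-3" if l <= 3 else "4-7"


def signature_key(hit: PQSCluster) -> str:
    """Canonical signature key of a hit, e.g. ``4/1-3,4/1-3,4/1-3,3``.

    Each non-final run contributes ``run/loopbucket`` (run capped at
    ``5+``); the final run stands alone.  Deterministic in the hit's parsed
    structure.
    """
    parts = []
    for run, loop in hit.signature[:-1]:
        r = str(run) if run <= _RUN_CAP else f"{_RUN_CAP}+"
        parts.append(f"{r}/{_loop_bucket(loop)}")
    last = hit.signature[-1][0]
    parts.append(str(last) if last <= _RUN_CAP else f"{_RUN_CAP}+")
    return ",".join(parts)


@dataclass
class MotifCluster:
    family: str
    signature_key: str
    members: list[PQSCluster]
    representative: str = ""
    consensus_loops: tuple[str, ...] = ()

    @property
    def count(self) -> int:
        return len(self.members)


def _loops_of(hit: PQSCluster) -> list[str]:
    """Loop substrings of a hit (on the strand the signature describes)."""
    seq = hit.matched_seq
    if hit.strand_label.endswith("-"):
        from .scanner import revcomp

        seq = revcomp(seq)
    loops, pos = [], 0
    for run, loop in hit.signature:
        pos += run
        if loop:
            loops.append(seq[pos : pos + loop])
            pos += loop
    return loops


def _consensus_loops(members: Sequence[PQSCluster]) -> tuple[str, ...]:
    """Majority loop string per loop index (ties: lexicographically smallest)."""
    n_loops = max((len(h.signature) - 1 for h in members), default=0)
    out = []
    for i in range(n_loops):
        c = Counter()
        for h in members:
            loops = _loops_of(h)
            if i < len(loops):
                c[loops[i]] += 1
        if c:
            best = sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            out.append(best)
    return tuple(out)


def cluster_and_rank(hits: Sequence[PQSCluster], family: str = "") -> list[MotifCluster]:
    """Partition hits by signature key, ranked by count desc then key asc.

    The representative is the most frequent exact matched sequence (ties
    broken lexicographically).  Input order never affects cluster contents
    or ranking.  Empty input yields an empty list.
    """
    groups: dict[str, list[PQSCluster]] = {}
    for h in sorted(hits, key=lambda h: (h.matched_seq, h.start, h.end)):
        groups.setdefault(signature_key(h), []).append(h)
    out = []
    for key in sorted(groups, key=lambda k: (-len(groups[k]), k)):
        members = groups[key]
        seq_counts = Counter(h.matched_seq for h in members)
        rep = sorted(seq_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(
            MotifCluster(
                family=family,
                signature_key=key,
                members=members,
                representative=rep,
                consensus_loops=_consensus_loops(members),
            )
        )
    return out


def _identity(a: str, b: str) -> float:
    """Fraction of matching positions over the longer length (no alignment)."""
    if not a or not b:
        return 0.0
    m = sum(1 for x, y in zip(a, b) if x == y)
    return m / max(len(a), len(b))


def cluster_by_identity(
    hits: Sequence[PQSCluster], family: str = "", threshold: float = 0.8
) -> list[MotifCluster]:
    """Greedy centroid clustering by full-sequence identity (comparison mode)."""
    centroids: list[MotifCluster] = []
    for h in sorted(hits, key=lambda h: (-len(h.matched_seq), h.matched_seq)):
        placed = False
        for c in centroids:
            if _identity(h.matched_seq, c.representative) >= threshold:
                c.members.append(h)
                placed = True
                break
        if not placed:
            centroids.append(
                MotifCluster(family=family, signature_key="", members=[h], representative=h.matched_seq)
            )
    centroids.sort(key=lambda c: (-c.count, c.representative))
    return centroids
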