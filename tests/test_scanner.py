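"""PQS scanner: pattern semantics, oracle equivalence, strand symmetry."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tequadscan.scanner import (
    PQSCluster,
    ScanParams,
    brute_force_oracle,
    revcomp,
    scan_both,
    scan_minus,
    scan_plus,
    scan_record,
)
from tequadscan.annotation import SequenceRecord
from tequadscan.simulate import TABLE1_SEQUENCES

DNA = st.text(alphabet="ACGT", min_size=0, max_size=120)


def _spans(hits):
    return [(h.start, h.end) for h in hits]


@pytest.mark.parametrize(
    "seq,expected_spans",
    [
        ("GGGAGGGAGGGAGGG", [(0, 15)]),  # canonical four spaced runs
        ("ATATATATAT", []),  # no G runs
        ("GGGAGGGAGGG", []),  # only three runs
        ("G" * 15, [(0, 15)]),  # long tract carved via G loops
        ("CCCTCCCTCCCTCCC", []),  # C-rich: plus strand has nothing
        ("", []),
    ],
)
def test_scan_plus_examples(seq, expected_spans):
    assert _spans(scan_plus(seq)) == expected_spans


def test_canonical_cluster_structure():
    (hit,) = scan_plus("GGGAGGGAGGGAGGG")
    assert hit.n_runs == 4
    assert hit.signature == ((3, 1), (3, 1), (3, 1), (3, 0))
    assert hit.strand_label == "PQS3+"
    assert hit.matched_seq == "GGGAGGGAGGGAGGG"


def test_scan_minus_is_mirror_of_plus():
    hits = scan_minus("CCCTCCCTCCCTCCC")
    assert _spans(hits) == [(0, 15)]
    assert hits[0].strand_label == "PQS3-"
    assert hits[0].matched_seq == "CCCTCCCTCCCTCCC"  # plus-strand sequence
    # a G-rich plus strand yields nothing on the minus strand
    assert scan_minus("GGGAGGGAGGGAGGG") == []


@pytest.mark.parametrize("name,seq", sorted(TABLE1_SEQUENCES.items()))
def test_each_bundled_oligo_has_pqs3_plus(name, seq):
    """Every bundled oligonucleotide contains a sense-strand PQS by design."""
    hits = scan_plus(seq)
    assert len(hits) >= 1, name
    for h in hits:
        assert h.n_runs >= 4


def test_n_in_loops_toggle():
    seq = "GGGNGGGNGGGNGGG"
    assert len(scan_plus(seq, ScanParams())) == 1
    assert scan_plus(seq, ScanParams(allow_n_loops=False)) == []


def test_strict_loops_excludes_pure_g_tract():
    assert len(scan_plus("G" * 15)) == 1
    assert scan_plus("G" * 15, ScanParams(allow_g_loops=False)) == []
    # spaced runs are unaffected by the strict-loop option
    assert len(scan_plus("GGGAGGGAGGGAGGG", ScanParams(allow_g_loops=False))) == 1


def test_cluster_signature_accounts_for_span():
    """run+loop lengths tile the cluster exactly; loops within bounds."""
    rng = np.random.default_rng(5)
    params = ScanParams()
    for _ in range(300):
        n = int(rng.integers(20, 200))
        seq = "".join(np.array(list("ACGGT"))[rng.integers(0, 5, size=n)])
        for h in scan_plus(seq, params):
            total = sum(r + l for r, l in h.signature)
            assert total == h.end - h.start
            assert h.n_runs == len(h.signature) >= params.min_runs
            for i, (r, l) in enumerate(h.signature):
                assert r >= params.min_run
                if i < len(h.signature) - 1:
                    assert params.loop_min <= l <= params.loop_max
                else:
                    assert l == 0


def test_oracle_equivalence_on_seeded_corpus():
    """The DP scanner and the exhaustive enumeration oracle agree exactly."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(0, 301))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
        a = [(h.start, h.end, h.signature) for h in scan_plus(seq)]
        b = [(h.start, h.end, h.signature) for h in brute_force_oracle(seq)]
        assert a == b, seq


def test_oracle_equivalence_g_rich():
    """Agreement also on G-biased sequences where carving is exercised."""
    rng = np.random.default_rng(11)
    for _ in range(300):
        n = int(rng.integers(0, 120))
        seq = "".join("G" if x < 0.55 else "AT"[int(x * 100) % 2] for x in rng.random(n))
        assert _spans(scan_plus(seq)) == _spans(brute_force_oracle(seq))


def test_oracle_refuses_long_input():
    with pytest.raises(ValueError):
        brute_force_oracle("A" * 2000)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(DNA)
def test_strand_mirror_property(seq):
    """scan_minus(seq) == length-reflected scan_plus(revcomp(seq))."""
    n = len(seq)
    minus = [(h.start, h.end) for h in scan_minus(seq)]
    mirrored = sorted((n - h.end, n - h.start) for h in scan_plus(revcomp(seq)))
    assert sorted(minus) == mirrored


@settings(max_examples=300, deadline=None, derandomize=True)
@given(DNA)
def test_clusters_disjoint_per_strand(seq):
    for scan in (scan_plus, scan_minus):
        hits = scan(seq)
        for a, b in zip(hits, hits[1:]):
            assert a.end <= b.start


@settings(max_examples=200, deadline=None, derandomize=True)
@given(DNA, DNA)
def test_spacer_concatenation_is_union(left, right):
    """Sequences joined by a 20 nt A-spacer scan to the union of their hits."""
    spacer = "A" * 20
    joined = left + spacer + right
    expected = _spans(scan_plus(left)) + [
        (s + len(left) + 20, e + len(left) + 20) for s, e in _spans(scan_plus(right))
    ]
    assert _spans(scan_plus(joined)) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(DNA)
def test_relaxing_parameters_is_monotone(seq):
    """Wider loops or shorter runs never reduce pattern-covered positions."""

    def covered(params):
        return sum(h.end - h.start for h in scan_plus(seq, params))

    base = covered(ScanParams())
    assert covered(ScanParams(loop_max=12)) >= base
    assert covered(ScanParams(min_run=2)) >= base


def test_scan_record_lifts_to_genome_coordinates():
    seq = "T" * 9 + "GGGAGGGAGGGAGGGAGGGAGGGA" + "T" * 9
    rec = SequenceRecord("r", seq, origin=("chr1", 1000, 1000 + len(seq), "+"))
    (hit,) = [h for h in scan_record(rec) if h.strand_label == "PQS3+"]
    assert hit.chrom == "chr1"
    # the cluster is the 23 bp six-run chain starting at sequence offset 9
    assert (hit.start, hit.end) == (1009, 1032)


def test_scan_record_minus_strand_origin_reflects():
    """Minus-strand records are oriented to the genome plus strand first."""
    plus_seq = "T" * 10 + "GGGAGGGAGGGAGGG" + "C" * 10
    rec_plus = SequenceRecord("p", plus_seq, origin=("chr2", 500, 500 + len(plus_seq), "+"))
    rec_minus = SequenceRecord(
        "m", revcomp(plus_seq), origin=("chr2", 500, 500 + len(plus_seq), "-")
    )
    key = lambda h: (h.start, h.end, h.strand_label)
    assert sorted(map(key, scan_record(rec_plus))) == sorted(map(key, scan_record(rec_minus)))


def test_scan_record_without_origin_stays_in_sequence_space():
    rec = SequenceRecord("oligo", "GGGAGGGAGGGAGGG")
    (hit,) = [h for h in scan_record(rec) if h.strand_label == "PQS3+"]
    assert hit.chrom is None
    assert hit.source_id == "oligo"
    assert (hit.start, hit.end) == (0, 15)
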