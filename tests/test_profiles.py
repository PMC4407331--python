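"""Consensus-coordinate projection and family density profiles."""

from __future__ import annotations

import numpy as np
import pytest

from tequadscan.annotation import RepeatAnnotation
from tequadscan.context import ZoneAssignment, assign_zones
from tequadscan.profiles import (
    build_profile,
    default_window,
    project_to_consensus,
    reference_density,
)
from tequadscan.scanner import PQSCluster


def _ann(start=1000, end=2000, strand="+", cons=None, chrom="chr1", name="SVA_F", eid="e0"):
    cs, ce = cons if cons else (None, None)
    return RepeatAnnotation(
        chrom=chrom,
        geno_start=start,
        geno_end=end,
        strand=strand,
        rep_name=name,
        rep_class="Retroposon",
        rep_family="SVA",
        cons_start=cs,
        cons_end=ce,
        element_id=eid,
    )


def _hit(start, end, strand_label="PQS3+", chrom="chr1"):
    return PQSCluster(
        source_id=chrom,
        start=start,
        end=end,
        strand_label=strand_label,
        matched_seq="N" * (end - start),
        n_runs=4,
        signature=((3, 1), (3, 1), (3, 1), (3, 0)),
        chrom=chrom,
    )


class TestProjection:
    def test_linear_map_with_consensus_coords(self):
        ann = _ann(cons=(0, 1000))
        pos, label = project_to_consensus(_hit(1490, 1510), ann)
        assert pos == pytest.approx(500.0)
        assert label == "PQS3+"

    def test_minus_strand_reflects_and_flips(self):
        ann = _ann(strand="-", cons=(0, 1000))
        pos, label = project_to_consensus(_hit(1490, 1510), ann)
        assert pos == pytest.approx(500.0)
        assert label == "PQS3-"  # element-sense orientation

    def test_truncated_element_interpolates_into_consensus(self):
        # copy occupies consensus [2000, 6000) of a 6 kb consensus,
        # genome-relative offset 1000 of 4000 -> consensus 3000
        ann = _ann(start=10_000, end=14_000, cons=(2000, 6000))
        pos, _ = project_to_consensus(_hit(10_999, 11_001), ann)
        assert pos == pytest.approx(3000.0)

    def test_length_scaling_without_consensus_coords(self):
        ann = _ann()
        pos, _ = project_to_consensus(_hit(1249, 1251), ann, consensus_length=2000)
        assert pos == pytest.approx(500.0)

    def test_hit_outside_element_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            project_to_consensus(_hit(100, 130), _ann(cons=(0, 1000)))


def test_default_window_clamped():
    assert default_window(6000) == 120
    assert default_window(300) == 40
    assert default_window(2500) == 50


class TestBuildProfile:
    def _assignments(self, hits, anns):
        return assign_zones(hits, anns, flank=200)

    def test_point_mass_lands_in_covering_windows(self):
        ann = _ann(start=0, end=2000, cons=(0, 2000))
        hits = [_hit(495, 505) for _ in range(10)]
        prof = build_profile(
            self._assignments(hits, [ann]), [ann], "SVA",
            consensus_length=2000, window_len=100, stride=50,
        )
        pooled = prof.pooled("PQS3+")
        covering = (prof.window_starts <= 500) & (500 < prof.window_starts + 100)
        assert (pooled[covering] == 10).all()
        assert pooled[~covering].sum() == 0

    def test_tiled_counts_conserve_hits(self):
        rng = np.random.default_rng(1)
        ann = _ann(start=0, end=2000, cons=(0, 2000))
        hits = [_hit(int(s), int(s) + 20) for s in rng.integers(0, 1980, size=40)]
        asg = self._assignments(hits, [ann])
        prof = build_profile(asg, [ann], "SVA", consensus_length=2000,
                             window_len=100, stride=100)
        n_inside = sum(a.zone == "inside" for a in asg)
        assert prof.pooled().sum() == n_inside == prof.n_hits

    def test_strand_flip_consistency(self):
        """Inverting every element strand (and hit labels, as a reverse-
        complemented genome would produce) leaves the profile unchanged."""
        rng = np.random.default_rng(2)
        L = 2000
        ann_f = _ann(start=0, end=L, strand="+", cons=(0, L))
        hits_f, hits_r = [], []
        for s in rng.integers(0, L - 30, size=25):
            s = int(s)
            label = "PQS3+" if rng.random() < 0.5 else "PQS3-"
            hits_f.append(_hit(s, s + 20, label))
            flipped = "PQS3-" if label == "PQS3+" else "PQS3+"
            hits_r.append(_hit(L - (s + 20), L - s, flipped))
        ann_r = _ann(start=0, end=L, strand="-", cons=(0, L))
        prof_f = build_profile(self._assignments(hits_f, [ann_f]), [ann_f], "SVA",
                               consensus_length=L, window_len=100, stride=100)
        prof_r = build_profile(self._assignments(hits_r, [ann_r]), [ann_r], "SVA",
                               consensus_length=L, window_len=100, stride=100)
        for key in prof_f.counts:
            assert (prof_f.counts[key] == prof_r.counts.get(key, 0)).all()

    def test_empty_family_flagged(self):
        prof = build_profile([], [], "SVA", consensus_length=2000)
        assert prof.n_elements == 0 and prof.n_hits == 0
        assert prof.pooled().sum() == 0


class TestPlantedPeaks:
    def test_l1_peak_in_terminal_consensus_bins(self, demo_bundle, demo_scan):
        """The L1-like family plants most PQS in the 3'-terminal segment."""
        genome, annotations, _ = demo_bundle
        _, assignments = demo_scan
        prof = build_profile(assignments, annotations, "L1", consensus_length=6000)
        pooled = prof.pooled("PQS3+")
        centers = (prof.window_starts + prof.window_ends) / 2
        peak = centers[int(np.argmax(pooled))]
        assert peak >= 5640  # inside the terminal segment
        # terminal windows hold the majority of plus-strand hits
        tail = pooled[prof.window_ends > 5640].sum()
        assert tail > pooled.sum() / 2

    def test_sva_strand_specific_peaks(self, demo_bundle, demo_scan):
        """SVA-like: minus-strand PQS at the 5' hexamer repeat, plus-strand
        along the central VNTR."""
        genome, annotations, _ = demo_bundle
        _, assignments = demo_scan
        prof = build_profile(assignments, annotations, "SVA", consensus_length=2000)
        centers = (prof.window_starts + prof.window_ends) / 2
        minus_peak = centers[int(np.argmax(prof.pooled("PQS3-")))]
        plus_peak = centers[int(np.argmax(prof.pooled("PQS3+")))]
        assert minus_peak < 180 + prof.window_len
        assert 700 - prof.window_len <= plus_peak < 1060 + prof.window_len


class TestReferenceDensity:
    def test_arithmetic(self):
        assert reference_density(1000, 10_000_000, 100, 50) == pytest.approx(0.5)

    def test_zero_hits(self):
        assert reference_density(0, 1000, 100) == 0.0

    def test_linear_in_window(self):
        a = reference_density(500, 1_000_000, 40)
        b = reference_density(500, 1_000_000, 120)
        assert b == pytest.approx(3 * a)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            reference_density(10, 0, 100)
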