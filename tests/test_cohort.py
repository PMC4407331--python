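"""Stratified abundance summaries: percentages, age trends, contrasts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tequadscan.annotation import RepeatAnnotation
from tequadscan.cohort import (
    ALU_AGE,
    SVA_AGE,
    AgeOrder,
    age_trend,
    element_table,
    length_activity_contrast,
    percent_with_pqs,
)
from tequadscan.context import assign_zones
from tequadscan.scanner import PQSCluster


def _ann(eid, start, end, name="SVA_F", cls="Retroposon", fam="SVA", strand="+", chrom="chr1"):
    return RepeatAnnotation(
        chrom=chrom, geno_start=start, geno_end=end, strand=strand,
        rep_name=name, rep_class=cls, rep_family=fam, element_id=eid,
    )


def _hit(start, end, strand_label="PQS3+", chrom="chr1"):
    return PQSCluster(
        source_id=chrom, start=start, end=end, strand_label=strand_label,
        matched_seq="N" * (end - start), n_runs=4,
        signature=((3, 1), (3, 1), (3, 1), (3, 0)), chrom=chrom,
    )


def _elements(anns, hits):
    return element_table(anns, assign_zones(hits, anns, flank=200))


class TestPercentWithPqs:
    def test_half_of_elements_with_inside_hits(self):
        anns = [_ann(f"e{i}", i * 10_000, i * 10_000 + 2000) for i in range(4)]
        hits = [_hit(500, 530), _hit(10_500, 10_530)]
        out = percent_with_pqs(_elements(anns, hits), ("family",))
        row = out[out.family == "SVA"].iloc[0]
        assert row.n_elements == 4
        assert row.n_elements_with_pqs == 2
        assert row.pct_elements_with_pqs == pytest.approx(50.0)

    def test_empty_stratum_flagged_not_divided(self):
        out = percent_with_pqs(pd.DataFrame(
            {"family": [], "has_pqs": [], "n_pqs": [], "length": []}
        ))
        assert out.empty
        # a stratum with zero elements inside a grouped frame
        anns = [_ann("e0", 0, 2000)]
        elements = _elements(anns, [])
        out = percent_with_pqs(elements, ("family",))
        assert out.iloc[0].pct_elements_with_pqs == 0.0
        assert not out.iloc[0].empty

    def test_invariant_to_hit_and_row_order(self):
        anns = [_ann(f"e{i}", i * 10_000, i * 10_000 + 2000) for i in range(5)]
        hits = [_hit(500, 530), _hit(20_100, 20_130), _hit(40_900, 40_930)]
        a = percent_with_pqs(_elements(anns, hits))
        b = percent_with_pqs(_elements(anns[::-1], hits[::-1]))
        pd.testing.assert_frame_equal(a, b)


def _aged_cohort(counts_by_group, n_per_group=12, length=2000):
    """Cohort with a chosen mean inside-PQS count per SVA subfamily."""
    anns, hits = [], []
    i = 0
    for label, mean_hits in counts_by_group.items():
        for k in range(n_per_group):
            start = i * 10_000
            anns.append(_ann(f"{label}.{k}", start, start + length, name=label))
            for j in range(int(mean_hits)):
                hits.append(_hit(start + 100 + 40 * j, start + 120 + 40 * j))
            i += 1
    return _elements(anns, hits)


class TestAgeTrend:
    def test_constant_abundance_gives_tau_zero(self):
        elements = _aged_cohort({l: 2 for l in SVA_AGE.labels})
        _, res = age_trend(elements, SVA_AGE, n_permutations=99, seed=1)
        assert res["tau"] == 0.0

    def test_strictly_increasing_abundance_gives_tau_one(self):
        elements = _aged_cohort(
            {l: i for i, l in enumerate(SVA_AGE.labels)}
        )
        table, res = age_trend(elements, SVA_AGE, n_permutations=199, seed=1)
        assert res["tau"] == pytest.approx(1.0)
        assert res["p_value"] <= 0.05
        assert list(table.age_group) == SVA_AGE.labels  # ordered old -> young

    def test_single_populated_subfamily_leaves_trend_undefined(self):
        elements = _aged_cohort({"SVA_A": 2})
        table, res = age_trend(elements, SVA_AGE, n_permutations=99, seed=0)
        assert np.isnan(res["tau"]) and np.isnan(res["p_value"])
        assert len(table) == 6  # rows still emitted

    def test_permutation_p_seeded_deterministic(self):
        elements = _aged_cohort({l: i % 3 for i, l in enumerate(SVA_AGE.labels)})
        _, a = age_trend(elements, SVA_AGE, n_permutations=199, seed=5)
        _, b = age_trend(elements, SVA_AGE, n_permutations=199, seed=5)
        assert a["p_value"] == b["p_value"] and a["tau"] == b["tau"]

    def test_p_values_roughly_uniform_under_null(self):
        """Permuting labels of a label-independent cohort gives a p-value
        that is small no more often than its nominal level."""
        rng = np.random.default_rng(42)
        small = 0
        n_data = 120
        for _ in range(n_data):
            counts = {l: int(rng.integers(0, 4)) for l in SVA_AGE.labels}
            elements = _aged_cohort(counts, n_per_group=6)
            _, res = age_trend(
                elements, SVA_AGE, n_permutations=79, seed=int(rng.integers(2**31))
            )
            if res["p_value"] <= 0.25:
                small += 1
        # binomial(120, 0.25): mean 30, sd ~4.7; allow 3.5 sd
        assert abs(small - 30) < 17

    def test_age_order_matching(self):
        assert SVA_AGE.match("SVA_D") == "SVA_D"
        assert SVA_AGE.match("SVA_X") == "other"
        assert ALU_AGE.match("AluYa5") == "AluY"
        assert ALU_AGE.match("FLAM") == "other"


class TestLengthActivityContrast:
    def _l1_cohort(self):
        """Full-length copies carry 2 inside PQS, truncated none."""
        anns, hits = [], []
        for i in range(10):
            start = i * 20_000
            full = i % 2 == 0
            name = "L1HS" if i in (0, 1) else "L1PA7"
            end = start + (5000 if full else 2000)
            anns.append(_ann(f"l{i}", start, end, name=name, cls="LINE", fam="L1"))
            if full:
                hits += [_hit(start + 4500, start + 4530), _hit(start + 4600, start + 4630)]
        return _elements(anns, hits)

    def test_truncation_removing_pqs_gives_zero_truncated_abundance(self):
        table, ratios = length_activity_contrast(self._l1_cohort())
        sel = table[(table.group == "all") & (table.chrom_class == "all")]
        tr = sel[sel.length_class == "truncated"].iloc[0]
        fl = sel[sel.length_class == "full_length"].iloc[0]
        assert tr.pqs_per_element == 0.0
        assert fl.pqs_per_element == pytest.approx(2.0)
        assert ratios["full_vs_truncated"] == np.inf

    def test_active_rows_are_subsets(self):
        table, _ = length_activity_contrast(self._l1_cohort())
        for lc in ("all", "full_length", "truncated"):
            sel = table[(table.length_class == lc) & (table.chrom_class == "all")]
            n_all = sel[sel.group == "all"].iloc[0].n_elements
            n_act = sel[sel.group == "active"].iloc[0].n_elements
            assert n_act <= n_all

    def test_additivity_of_stratified_counts(self):
        table, _ = length_activity_contrast(self._l1_cohort())
        sel = table[(table.group == "all") & (table.chrom_class == "all")]
        total = sel[sel.length_class == "all"].iloc[0].n_pqs
        parts = sel[sel.length_class != "all"].n_pqs.sum()
        assert total == parts


def test_element_table_strand_orientation():
    """Inside counts are element-sense: labels flip for minus-strand copies."""
    ann = _ann("e0", 1000, 3000, strand="-")
    elements = _elements([ann], [_hit(1500, 1530, "PQS3-")])
    row = elements.iloc[0]
    assert row.n_pqs_plus == 1 and row.n_pqs_minus == 0
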