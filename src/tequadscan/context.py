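"""Relating PQS hits to repeat annotations.

Zone classification follows the end-point rule: a hit is *inside* an element
only if at least one of its ends lies within the element proper, not merely
overlapping it.  Otherwise a hit intersecting the 5'/3' flanking windows
(default 200 bp) is *upstream*/*downstream*, where the directions are
relative to the element's own strand (upstream = 5' of the element).

Full-length status uses per-family minimum-length thresholds (two thirds of
a typical representative): L1 4700, Alu 250, SVA 1600, HERV LTR 300 and
HERV internal 2000 bp, with the comparison inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import RepeatAnnotation
from .scanner import PQSCluster

__all__ = [
    "DEFAULT_THRESHOLDS",
    "FullLengthRule",
    "ZoneAssignment",
    "resolve_family_key",
    "classify_zone",
    "assign_zones",
    "is_full_length",
    "zone_density",
]

DEFAULT_THRESHOLDS = {
    "L1": 4700,
    "Alu": 250,
    "SVA": 1600,
    "HERV_ltr": 300,
    "HERV_internal": 2000,
}

ZONES = ("inside", "upstream", "downstream")


def resolve_family_key(
    ann: RepeatAnnotation,
    overrides: dict[str, str] | None = None,
    herv_internal_suffix: str = "-int",
) -> str | None:
    """Map an annotation to a family key (L1 / Alu / SVA / HERV_ltr /
    HERV_internal) or None when no rule applies.

    ``overrides`` maps rep_name or rep_family strings directly to keys.
    HERV rows are split into LTR vs internal by the RepeatMasker ``-int``
    rep_name suffix convention (configurable).
    """
    if overrides:
        for attr in (ann.rep_name, ann.rep_family):
            if attr in overrides:
                return overrides[attr]
    name, family, cls = ann.rep_name, ann.rep_family, ann.rep_class
    if "SVA" in name or "SVA" in family or cls == "SVA":
        return "SVA"
    if family.startswith("L1") or name.startswith("L1"):
        return "L1"
    if family.startswith("Alu") or name.startswith("Alu"):
        return "Alu"
    if cls == "LTR" or family.startswith(("ERV", "HERV")) or name.startswith(("HERV", "LTR", "MER")):
        if name.endswith(herv_internal_suffix):
            return "HERV_internal"
        return "HERV_ltr"
    return None


@dataclass(frozen=True)
class FullLengthRule:
    """Per-family minimum lengths defining 'full length' (inclusive >=)."""

    thresholds: tuple = tuple(sorted(DEFAULT_THRESHOLDS.items()))
    overrides: tuple = ()
    strict: bool = False

    def threshold_for(self, ann: RepeatAnnotation) -> int | None:
        key = resolve_family_key(ann, dict(self.overrides))
        th = dict(self.thresholds)
        if key is None or key not in th:
            if self.strict:
                raise KeyError(
                    f"{ann.element_id or ann.rep_name}: no full-length rule for "
                    f"name={ann.rep_name} class={ann.rep_class} family={ann.rep_family}"
                )
            return None
        return th[key]


def is_full_length(ann: RepeatAnnotation, rule: FullLengthRule | None = None) -> bool | None:
    """True/False per the family threshold; None when no rule resolves
    (lenient mode), excluding the element from full-length analyses."""
    rule = rule or FullLengthRule()
    th = rule.threshold_for(ann)
    if th is None:
        return None
    return ann.length >= th


@dataclass
class ZoneAssignment:
    element_id: str
    zone: str  # inside / upstream / downstream / unassigned
    hit: PQSCluster
    family_key: str | None = None


def classify_zone(hit: PQSCluster, ann: RepeatAnnotation, flank: int = 200) -> ZoneAssignment:
    """Assign one hit relative to one element.

    Inside iff an end of the hit (start or last base) lies in
    ``[geno_start, geno_end)``; otherwise the hit is assigned to whichever
    flanking window it intersects, with upstream/downstream oriented by the
    element's strand.  A hit spanning the whole element without an end
    inside is assigned to the flank with the larger overlap (ties 5').
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if hit.chrom is not None and hit.chrom != ann.chrom:
        raise ValueError(
            f"hit on {hit.chrom} cannot be classified against element on {ann.chrom}"
        )
    gs, ge = ann.geno_start, ann.geno_end
    if gs <= hit.start < ge or gs <= hit.end - 1 < ge:
        zone = "inside"
    else:
        left = max(0, min(hit.end, gs) - max(hit.start, gs - flank))
        right = max(0, min(hit.end, ge + flank) - max(hit.start, ge))
        if left == 0 and right == 0:
            zone = "unassigned"
        else:
            side = "left" if left >= right else "right"
            if ann.strand == "+":
                zone = "upstream" if side == "left" else "downstream"
            else:
                zone = "downstream" if side == "left" else "upstream"
    return ZoneAssignment(element_id=ann.element_id, zone=zone, hit=hit)


def assign_zones(
    hits: Sequence[PQSCluster],
    annotations: Sequence[RepeatAnnotation],
    flank: int = 200,
) -> list[ZoneAssignment]:
    """Classify every hit against every element whose window it overlaps.

    A hit lying within reach of two elements yields one assignment per
    (hit, element) pair.  Hits must carry genome coordinates (``chrom``).
    """
    trees: dict[str, IntervalTree] = {}
    by_id = {}
    for ann in annotations:
        t = trees.setdefault(ann.chrom, IntervalTree())
        t.addi(ann.geno_start - flank, ann.geno_end + flank, ann)
        by_id[ann.element_id] = ann
    out: list[ZoneAssignment] = []
    for hit in hits:
        if hit.chrom is None:
            raise ValueError(f"hit on {hit.source_id!r} lacks genome coordinates")
        tree = trees.get(hit.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(hit.start, hit.end), key=lambda iv: (iv.begin, iv.data.element_id)):
            za = classify_zone(hit, iv.data, flank)
            if za.zone != "unassigned":
                za.family_key = resolve_family_key(iv.data)
                out.append(za)
    return out


def zone_density(
    assignments: Sequence[ZoneAssignment],
    annotations: Sequence[RepeatAnnotation],
    flank: int = 200,
    rule: FullLengthRule | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-100 bp PQS densities inside / upstream / downstream per stratum.

    Strata are family x hit strand label x length class ({all, full_length}).
    Denominators sum element lengths (inside) and flank lengths (up- and
    downstream); flank bp truncated at chromosome ends are excluded from the
    denominator when ``chrom_lengths`` is provided.  Empty strata appear
    with density 0 and their bp total.
    """
    rule = rule or FullLengthRule()
    anns = {a.element_id: a for a in annotations}

    # per (family, length_class) zone bp denominators
    zone_bp: dict[tuple[str, str, str], int] = {}
    membership: dict[str, list[str]] = {}
    for ann in annotations:
        fam = resolve_family_key(ann)
        if fam is None:
            continue
        fl = is_full_length(ann, rule)
        classes = ["all"] + (["full_length"] if fl else [])
        membership[ann.element_id] = classes
        lf = min(flank, ann.geno_start) if chrom_lengths else flank
        if chrom_lengths:
            rf = min(flank, chrom_lengths.get(ann.chrom, ann.geno_end + flank) - ann.geno_end)
        else:
            rf = flank
        up_bp, down_bp = (lf, rf) if ann.strand == "+" else (rf, lf)
        for lc in classes:
            zone_bp[(fam, lc, "inside")] = zone_bp.get((fam, lc, "inside"), 0) + ann.length
            zone_bp[(fam, lc, "upstream")] = zone_bp.get((fam, lc, "upstream"), 0) + up_bp
            zone_bp[(fam, lc, "downstream")] = zone_bp.get((fam, lc, "downstream"), 0) + down_bp

    counts: dict[tuple[str, str, str, str], int] = {}
    for za in assignments:
        ann = anns.get(za.element_id)
        if ann is None:
            continue
        fam = za.family_key or resolve_family_key(ann)
        if fam is None or za.zone == "unassigned":
            continue
        for lc in membership.get(ann.element_id, []):
            key = (fam, za.hit.strand_label, lc, za.zone)
            counts[key] = counts.get(key, 0) + 1

    families = sorted({k[0] for k in zone_bp})
    strands = ("PQS3+", "PQS3-")
    rows = []
    for fam in families:
        for strand in strands:
            for lc in ("all", "full_length"):
                for zone in ZONES:
                    bp = zone_bp.get((fam, lc, zone), 0)
                    n = counts.get((fam, strand, lc, zone), 0)
                    rows.append(
                        {
                            "family": fam,
                            "strand_label": strand,
                            "length_class": lc,
                            "zone": zone,
                            "n_pqs": n,
                            "zone_bp": bp,
                            "density_per_100bp": (100.0 * n / bp) if bp else 0.0,
                            "empty": bp == 0,
                        }
                    )
    return pd.DataFrame(rows)
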