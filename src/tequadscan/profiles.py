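"""Positional PQS density profiles in family consensus coordinates.

Hits assigned inside elements are projected (by cluster midpoint) into the
family's consensus coordinate system, pooling all copies: annotations that
carry consensus coordinates are interpolated linearly within
``[cons_start, cons_end)``; annotations without them are scaled linearly to
a configured consensus length.  Copies on the genome minus strand are
reflected so position 0 is always the element's 5' end, and the hit strand
label is flipped accordingly, so ``PQS3+`` always means the element-sense
strand.

Profiles are sliding-window counts per stratum (strand label x chromosome
class), with a Markov-null expectation and a dataset-wide reference density
attachable per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import RepeatAnnotation, chromosome_class
from .context import ZoneAssignment
from .scanner import PQSCluster

__all__ = [
    "FamilyProfile",
    "project_to_consensus",
    "build_profile",
    "reference_density",
    "default_window",
]

_FLIP = {"PQS3+": "PQS3-", "PQS3-": "PQS3+"}

STRANDS = ("PQS3+", "PQS3-")
CHROM_CLASSES = ("autosome", "X", "Y")


def default_window(consensus_length: int) -> int:
    """Window length for a family: consensus_length/50 clamped to [40, 120]."""
    return int(min(120, max(40, consensus_length // 50)))


def project_to_consensus(
    hit: PQSCluster,
    ann: RepeatAnnotation,
    consensus_length: int | None = None,
) -> tuple[float, str]:
    """Project an inside hit's midpoint to consensus space.

    Returns ``(consensus_position, oriented_strand_label)``.  Raises when
    the hit midpoint does not fall within the element (projection is defined
    for inside hits).
    """
    gs, ge = ann.geno_start, ann.geno_end
    m = hit.midpoint
    if not (gs <= m < ge):
        raise ValueError(
            f"hit [{hit.start},{hit.end}) midpoint not inside element "
            f"[{gs},{ge}); projection requires an inside hit"
        )
    rel = (m - gs) if ann.strand == "+" else (ge - m)
    frac = rel / (ge - gs)
    if ann.cons_start is not None:
        pos = ann.cons_start + frac * (ann.cons_end - ann.cons_start)
    elif consensus_length is not None:
        pos = frac * consensus_length
    else:
        raise ValueError(
            f"{ann.element_id}: no consensus coordinates and no configured "
            "consensus length"
        )
    label = hit.strand_label if ann.strand == "+" else _FLIP[hit.strand_label]
    return float(pos), label


@dataclass
class FamilyProfile:
    """Sliding-window PQS counts along a family consensus.

    ``counts[stratum]`` holds one count per window; strata are
    (strand_label, chromosome_class).  ``null_density`` and
    ``reference_density`` are per-window expectations (scalars broadcast
    over windows).
    """

    family: str
    consensus_length: int
    window_len: int
    stride: int
    window_starts: np.ndarray
    counts: dict[tuple[str, str], np.ndarray]
    n_elements: int
    n_hits: int
    null_density: float | None = None
    reference_density: float | None = None
    projection_modes: dict[str, int] = field(default_factory=dict)

    @property
    def window_ends(self) -> np.ndarray:
        return np.minimum(self.window_starts + self.window_len, self.consensus_length)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (strand, cclass), c in sorted(self.counts.items()):
            for ws, we, n in zip(self.window_starts, self.window_ends, c):
                rows.append(
                    {
                        "family": self.family,
                        "window_start": int(ws),
                        "window_end": int(we),
                        "strand_label": strand,
                        "chrom_class": cclass,
                        "count": int(n),
                        "null_expected": self.null_density,
                        "reference_expected": self.reference_density,
                    }
                )
        return pd.DataFrame(rows)

    def pooled(self, strand: str | None = None) -> np.ndarray:
        """Counts summed over strata (optionally one strand only)."""
        total = np.zeros(len(self.window_starts))
        for (s, _), c in self.counts.items():
            if strand is None or s == strand:
                total = total + c
        return total


def build_profile(
    assignments: Sequence[ZoneAssignment],
    annotations: Sequence[RepeatAnnotation],
    family: str,
    consensus_length: int,
    window_len: int | None = None,
    stride: int | None = None,
    family_key_fn=None,
) -> FamilyProfile:
    """Build the positional profile of one family.

    ``assignments`` are zone assignments (only ``inside`` ones contribute);
    ``family`` selects annotations via ``family_key_fn`` (defaults to the
    standard family-key resolver).  Window defaults to
    ``consensus_length/50`` clamped to [40, 120] with stride = window/2; a
    tiled profile is obtained with ``stride == window_len``.
    """
    from .context import resolve_family_key

    key_fn = family_key_fn or resolve_family_key
    if window_len is None:
        window_len = default_window(consensus_length)
    if not (40 <= window_len <= 120):
        raise ValueError("window_len must lie in [40, 120]")
    if stride is None:
        stride = max(1, window_len // 2)
    if stride > window_len:
        raise ValueError("stride must be <= window_len")

    anns = {a.element_id: a for a in annotations if key_fn(a) == family}
    window_starts = np.arange(0, max(consensus_length - window_len, 0) + stride, stride)
    window_starts = window_starts[window_starts < consensus_length]
    nw = len(window_starts)
    counts = {(s, c): np.zeros(nw, dtype=int) for s in STRANDS for c in CHROM_CLASSES + ("other",)}
    modes = {"consensus_coords": 0, "length_scaled": 0}
    n_hits = 0
    for za in assignments:
        if za.zone != "inside":
            continue
        ann = anns.get(za.element_id)
        if ann is None:
            continue
        pos, label = project_to_consensus(za.hit, ann, consensus_length)
        modes["consensus_coords" if ann.cons_start is not None else "length_scaled"] += 1
        cclass = chromosome_class(ann.chrom)
        pos = min(pos, consensus_length - 1e-9)
        in_window = (window_starts <= pos) & (pos < window_starts + window_len)
        counts[(label, cclass)][in_window] += 1
        n_hits += 1
    counts = {k: v for k, v in counts.items() if k[1] != "other" or v.any()}
    return FamilyProfile(
        family=family,
        consensus_length=consensus_length,
        window_len=window_len,
        stride=stride,
        window_starts=window_starts,
        counts=counts,
        n_elements=len(anns),
        n_hits=n_hits,
        projection_modes=modes,
    )


def reference_density(
    total_hits: int, dataset_bp: int, window_len: int, n_elements: int = 1
) -> float:
    """Dataset-wide mean PQS density recast to an expected count per window.

    hits-per-bp x window length x number of contributing elements: the count
    a profile window would show if PQS were spread uniformly at the
    dataset-wide rate.
    """
    if dataset_bp <= 0:
        raise ValueError("dataset_bp must be > 0")
    return total_hits / dataset_bp * window_len * n_elements
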