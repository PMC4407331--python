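"""Stratified PQS abundance summaries.

Element-level aggregation of inside-assigned PQS hits: percent of elements
containing at least one PQS per family, abundance ordered by subfamily age
(SVA A-F; Alu J/S/Y with the young AluYa5/AluYg6 set), the full-length vs
truncated and active-subfamily contrasts for L1, all stratified by
chromosome class and hit strand.

"Abundance" is operationalized as PQS per element, with a per-kb variant
emitted alongside.  The age trend is summarized by Kendall's tau between
age rank (old -> young) and per-subfamily abundance, with a seeded
permutation p-value (subfamily labels permuted across elements); the trend
statistic is an extension of this package and marked as such in output
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import RepeatAnnotation, chromosome_class
from .context import FullLengthRule, ZoneAssignment, is_full_length, resolve_family_key

__all__ = [
    "AgeOrder",
    "element_table",
    "percent_with_pqs",
    "age_trend",
    "length_activity_contrast",
]


@dataclass(frozen=True)
class AgeOrder:
    """Ordered subfamily groups per family, oldest first.

    ``match`` maps an annotation rep_name to its group label, or ``other``
    when no group matches.
    """

    family: str
    groups: tuple[tuple[str, tuple[str, ...]], ...]  # (label, name prefixes)

    def match(self, rep_name: str) -> str:
        for label, prefixes in self.groups:
            if any(rep_name.startswith(p) for p in prefixes):
                return label
        return "other"

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]


SVA_AGE = AgeOrder(
    "SVA",
    (
        ("SVA_A", ("SVA_A",)),
        ("SVA_B", ("SVA_B",)),
        ("SVA_C", ("SVA_C",)),
        ("SVA_D", ("SVA_D",)),
        ("SVA_E", ("SVA_E",)),
        ("SVA_F", ("SVA_F",)),
    ),
)

# youngest subfamilies are listed before the broad AluY bucket so they match first
ALU_AGE = AgeOrder(
    "Alu",
    (
        ("AluJ", ("AluJ",)),
        ("AluS", ("AluS",)),
        ("AluY", ("AluY",)),
    ),
)

ALU_YOUNG = ("AluYa5", "AluYg6")
L1_ACTIVE = ("L1HS", "L1PA2")


def element_table(
    annotations: Sequence[RepeatAnnotation],
    assignments: Sequence[ZoneAssignment],
    rule: FullLengthRule | None = None,
) -> pd.DataFrame:
    """One row per element with its inside-PQS counts and stratifiers.

    Columns: element_id, family (resolved key), rep_name, chrom_class,
    strand, length, full_length (True/False/None), n_pqs, n_pqs_plus,
    n_pqs_minus, has_pqs, pqs_per_kb.  Strand labels are element-oriented
    (flipped for minus-strand copies) so PQS3+ means element-sense.
    """
    rule = rule or FullLengthRule()
    inside_counts: dict[str, dict[str, int]] = {}
    for za in assignments:
        if za.zone != "inside":
            continue
        d = inside_counts.setdefault(za.element_id, {"PQS3+": 0, "PQS3-": 0})
        d[za.hit.strand_label] += 1
    rows = []
    for ann in annotations:
        c = inside_counts.get(ann.element_id, {"PQS3+": 0, "PQS3-": 0})
        plus, minus = c["PQS3+"], c["PQS3-"]
        if ann.strand == "-":
            plus, minus = minus, plus
        n = plus + minus
        rows.append(
            {
                "element_id": ann.element_id,
                "family": resolve_family_key(ann),
                "rep_name": ann.rep_name,
                "chrom_class": chromosome_class(ann.chrom),
                "strand": ann.strand,
                "length": ann.length,
                "full_length": is_full_length(ann, rule),
                "n_pqs": n,
                "n_pqs_plus": plus,
                "n_pqs_minus": minus,
                "has_pqs": n > 0,
                "pqs_per_kb": 1000.0 * n / ann.length,
            }
        )
    return pd.DataFrame(rows)


def _summarize(group: pd.DataFrame) -> dict:
    n = len(group)
    n_with = int(group["has_pqs"].sum())
    n_pqs = int(group["n_pqs"].sum())
    return {
        "n_elements": n,
        "n_elements_with_pqs": n_with,
        "n_pqs": n_pqs,
        "pqs_per_element": (n_pqs / n) if n else 0.0,
        "pqs_per_kb": (1000.0 * n_pqs / group["length"].sum()) if n else 0.0,
        "pct_elements_with_pqs": (100.0 * n_with / n) if n else 0.0,
        "empty": n == 0,
    }


def percent_with_pqs(
    elements: pd.DataFrame, stratifiers: Sequence[str] = ("family",)
) -> pd.DataFrame:
    """Abundance summary rows per stratifier combination.

    An element counts as "with PQS" iff at least one hit was assigned inside
    it.  Empty strata are flagged, never a division error.
    """
    if elements.empty:
        return pd.DataFrame()
    rows = []
    for key, group in elements.groupby(list(stratifiers), dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        row = dict(zip(stratifiers, key))
        row.update(_summarize(group))
        rows.append(row)
    return pd.DataFrame(rows)


def age_trend(
    elements: pd.DataFrame,
    age_order: AgeOrder,
    value: str = "pqs_per_element",
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-subfamily abundance ordered old -> young, plus a trend statistic.

    Kendall's tau between age rank and per-subfamily abundance with a
    one-sided (positive-trend) permutation p-value: element subfamily labels
    are permuted ``n_permutations`` times (seeded) and tau recomputed on the
    per-subfamily means.  With fewer than two populated subfamilies the
    trend is undefined (tau/p = NaN) while rows are still emitted.
    """
    sub = elements[elements["family"] == age_order.family].copy()
    sub["age_group"] = [age_order.match(n) for n in sub["rep_name"]]
    sub = sub[sub["age_group"] != "other"]
    rows = []
    for rank, label in enumerate(age_order.labels):
        group = sub[sub["age_group"] == label]
        row = {"age_group": label, "age_rank": rank}
        row.update(_summarize(group))
        rows.append(row)
    table = pd.DataFrame(rows)

    populated = table[table["n_elements"] > 0]
    result = {
        "tau": float("nan"),
        "p_value": float("nan"),
        "n_permutations": n_permutations,
        "seed": seed,
        "statistic": "kendall_tau(age_rank, %s), permutation one-sided; "
        "package extension, not reported by the underlying study design" % value,
    }
    if len(populated) >= 2 and not sub.empty:
        per_el = sub["n_pqs"].to_numpy(dtype=float)
        if value == "pqs_per_kb":
            per_el = sub["pqs_per_kb"].to_numpy(dtype=float)
        labels = sub["age_group"].to_numpy()
        ranks = {label: r for r, label in enumerate(age_order.labels)}

        def tau_of(lab: np.ndarray) -> float:
            means, rk = [], []
            for label, r in ranks.items():
                mask = lab == label
                if mask.any():
                    means.append(per_el[mask].mean())
                    rk.append(r)
            if len(means) < 2:
                return np.nan
            if np.allclose(means, means[0]):
                return 0.0  # no trend: constant abundance across subfamilies
            return stats.kendalltau(rk, means).statistic

        tau_obs = tau_of(labels)
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            t = tau_of(rng.permutation(labels))
            if not np.isnan(t) and t >= tau_obs:
                hits += 1
        result["tau"] = float(tau_obs)
        result["p_value"] = (1 + hits) / (1 + n_permutations)
    return table, result


def length_activity_contrast(
    elements: pd.DataFrame,
    active_set: Sequence[str] = L1_ACTIVE,
    family: str = "L1",
    by_chrom_class: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Abundance of all / full-length / truncated elements and the active set.

    Returns per-stratum rows ({all, full_length, truncated} x {all elements,
    active subfamilies} x chromosome class) and headline contrast ratios:
    full-length vs truncated PQS per element, and active full-length vs all
    full-length.
    """
    sub = elements[elements["family"] == family].copy()
    sub = sub[sub["full_length"].notna()]
    sub["length_class"] = np.where(sub["full_length"].astype(bool), "full_length", "truncated")
    sub["activity"] = np.where(sub["rep_name"].isin(list(active_set)), "active", "other")

    rows = []
    groups = [("all", sub), ("active", sub[sub["activity"] == "active"])]
    cclasses = ["all"] + (sorted(sub["chrom_class"].unique()) if by_chrom_class else [])
    for gname, gdf in groups:
        for lc in ("all", "full_length", "truncated"):
            ldf = gdf if lc == "all" else gdf[gdf["length_class"] == lc]
            for cc in cclasses:
                cdf = ldf if cc == "all" else ldf[ldf["chrom_class"] == cc]
                row = {"group": gname, "length_class": lc, "chrom_class": cc}
                row.update(_summarize(cdf))
                rows.append(row)
    table = pd.DataFrame(rows)

    def mean_of(gname, lc):
        m = table[
            (table["group"] == gname)
            & (table["length_class"] == lc)
            & (table["chrom_class"] == "all")
        ]
        return float(m["pqs_per_element"].iloc[0]) if len(m) else float("nan")

    fl, tr = mean_of("all", "full_length"), mean_of("all", "truncated")
    afl = mean_of("active", "full_length")
    ratios = {
        "full_vs_truncated": fl / tr if tr else float("inf") if fl else float("nan"),
        "active_full_vs_full": afl / fl if fl else float("nan"),
    }
    return table, ratios
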