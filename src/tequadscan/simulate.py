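"""Synthetic genomes with planted transposable-element families and PQS.

The generator emulates the statistical structure the analysis pipeline is
built for: a background genome with TE copies inserted on random strands,
each family carrying PQS-dense segments at fixed consensus positions
(3'-terminal and 5'-UTR segments for the L1-like family; a 5' hexamer-
repeat minus-strand segment and a central VNTR-like plus-strand segment for
the SVA-like family; an LTR segment for the HERV-like family; a near-5'
segment for the Alu-like family), 5'-truncation of a configurable fraction
of copies, and subfamily series of increasing per-base divergence emulating
age (older copies accumulate substitutions that degrade G-runs and thereby
destroy PQS).

Mutations are i.i.d. substitutions, uniform over alternative bases; indels
are not modelled.  Every quantity is reproducible from the spec seed.

The twelve oligonucleotides used for the conformational work are bundled
as an in-package fixture (:func:`table1_fixture`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import RepeatAnnotation, SequenceRecord, write_fasta, write_rmsk_table
from . import __version__
from .scanner import ScanParams, revcomp, scan_both

__all__ = [
    "FamilySpec",
    "SyntheticSpec",
    "make_genome",
    "write_genome",
    "demo_spec",
    "table1_fixture",
    "TABLE1_SEQUENCES",
    "TABLE1_EXPECTED_LENGTHS",
]

# ---------------------------------------------------------------------------
# Bundled oligonucleotide fixture (12 sequences with their printed lengths)
# ---------------------------------------------------------------------------

TABLE1_SEQUENCES: dict[str, str] = {
    "L1_1": "TAGGTGCTCGGGGTCAGGGGTCAGGGGTCAGGGACCCACTTG",
    "L1_2": "ATCACACTCTGGGGTGTTGTGGGTGGGGGGAGGGGGGAGGATAGCATTGGGAGATATACC",
    "HERV_1": "AAAGAGTCAGGGAAGGGAGATAAGGGTGGGGCCGTTTTAT",
    "HERV_2": "TAAATTGCTGGGCAGGGGGGGAGGGCTAGTCACG",
    "SVA-A_HEX": "GGAGATCAAGGGAAAGGGGGAGAGGGAGAGGGAGAGGCCAA",
    "SVA-CF_VNTR": "CGCCCGTCCGGGAGGGAGGTGGGGGGGGTCAGCCCCC",
    "SVA-C_HEX": "GGAGACCGTGGGGAGAGGGAGAGGGAGGGGGAGAGGAGAC",
    "SVA-BF_VNTR": "GCCCCGTCCGGGAGGGAGGTGGGGGGGTCAGCCCCC",
    "SVA-F_HEX": "GGAGAGAGAGGGAGAGGGAGAGGGAGAGGGAGAGGGAGAGTGCTG",
    "SVA-F_VNTR": "GTGCCATCCGGGAGGGAGGTGGGGGGGTCAGCCCCC",
    "ALU-S_1": "CCAGCACTTTGGGAGGCCGGGTGGGTGGGTCACCTGAGG",
    "ALU-S_2": "CCAGCACTTTGGGAGGGTGGGTGGGTGGATCACTT",
}

TABLE1_EXPECTED_LENGTHS: dict[str, int] = {
    "L1_1": 42,
    "L1_2": 60,
    "HERV_1": 40,
    "HERV_2": 34,
    "SVA-A_HEX": 41,
    "SVA-CF_VNTR": 37,
    "SVA-C_HEX": 40,
    "SVA-BF_VNTR": 36,
    "SVA-F_HEX": 45,
    "SVA-F_VNTR": 36,
    "ALU-S_1": 39,
    "ALU-S_2": 35,
}


def table1_fixture() -> list[SequenceRecord]:
    """The 12 bundled oligonucleotide records, in table order."""
    return [SequenceRecord(record_id=name, seq=seq) for name, seq in TABLE1_SEQUENCES.items()]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySpec:
    """One synthetic TE family.

    ``pqs_segments`` are (label, cons_start, cons_end, strand) intervals of
    the consensus carrying planted PQS; the rest of the consensus is kept
    PQS-free on both strands.  ``subfamilies`` is a series of
    (rep_name, n_copies, divergence) emulating age, oldest typically having
    the largest divergence.  Truncation removes a 5' prefix: a copy is
    full-length with probability ``full_length_prob``, otherwise it keeps a
    consensus suffix fraction drawn uniformly from ``truncated_keep``.
    """

    name: str
    rep_class: str
    rep_family: str
    consensus_length: int
    pqs_segments: tuple[tuple[str, int, int, str], ...]
    subfamilies: tuple[tuple[str, int, float], ...]
    full_length_prob: float = 0.5
    truncated_keep: tuple[float, float] = (0.2, 0.7)

    def __post_init__(self) -> None:
        for _, n, d in self.subfamilies:
            if not (0.0 <= d <= 0.3):
                raise ValueError(f"divergence {d} outside [0, 0.3]")
            if n < 0:
                raise ValueError("negative copy number")
        for label, a, b, s in self.pqs_segments:
            if not (0 <= a < b <= self.consensus_length):
                raise ValueError(f"segment {label} outside consensus")
            if s not in ("+", "-"):
                raise ValueError(f"segment {label}: bad strand {s!r}")

    @property
    def n_copies(self) -> int:
        return sum(n for _, n, _ in self.subfamilies)


@dataclass(frozen=True)
class SyntheticSpec:
    """A full synthetic genome: background plus planted families."""

    seed: int
    genome_len: int = 2_000_000
    gc: float = 0.41
    chromosomes: tuple[tuple[str, float], ...] = (
        ("chr1", 0.40),
        ("chr2", 0.30),
        ("chrX", 0.20),
        ("chrY", 0.10),
    )
    families: tuple[FamilySpec, ...] = ()
    min_gap: int = 500


# ---------------------------------------------------------------------------
# Sequence construction helpers
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _at_random(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("AT"))[rng.integers(0, 2, size=n)])


def _pqs_free_dna(rng: np.random.Generator, n: int, gc: float, params: ScanParams) -> str:
    """Random DNA with any accidental PQS overwritten by A/T sequence."""
    seq = list(_random_dna(rng, n, gc))
    for _ in range(20):
        hits = scan_both("".join(seq), params)
        if not hits:
            break
        for h in hits:
            seq[h.start : h.end] = list(_at_random(rng, h.end - h.start))
    return "".join(seq)


def _cassette(rng: np.random.Generator, cores: Sequence[str], length: int, spacer: int = 20) -> str:
    """Planted-PQS segment: cores separated/padded by A/T spacers to ``length``."""
    need = sum(len(c) for c in cores) + spacer * (len(cores) + 1)
    if need > length:
        raise ValueError(f"cassette cores do not fit in {length} bp")
    pad = length - need
    pieces = [_at_random(rng, spacer + (pad if i == 0 else 0)) for i in range(1)]
    out = [pieces[0]]
    for i, core in enumerate(cores):
        out.append(core)
        out.append(_at_random(rng, spacer))
    return "".join(out)


# PQS cores used in planted segments (derived from the bundled oligo motifs)
_L1_5UTR_CORE = "GGGGTCAGGGGTCAGGGGTCAGGG"
_L1_3UTR_CORE = "GGGGTGTTGTGGGTGGGGGGAGGGGGG"
_SVA_HEX_UNIT = "CCCTCT"
_SVA_VNTR_UNIT = "GTGCCATCCGGGAGGGAGGTGGGGGGGTCAGCCCCC"
_HERV_LTR_CORE = "GGGAAGGGAGATAAGGGTGGGG"
_HERV_INT_CORE = "GGGCAGGGGGGGAGGG"
_ALU_CORE = "GGGAGGGTGGGTGGG"


def _build_consensus(rng: np.random.Generator, fam: FamilySpec, gc: float, params: ScanParams) -> str:
    """Family consensus: PQS-free background with planted segments pasted in."""
    L = fam.consensus_length
    seq = list(_pqs_free_dna(rng, L, gc, params))
    for label, a, b, strand in fam.pqs_segments:
        n = b - a
        if label == "hex":
            content = (_SVA_HEX_UNIT * (n // len(_SVA_HEX_UNIT) + 1))[:n]
        elif label == "vntr":
            reps = n // len(_SVA_VNTR_UNIT)
            content = (_SVA_VNTR_UNIT * reps) + _at_random(rng, n - reps * len(_SVA_VNTR_UNIT))
        elif label == "utr5":
            content = _cassette(rng, [_L1_5UTR_CORE], n)
        elif label == "utr3":
            content = _cassette(rng, [_L1_3UTR_CORE] * 4, n)
        elif label == "ltr":
            content = _cassette(rng, [_HERV_LTR_CORE], n)
        elif label == "internal":
            content = _cassette(rng, [revcomp(_HERV_INT_CORE)], n)
        elif label == "left_monomer":
            content = _cassette(rng, [_ALU_CORE], n, spacer=10)
        else:
            raise ValueError(f"unknown planted segment label {label!r}")
        if strand == "-" and label not in ("hex", "internal"):
            content = revcomp(content)
        seq[a:b] = list(content)
    return "".join(seq)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(seq)) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        cur = arr[i].decode()
        alts = [b for b in "ACGT" if b != cur]
        arr[i] = alts[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


def demo_spec(seed: int = 7, scale: float = 1.0) -> SyntheticSpec:
    """The documented demo genome: 2 Mb, four TE-like families.

    ``scale`` < 1 shrinks copy numbers and genome length proportionally for
    quick runs; the family structure is unchanged.
    """

    def s(n: int) -> int:
        return max(2, int(round(n * scale)))

    l1 = FamilySpec(
        name="L1",
        rep_class="LINE",
        rep_family="L1",
        consensus_length=6000,
        pqs_segments=(("utr5", 100, 220, "+"), ("utr3", 5640, 6000, "+")),
        subfamilies=(
            ("L1HS", s(16), 0.004),
            ("L1PA2", s(20), 0.010),
            ("L1PA7", s(40), 0.050),
            ("L1MA4", s(44), 0.120),
        ),
        full_length_prob=0.35,
        truncated_keep=(0.08, 0.75),
    )
    sva = FamilySpec(
        name="SVA",
        rep_class="Retroposon",
        rep_family="SVA",
        consensus_length=2000,
        pqs_segments=(("hex", 0, 180, "-"), ("vntr", 700, 1060, "+")),
        subfamilies=(
            ("SVA_A", s(15), 0.130),
            ("SVA_B", s(15), 0.100),
            ("SVA_C", s(15), 0.070),
            ("SVA_D", s(15), 0.045),
            ("SVA_E", s(15), 0.025),
            ("SVA_F", s(15), 0.008),
        ),
        full_length_prob=0.85,
        truncated_keep=(0.40, 0.75),
    )
    alu = FamilySpec(
        name="Alu",
        rep_class="SINE",
        rep_family="Alu",
        consensus_length=300,
        pqs_segments=(("left_monomer", 35, 75, "+"),),
        subfamilies=(
            ("AluJb", s(32), 0.130),
            ("AluSx", s(48), 0.090),
            ("AluY", s(28), 0.030),
            ("AluYa5", s(12), 0.010),
        ),
        full_length_prob=0.90,
        truncated_keep=(0.50, 0.80),
    )
    herv_ltr = FamilySpec(
        name="HERV_ltr",
        rep_class="LTR",
        rep_family="ERV1",
        consensus_length=400,
        pqs_segments=(("ltr", 150, 215, "+"),),
        subfamilies=(("LTR5X", s(14), 0.080),),
        full_length_prob=0.90,
        truncated_keep=(0.40, 0.70),
    )
    herv_int = FamilySpec(
        name="HERV_internal",
        rep_class="LTR",
        rep_family="ERV1",
        consensus_length=3000,
        pqs_segments=(("internal", 1400, 1460, "-"),),
        subfamilies=(("HERVX-int", s(10), 0.080),),
        full_length_prob=0.70,
        truncated_keep=(0.30, 0.60),
    )
    return SyntheticSpec(
        seed=seed,
        genome_len=int(2_000_000 * scale),
        families=(l1, sva, alu, herv_ltr, herv_int),
    )


@dataclass
class _Copy:
    fam: FamilySpec
    rep_name: str
    seq: str  # mutated, element-oriented (consensus orientation)
    cons_start: int
    cons_end: int
    strand: str
    element_id: str


def make_genome(
    spec: SyntheticSpec, params: ScanParams | None = None
) -> tuple[dict[str, str], list[RepeatAnnotation], pd.DataFrame]:
    """Assemble the synthetic genome.

    Returns ``(genome, annotations, truth)``: chromosome sequences, rmsk-
    style annotations with consensus coordinates reflecting truncation, and
    the truth table of surviving planted PQS: every PQS cluster found by
    re-scanning each mutated copy, lifted to genome coordinates and genome-
    strand labels, tagged with the designated consensus segment it falls in
    (or ``background``).
    """
    params = params or ScanParams()
    rng_cons = np.random.default_rng([spec.seed, 0])
    rng_copy = np.random.default_rng([spec.seed, 1])
    rng_bg = np.random.default_rng([spec.seed, 2])
    rng_place = np.random.default_rng([spec.seed, 3])

    consensi = {fam.name: _build_consensus(rng_cons, fam, spec.gc, params) for fam in spec.families}

    copies: list[_Copy] = []
    counter = 0
    for fam in spec.families:
        cons = consensi[fam.name]
        L = fam.consensus_length
        for rep_name, n, div in fam.subfamilies:
            for _ in range(n):
                if rng_copy.random() < fam.full_length_prob:
                    keep = L
                else:
                    lo, hi = fam.truncated_keep
                    keep = int(round(L * rng_copy.uniform(lo, hi)))
                keep = max(keep, 30)
                cs, ce = L - keep, L
                seq = _mutate(rng_copy, cons[cs:ce], div)
                strand = "+" if rng_copy.random() < 0.5 else "-"
                copies.append(
                    _Copy(fam, rep_name, seq, cs, ce, strand, f"{rep_name}.{counter}")
                )
                counter += 1

    total_copy_bp = sum(len(c.seq) for c in copies)
    if total_copy_bp + (len(copies) + len(spec.chromosomes)) * spec.min_gap > spec.genome_len:
        raise ValueError("insertions exceed genome_len")

    # distribute copies over chromosomes in random order, weighted by the
    # remaining free space so density stays comparable across chromosomes
    order = rng_place.permutation(len(copies))
    chrom_names = [c for c, _ in spec.chromosomes]
    chrom_len = {c: int(spec.genome_len * w) for c, w in spec.chromosomes}
    budget = {
        c: chrom_len[c] - spec.min_gap for c in chrom_names
    }  # reserve a trailing gap
    per_chrom: dict[str, list[_Copy]] = {c: [] for c in chrom_names}
    for i in order:
        c = copies[i]
        need = len(c.seq) + spec.min_gap
        open_names = [n for n in chrom_names if budget[n] >= need]
        if not open_names:
            raise ValueError("insertions exceed genome_len")
        w = np.array([budget[n] for n in open_names], dtype=float)
        choice = open_names[int(rng_place.choice(len(open_names), p=w / w.sum()))]
        per_chrom[choice].append(c)
        budget[choice] -= need

    genome: dict[str, str] = {}
    annotations: list[RepeatAnnotation] = []
    truth_rows: list[dict] = []
    for name in chrom_names:
        chosen = per_chrom[name]
        n = len(chosen)
        free = chrom_len[name] - sum(len(c.seq) for c in chosen) - (n + 1) * spec.min_gap
        extra = rng_place.multinomial(free, np.full(n + 1, 1.0 / (n + 1))) if free > 0 else np.zeros(n + 1, int)
        gaps = [spec.min_gap + int(e) for e in extra]
        parts = []
        pos = 0
        for i, c in enumerate(chosen):
            parts.append(_random_dna(rng_bg, gaps[i], spec.gc))
            pos += gaps[i]
            gstart, gend = pos, pos + len(c.seq)
            inserted = c.seq if c.strand == "+" else revcomp(c.seq)
            parts.append(inserted)
            pos = gend
            annotations.append(
                RepeatAnnotation(
                    chrom=name,
                    geno_start=gstart,
                    geno_end=gend,
                    strand=c.strand,
                    rep_name=c.rep_name,
                    rep_class=c.fam.rep_class,
                    rep_family=c.fam.rep_family,
                    cons_start=c.cons_start,
                    cons_end=c.cons_end,
                    element_id=c.element_id,
                )
            )
            for h in scan_both(c.seq, params):
                if c.strand == "+":
                    g0, g1 = gstart + h.start, gstart + h.end
                    label = h.strand_label
                else:
                    g0, g1 = gend - h.end, gend - h.start
                    label = "PQS3-" if h.strand_label == "PQS3+" else "PQS3+"
                cons_mid = c.cons_start + h.midpoint
                segment = "background"
                for seg_label, a, b, seg_strand in c.fam.pqs_segments:
                    if a <= cons_mid < b:
                        segment = seg_label
                        break
                # clusters touching the copy boundary can be extended by
                # genomic context in a whole-genome scan (cluster maximality),
                # so their exact coordinates are context-dependent
                margin = params.loop_max + 1
                edge = h.start < margin or h.end > len(c.seq) - margin
                truth_rows.append(
                    {
                        "element_id": c.element_id,
                        "rep_name": c.rep_name,
                        "family": c.fam.name,
                        "chrom": name,
                        "start": g0,
                        "end": g1,
                        "strand_label": label,
                        "element_strand": c.strand,
                        "cons_mid": cons_mid,
                        "segment": segment,
                        "edge": edge,
                    }
                )
        parts.append(_random_dna(rng_bg, gaps[n], spec.gc))
        genome[name] = "".join(parts)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "element_id",
            "rep_name",
            "family",
            "chrom",
            "start",
            "end",
            "strand_label",
            "element_strand",
            "cons_mid",
            "segment",
            "edge",
        ],
    )
    return genome, annotations, truth


def write_genome(
    genome: dict[str, str],
    annotations: Sequence[RepeatAnnotation],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write genome FASTA, rmsk-style TSV and truth TSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "rmsk": outdir / "rmsk.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(
        [SequenceRecord(record_id=c, seq=s) for c, s in genome.items()], paths["fasta"]
    )
    write_rmsk_table(annotations, paths["rmsk"])
    with open(paths["truth"], "w") as fh:
        fh.write(f"# tequadscan v{__version__} synthetic truth table\n")
        truth.to_csv(fh, sep="\t", index=False)
    return paths
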