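"""Reading and writing the formats the pipeline touches.

Covers FASTA sequence input, RepeatMasker-style (rmsk) annotation tables,
the flanked-FASTA header dialect used to interchange extracted repeats, and
BED/TSV result output.  All coordinates are 0-based half-open internally;
1-based rmsk dialects are handled by an explicit flag on load.

Flanked-FASTA header dialect
----------------------------
Extracted repeat records carry their genomic position and repeat identity in
the header::

    >chrom:start-end(strand)|repName|repClass|repFamily|flank

e.g. ``>chr1:1000-1500(+)|L1HS|LINE|L1|200``.  ``start``/``end`` are 0-based
half-open coordinates of the record *including* flanks; ``flank`` is the
flank size in bp requested on each side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__

__all__ = [
    "RepeatAnnotation",
    "SequenceRecord",
    "chromosome_class",
    "read_fasta",
    "write_fasta",
    "parse_ucsc_header",
    "format_ucsc_header",
    "read_rmsk_table",
    "write_rmsk_table",
    "extract_records",
    "write_hits_bed",
    "hits_to_frame",
    "write_hits_tsv",
    "FormatError",
]

_VALID = set("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files or headers."""


@dataclass
class RepeatAnnotation:
    """One repeat interval with identity, strand and optional consensus span.

    Genomic coordinates are 0-based half-open.  ``cons_start``/``cons_end``
    locate the copy within its family consensus (0-based half-open) when the
    source table provides them.
    """

    chrom: str
    geno_start: int
    geno_end: int
    strand: str
    rep_name: str
    rep_class: str
    rep_family: str
    cons_start: int | None = None
    cons_end: int | None = None
    element_id: str = ""

    def __post_init__(self) -> None:
        if self.geno_start >= self.geno_end:
            raise ValueError(
                f"{self.element_id or self.rep_name}: geno_start >= geno_end "
                f"({self.geno_start} >= {self.geno_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if (self.cons_start is None) != (self.cons_end is None):
            raise ValueError("consensus coordinates must be given as a pair")
        if self.cons_start is not None and self.cons_start >= self.cons_end:
            raise ValueError("cons_start >= cons_end")

    @property
    def length(self) -> int:
        return self.geno_end - self.geno_start


@dataclass
class SequenceRecord:
    """A DNA sequence with optional genome origin and repeat linkage."""

    record_id: str
    seq: str
    origin: tuple[str, int, int, str] | None = None  # (chrom, start, end, strand)
    annotation_ref: str | None = None
    flank: int = 0

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.origin is not None:
            chrom, start, end, strand = self.origin
            if end - start != len(self.seq):
                raise ValueError(
                    f"{self.record_id}: origin span {end - start} != "
                    f"sequence length {len(self.seq)}"
                )


def chromosome_class(
    name: str,
    x_pattern: str = r"(chr)?X$",
    y_pattern: str = r"(chr)?Y$",
    autosome_pattern: str = r"(chr)?\d+$",
) -> str:
    """Classify a chromosome name as autosome / X / Y / other.

    Total: any name that matches none of the patterns maps to ``other``.
    """
    if re.fullmatch(x_pattern, name):
        return "X"
    if re.fullmatch(y_pattern, name):
        return "Y"
    if re.fullmatch(autosome_pattern, name):
        return "autosome"
    return "other"


def _normalize_seq(record_id: str, seq: str, invalid: str) -> str:
    s = seq.upper()
    if not s:
        raise FormatError(f"record {record_id!r}: empty sequence")
    if set(s) - _VALID:
        offending = sorted(set(s) - _VALID)
        if invalid == "strict":
            raise FormatError(
                f"record {record_id!r}: characters outside ACGTN: {offending}"
            )
        elif invalid == "to_n":
            s = re.sub(f"[^ACGTN]", "N", s)
        else:
            raise ValueError(f"unknown invalid-character policy {invalid!r}")
    return s


def read_fasta(
    path: str | Path, invalid: str = "strict", parse_headers: bool = False
) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects, order preserved.

    ``invalid`` is ``"strict"`` (reject characters outside ACGTN, naming the
    record) or ``"to_n"`` (map them to N).  With ``parse_headers=True`` each
    header is parsed as the flanked-FASTA dialect and origin/identity fields
    are populated.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_seq(rec.id, str(rec.seq), invalid)
        if parse_headers:
            origin, identity, flank = parse_ucsc_header(rec.description)
            out.append(
                SequenceRecord(
                    record_id=rec.id,
                    seq=seq,
                    origin=origin,
                    annotation_ref=identity[0],
                    flank=flank,
                )
            )
        else:
            out.append(SequenceRecord(record_id=rec.id, seq=seq))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.record_id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_HEADER_RE = re.compile(
    r"^(?P<chrom>[^:|\s]+):(?P<start>\d+)-(?P<end>\d+)"
    r"\((?P<strand>[+\-−])\)"
    r"\|(?P<name>[^|]+)\|(?P<cls>[^|]+)\|(?P<family>[^|]+)\|(?P<flank>\d+)$"
)

_HEADER_FIELDS = ("chrom:start-end", "(strand)", "repName", "repClass", "repFamily", "flank")


def parse_ucsc_header(header: str):
    """Parse the flanked-FASTA header dialect (see module docstring).

    Returns ``(origin, (name, cls, family), flank)`` where *origin* is
    ``(chrom, start, end, strand)`` with 0-based half-open coordinates.
    Raises :class:`FormatError` naming what is missing otherwise.
    """
    header = header.strip()
    m = _HEADER_RE.match(header)
    if not m:
        # diagnose the missing piece for a useful message
        missing = []
        if not re.search(r"[^:|\s]+:\d+-\d+", header):
            missing.append("chrom:start-end")
        if not re.search(r"\([+\-−]\)", header):
            missing.append("(strand)")
        if header.count("|") < 4:
            missing.append("identity/flank fields (need 4 '|'-separated)")
        raise FormatError(
            f"header {header!r} does not match "
            "'chrom:start-end(strand)|name|class|family|flank'"
            + (f"; missing: {', '.join(missing)}" if missing else "")
        )
    strand = m.group("strand")
    if strand == "−":  # unicode minus tolerated on input
        strand = "-"
    origin = (m.group("chrom"), int(m.group("start")), int(m.group("end")), strand)
    identity = (m.group("name"), m.group("cls"), m.group("family"))
    return origin, identity, int(m.group("flank"))


def format_ucsc_header(ann: RepeatAnnotation, start: int, end: int, flank: int) -> str:
    return (
        f"{ann.chrom}:{start}-{end}({ann.strand})"
        f"|{ann.rep_name}|{ann.rep_class}|{ann.rep_family}|{flank}"
    )


_RMSK_DEFAULT_COLUMNS = {
    "chrom": "chrom",
    "start": "genoStart",
    "end": "genoEnd",
    "strand": "strand",
    "rep_name": "repName",
    "rep_class": "repClass",
    "rep_family": "repFamily",
    "cons_start": "repStart",
    "cons_end": "repEnd",
    "element_id": "id",
}


def read_rmsk_table(
    path: str | Path,
    columns: dict[str, str] | None = None,
    one_based: bool = False,
) -> list[RepeatAnnotation]:
    """Read a RepeatMasker/UCSC-rmsk-style tab-separated annotation table.

    ``columns`` maps internal field names to column names in the file
    (defaults follow the UCSC rmsk track).  ``one_based=True`` decrements
    start coordinates on load for 1-based dialects; UCSC genoStart is
    already 0-based.  ``element_id`` falls back to the file-order row index
    when no ID column exists.
    """
    colmap = dict(_RMSK_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["chrom", "start", "end", "strand", "rep_name", "rep_class", "rep_family"]
    for key in required:
        if colmap[key] not in df.columns:
            raise FormatError(f"rmsk table missing required column {colmap[key]!r}")
    has_cons = colmap["cons_start"] in df.columns and colmap["cons_end"] in df.columns
    has_id = colmap["element_id"] in df.columns
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        start = int(rowd[colmap["start"]]) - (1 if one_based else 0)
        end = int(rowd[colmap["end"]])
        cons_start = cons_end = None
        if has_cons:
            cs, ce = rowd[colmap["cons_start"]], rowd[colmap["cons_end"]]
            if not (pd.isna(cs) or pd.isna(ce)):
                cons_start, cons_end = int(cs), int(ce)
        try:
            ann = RepeatAnnotation(
                chrom=str(rowd[colmap["chrom"]]),
                geno_start=start,
                geno_end=end,
                strand=str(rowd[colmap["strand"]]),
                rep_name=str(rowd[colmap["rep_name"]]),
                rep_class=str(rowd[colmap["rep_class"]]),
                rep_family=str(rowd[colmap["rep_family"]]),
                cons_start=cons_start,
                cons_end=cons_end,
                element_id=str(rowd[colmap["element_id"]]) if has_id else str(i),
            )
        except ValueError as exc:
            raise FormatError(f"row {i}: {exc}") from exc
        out.append(ann)
    return out


def write_rmsk_table(annotations: Sequence[RepeatAnnotation], path: str | Path) -> None:
    """Write annotations back out in UCSC rmsk column convention."""
    rows = []
    for ann in annotations:
        rows.append(
            {
                "chrom": ann.chrom,
                "genoStart": ann.geno_start,
                "genoEnd": ann.geno_end,
                "strand": ann.strand,
                "repName": ann.rep_name,
                "repClass": ann.rep_class,
                "repFamily": ann.rep_family,
                "repStart": "" if ann.cons_start is None else ann.cons_start,
                "repEnd": "" if ann.cons_end is None else ann.cons_end,
                "id": ann.element_id,
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# tequadscan v{__version__} rmsk table\n")
        df.to_csv(fh, sep="\t", index=False)


def extract_records(
    genome: dict[str, str],
    annotations: Sequence[RepeatAnnotation],
    flank: int = 200,
) -> list[SequenceRecord]:
    """Extract each annotation's sequence with ``flank`` bp on each side.

    Flanks are truncated at chromosome ends; the record's origin reflects the
    actual (clipped) interval while ``flank`` records the requested size.
    Sequences are genome plus-strand oriented.
    """
    out = []
    for ann in annotations:
        if ann.chrom not in genome:
            raise KeyError(f"{ann.element_id}: chromosome {ann.chrom!r} not in genome")
        chrom_seq = genome[ann.chrom]
        start = max(0, ann.geno_start - flank)
        end = min(len(chrom_seq), ann.geno_end + flank)
        out.append(
            SequenceRecord(
                record_id=format_ucsc_header(ann, start, end, flank),
                seq=chrom_seq[start:end].upper(),
                origin=(ann.chrom, start, end, ann.strand),
                annotation_ref=ann.element_id,
                flank=flank,
            )
        )
    return out


def hits_to_frame(hits: Sequence) -> pd.DataFrame:
    """PQS clusters as a DataFrame (sequence- or genome-space)."""
    rows = []
    for h in hits:
        rows.append(
            {
                "source_id": h.source_id,
                "chrom": h.chrom if h.chrom is not None else "",
                "start": h.start,
                "end": h.end,
                "strand_label": h.strand_label,
                "n_runs": h.n_runs,
                "signature": h.signature_str(),
                "matched_seq": h.matched_seq,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "source_id",
            "chrom",
            "start",
            "end",
            "strand_label",
            "n_runs",
            "signature",
            "matched_seq",
        ],
    )


def write_hits_tsv(hits: Sequence, path: str | Path, params=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tequadscan v{__version__} hits" + (f" params={params}" if params else "") + "\n")
        hits_to_frame(hits).to_csv(fh, sep="\t", index=False)


def write_hits_bed(hits: Sequence, path: str | Path) -> None:
    """Write genome-space hits as BED6, sorted by (chrom, start).

    Name column is the run/loop signature, score the run count, strand ``+``
    for PQS3+ and ``-`` for PQS3-.  Hits without a genome origin are
    rejected (use :func:`write_hits_tsv` for sequence-space output).
    """
    for h in hits:
        if h.chrom is None:
            raise ValueError(
                f"hit on {h.source_id!r} lacks genome coordinates; "
                "write sequence-space hits with write_hits_tsv instead"
            )
    ordered = sorted(hits, key=lambda h: (h.chrom, h.start, h.end))
    with open(path, "w") as fh:
        for h in ordered:
            strand = "+" if h.strand_label.endswith("+") else "-"
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.signature_str()}\t{h.n_runs}\t{strand}\n"
            )
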