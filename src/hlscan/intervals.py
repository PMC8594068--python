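"""Genomic intervals, transcriptional units, and BED/TSV I/O.

All coordinates are 0-based half-open (BED convention) everywhere inside
the package; any 1-based interchange happens only at documented I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class BedFormatError(ValueError):
    """Raised for malformed BED records, carrying the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class TranscriptionalUnit:
    """A gene body (TSS to TES of the canonical transcript) with its exons.

    The TSS is the body start on the + strand and ``body.end - 1`` on the
    - strand; every exon must lie inside the body.
    """

    gene_id: str
    body: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for ex in self.exons:
            if not (ex.chrom == self.body.chrom
                    and self.body.start <= ex.start and ex.end <= self.body.end):
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside body"
                )

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/4/6 into intervals; order of records is preserved."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path} line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise BedFormatError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand=strand, id=name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.id if iv.id is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_tsv(records: Sequence[dict], path: str | Path,
              columns: Sequence[str] | None = None) -> None:
    """Write dict records as a TSV with a header row."""
    records = list(records)
    if columns is None:
        columns = list(records[0].keys()) if records else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write("\t".join(str(rec.get(c, "")) for c in columns) + "\n")


def read_gene_annotation(gene_tsv: str | Path,
                         exon_bed: str | Path | None = None
                         ) -> list[TranscriptionalUnit]:
    """Read gene bodies from a TSV (gene_id, chrom, start, end, strand) plus
    an optional exon BED whose name column carries the owning gene_id."""
    units: dict[str, TranscriptionalUnit] = {}
    with open(gene_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gid = f[idx["gene_id"]]
            units[gid] = TranscriptionalUnit(
                gene_id=gid,
                body=GenomicInterval(f[idx["chrom"]], int(f[idx["start"]]),
                                     int(f[idx["end"]]), strand=f[idx["strand"]]),
                strand=f[idx["strand"]],
            )
    if exon_bed is not None:
        for iv in read_bed(exon_bed):
            if iv.id in units:
                units[iv.id].exons.append(iv)
        for u in units.values():
            TranscriptionalUnit.__post_init__(u)
    return list(units.values())
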