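"""Readers and writers for the genomic formats the pipeline touches.

One coordinate convention holds everywhere inside the package: 0-based,
half-open intervals. BED files already use that convention and are taken
verbatim; GTF files and ``chrom:start-end`` locus strings are 1-based
inclusive and are shifted at the boundary (``start - 1``) on read and
shifted back on write. Keeping a single internal convention prevents
off-by-one drift when BED and GTF inputs meet in the intersection step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

#: sentinel strand for features without strand information
UNSTRANDED = "."

_VALID_STRANDS = {"+", "-", UNSTRANDED}


class ParseError(ValueError):
    """Malformed record in a genomic text format; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Base pairs shared with ``other``; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def locus_string(self) -> str:
        """1-based inclusive ``chrom:start-end`` form used in reports."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class AlignedFragment:
    """One sequenced fragment (template): mates of a pair collapsed to one
    record whose span covers both mate alignments on the same chromosome."""

    read_id: str
    chrom: str
    span: GenomicInterval
    strand: str
    is_paired: bool = False


@dataclass
class GtfRecord:
    """One GTF feature line, with coordinates already internalised."""

    seqname: str
    source: str
    feature: str
    interval: GenomicInterval
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)
    name: str | None = None
    score: str = "."
    frame: str = "."


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[tuple[GenomicInterval, str, float]]:
    """Parse BED3-BED6 into ``(interval, name, score)`` triples.

    Coordinates are taken verbatim (BED is 0-based half-open). A missing
    strand column yields an unstranded interval; missing name/score yield
    ``""`` and ``0``.
    """
    out: list[tuple[GenomicInterval, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"expected >= 3 tab-separated fields", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", lineno
                ) from None
            if start >= end:
                raise ParseError(f"empty or inverted interval [{start}, {end})", lineno)
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                raise ParseError(f"non-numeric score {fields[4]!r}", lineno) from None
            strand = fields[5] if len(fields) > 5 else UNSTRANDED
            if strand not in _VALID_STRANDS:
                raise ParseError(f"invalid strand {strand!r}", lineno)
            try:
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            out.append((interval, name, score))
    return out


def write_bed(path, records: Iterable[tuple[GenomicInterval, str, float]]) -> None:
    """Write ``(interval, name, score)`` triples as BED6."""
    with open(path, "w") as fh:
        for interval, name, score in records:
            score_txt = str(int(score)) if float(score).is_integer() else repr(score)
            fh.write(
                f"{interval.chrom}\t{interval.start}\t{interval.end}\t"
                f"{name}\t{score_txt}\t{interval.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF

GTF_DIALECTS = ("ensembl", "repeatmasker")


def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise ParseError(f"malformed attribute {chunk!r}", lineno)
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path, dialect: str = "ensembl") -> list[GtfRecord]:
    """Parse GTF (1-based inclusive) into internal 0-based half-open records.

    ``dialect="ensembl"`` requires a ``gene_id`` attribute on every record.
    ``dialect="repeatmasker"`` maps the repeat name onto ``record.name``:
    the first attribute value matching the ``Alu`` prefix, falling back to
    ``gene_id`` (UCSC table-browser GTF exports put the repeat name in both
    ``gene_id`` and ``transcript_id``).
    """
    if dialect not in GTF_DIALECTS:
        raise ValueError(f"unknown GTF dialect {dialect!r}; expected one of {GTF_DIALECTS}")
    records: list[GtfRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"expected 9 tab-separated fields, got {len(fields)}", lineno)
            seqname, source, feature, start_s, end_s, score, strand, frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"non-integer coordinates {start_s!r}, {end_s!r}", lineno) from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"invalid 1-based span {start1}-{end1}", lineno)
            if strand not in _VALID_STRANDS:
                raise ParseError(f"invalid strand {strand!r}", lineno)
            attrs = _parse_gtf_attributes(attr_s, lineno)
            if dialect == "ensembl" and "gene_id" not in attrs:
                raise ParseError("ensembl-dialect record missing gene_id", lineno)
            name = None
            if dialect == "repeatmasker":
                name = next(
                    (v for v in attrs.values() if v.startswith("Alu")),
                    attrs.get("gene_id"),
                )
            interval = GenomicInterval(seqname, start1 - 1, end1, strand)
            records.append(
                GtfRecord(seqname, source, feature, interval, strand, attrs, name, score, frame)
            )
    return records


def write_gtf(path, records: Iterable[GtfRecord]) -> None:
    """Write records back out as GTF, restoring 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for rec in records:
            attr_s = " ".join(f'{k} "{v}";' for k, v in rec.attributes.items())
            fh.write(
                f"{rec.seqname}\t{rec.source}\t{rec.feature}\t"
                f"{rec.interval.start + 1}\t{rec.interval.end}\t{rec.score}\t"
                f"{rec.strand}\t{rec.frame}\t{attr_s}\n"
            )


def parse_locus(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``chrom:start-end`` locus string."""
    try:
        chrom, _, span = text.partition(":")
        start_s, _, end_s = span.partition("-")
        start1, end1 = int(start_s), int(end_s)
    except ValueError:
        raise ValueError(f"malformed locus string {text!r}") from None
    if not chrom:
        raise ValueError(f"malformed locus string {text!r}")
    if start1 > end1:
        raise ValueError(f"locus start {start1} > end {end1} in {text!r}")
    return GenomicInterval(chrom, start1 - 1, end1)


# ---------------------------------------------------------------------------
# SAM


class MissingHeaderError(ValueError):
    """SAM input without a usable header (no @SQ reference lines)."""


def read_alignments(path) -> list[AlignedFragment]:
    """Read SAM alignments into fragments, merging mate pairs by template.

    Secondary (0x100), supplementary (0x800) and unmapped records are
    dropped. Two primary mates on the same chromosome collapse to one
    fragment spanning both; the fragment strand is the first-in-pair
    mate's strand. Mates on different chromosomes fall back to two
    single-end fragments (logged).
    """
    try:
        af = pysam.AlignmentFile(str(path), "r")
    except ValueError as exc:
        raise MissingHeaderError(f"cannot read SAM header from {path}: {exc}") from None
    with af:
        if not af.header.references:
            raise MissingHeaderError(f"SAM file {path} has no @SQ header lines")
        by_template: dict[str, list[pysam.AlignedSegment]] = {}
        order: list[str] = []
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.query_name not in by_template:
                by_template[read.query_name] = []
                order.append(read.query_name)
            by_template[read.query_name].append(read)

    fragments: list[AlignedFragment] = []
    for name in order:
        reads = by_template[name]
        paired_mates = [r for r in reads if r.is_paired]
        if len(reads) == 2 and len(paired_mates) == 2:
            r1, r2 = reads
            if r1.reference_name == r2.reference_name:
                first = r1 if r1.is_read1 else r2
                span = GenomicInterval(
                    r1.reference_name,
                    min(r1.reference_start, r2.reference_start),
                    max(r1.reference_end, r2.reference_end),
                    "-" if first.is_reverse else "+",
                )
                fragments.append(
                    AlignedFragment(name, r1.reference_name, span, span.strand, True)
                )
                continue
            logger.warning(
                "mates of %s on different chromosomes (%s, %s); keeping two "
                "single-end fragments",
                name, r1.reference_name, r2.reference_name,
            )
        for r in reads:
            span = GenomicInterval(
                r.reference_name,
                r.reference_start,
                r.reference_end,
                "-" if r.is_reverse else "+",
            )
            fragments.append(
                AlignedFragment(name, r.reference_name, span, span.strand, r.is_paired)
            )
    return fragments
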