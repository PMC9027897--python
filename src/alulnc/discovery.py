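"""Alu insertion discovery: intersect the Alu catalog with gene bodies
under a minimum-overlap fraction, classify each insertion's position in
the gene, call its orientation relative to the host, and link CAGE TSSs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .config import PipelineConfig
from .genes import FeatureSet, GeneModel, derive_features, select_reference_transcript
from .genome_io import UNSTRANDED, GenomicInterval
from .repeats import RepeatElement

POSITION_LABELS = ("Intron", "UTR5", "UTR3", "CDS_exon")

#: tie-break precedence when a repeat overlaps two feature classes equally
_POSITION_PRECEDENCE = {"UTR3": 0, "UTR5": 1, "CDS_exon": 2, "Intron": 3}


@dataclass(frozen=True)
class TssRecord:
    """One CAGE-derived transcription start site (single 0-based position)."""

    chrom: str
    pos: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("TSS position must be >= 0")


@dataclass
class AluInsertion:
    """A repeat joined to its host gene with the report's classification
    columns: sub-gene position, orientation, and TSS linkage."""

    repeat: RepeatElement
    gene_id: str
    gene_symbol: str
    position: str
    orientation: str
    tss_flag: str = "none"
    tss_distance: int | None = None

    @property
    def insertion_id(self) -> str:
        return f"{self.gene_symbol}|{self.repeat.subfamily}|{self.repeat.interval.locus_string()}"


class IntervalIndex:
    """Per-chromosome interval tree over (interval, payload) pairs.

    ``query`` returns every stored payload whose interval overlaps the
    query by at least one base (half-open semantics)."""

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for interval, payload in items:
            self.add(interval, payload)

    def add(self, interval: GenomicInterval, payload: object) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, (interval, payload))

    def query(self, chrom: str, start: int, end: int) -> list[tuple[GenomicInterval, object]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]


def build_interval_index(
    items: Iterable[tuple[GenomicInterval, object]]
) -> IntervalIndex:
    return IntervalIndex(items)


def min_overlap_bp(gene_length: int, fraction: float) -> int:
    """Overlap floor implied by a fractional-overlap rule: ceil(f * length)."""
    return math.ceil(fraction * gene_length)


def intersect_genes_alus(
    genes: Sequence[GeneModel],
    catalog: Sequence[RepeatElement],
    min_gene_fraction: float = 0.009,
    overlap_denominator: str = "gene",
) -> list[tuple[GeneModel, RepeatElement, int]]:
    """Report (gene, repeat, overlap_bp) for every pair whose overlap
    reaches the fractional floor.

    With ``overlap_denominator="gene"`` the fraction applies to the gene
    interval, exactly as a bedtools ``intersect -f`` run with genes as
    file A does — a short Alu can therefore never satisfy the rule inside
    a very long gene. ``"alu"`` applies it to the element instead.
    """
    index = build_interval_index((el.interval, el) for el in catalog)
    pairs: list[tuple[GeneModel, RepeatElement, int]] = []
    for gene in genes:
        hits = index.query(gene.interval.chrom, gene.interval.start, gene.interval.end)
        for _, el in sorted(hits, key=lambda h: (h[0].start, h[0].end)):
            overlap = gene.interval.overlap_bp(el.interval)
            denom = gene.interval.length if overlap_denominator == "gene" else el.interval.length
            if overlap >= min_overlap_bp(denom, min_gene_fraction):
                pairs.append((gene, el, overlap))
    return pairs


def classify_position(repeat: RepeatElement, features: FeatureSet,
                      gene_interval: GenomicInterval | None = None) -> str:
    """Label the insertion by the feature class with the largest base-pair
    overlap; ties break by precedence UTR3 > UTR5 > CDS_exon > Intron.

    A repeat outside the reference transcript's feature geometry but
    inside the gene interval is labelled Intron (annotation slack);
    outside the gene interval it is an error.
    """
    overlaps = {
        "Intron": sum(repeat.interval.overlap_bp(iv) for iv in features.introns),
        "UTR5": sum(repeat.interval.overlap_bp(iv) for iv in features.utr5),
        "UTR3": sum(repeat.interval.overlap_bp(iv) for iv in features.utr3),
        "CDS_exon": sum(repeat.interval.overlap_bp(iv) for iv in features.cds_exons),
    }
    best = max(overlaps.values())
    if best == 0:
        if gene_interval is not None and gene_interval.overlap_bp(repeat.interval) > 0:
            return "Intron"
        raise ValueError(
            f"repeat {repeat.subfamily} at {repeat.interval.locus_string()} does not "
            f"overlap gene features or gene interval"
        )
    return min(
        (label for label, bp in overlaps.items() if bp == best),
        key=_POSITION_PRECEDENCE.__getitem__,
    )


def call_orientation(repeat_strand: str, gene_strand: str) -> str:
    """Sense iff the element and host gene strands are equal."""
    if repeat_strand not in ("+", "-"):
        raise ValueError(f"repeat strand must be + or -, got {repeat_strand!r}")
    if gene_strand not in ("+", "-"):
        raise ValueError(f"gene strand must be + or -, got {gene_strand!r}")
    return "Sense" if repeat_strand == gene_strand else "Inverted"


def _five_prime_edge(interval: GenomicInterval, gene_strand: str) -> int:
    """Position of the element's 5'-most base in transcription direction."""
    return interval.start if gene_strand == "+" else interval.end - 1


def link_tss(
    repeat: RepeatElement,
    gene_strand: str,
    tss_records: Sequence[TssRecord],
    window: int = 1000,
    internal_fraction: float = 0.5,
) -> tuple[str, int | None]:
    """Attach the nearest qualifying CAGE TSS to an Alu element.

    ``upstream``: a strand-matching TSS strictly within ``window`` nt 5'
    of the element's transcription-direction start (distance >= 1, <
    window). ``internal_5prime``: a strand-matching TSS within the 5'
    ``internal_fraction`` of the element span. Upstream takes precedence;
    the reported distance is the smallest qualifying one. TSS strand
    matching uses the host gene's strand; unstranded TSS records match
    either strand.
    """
    iv = repeat.interval
    edge = _five_prime_edge(iv, gene_strand)
    best_upstream: int | None = None
    internal = False
    for tss in tss_records:
        if tss.chrom != iv.chrom:
            continue
        if tss.strand != UNSTRANDED and tss.strand != gene_strand:
            continue
        dist = edge - tss.pos if gene_strand == "+" else tss.pos - edge
        if 1 <= dist < window:
            if best_upstream is None or dist < best_upstream:
                best_upstream = dist
        if iv.start <= tss.pos < iv.end:
            offset = tss.pos - iv.start if gene_strand == "+" else (iv.end - 1) - tss.pos
            if offset < internal_fraction * iv.length:
                internal = True
    if best_upstream is not None:
        return "upstream", best_upstream
    if internal:
        return "internal_5prime", None
    return "none", None


def discover_insertions(
    genes: Sequence[GeneModel],
    catalog: Sequence[RepeatElement],
    tss_records: Sequence[TssRecord] = (),
    config: PipelineConfig | None = None,
) -> list[AluInsertion]:
    """Full discovery pass: intersect, classify, orient, and TSS-link.

    Returns every reported (gene, repeat) pair with its labels; use
    :func:`candidate_insertions` to drop protein-coding-exon overlaps
    from downstream candidate sets.
    """
    cfg = config or PipelineConfig()
    pairs = intersect_genes_alus(
        genes, catalog, cfg.min_gene_fraction, cfg.overlap_denominator
    )
    features_cache: dict[str, FeatureSet] = {}
    insertions: list[AluInsertion] = []
    for gene, el, _ in pairs:
        if gene.id not in features_cache:
            features_cache[gene.id] = derive_features(select_reference_transcript(gene))
        position = classify_position(el, features_cache[gene.id], gene.interval)
        orientation = call_orientation(el.interval.strand, gene.strand)
        tss_flag, tss_distance = link_tss(
            el, gene.strand, tss_records, cfg.tss_window, cfg.tss_internal_fraction
        )
        insertions.append(
            AluInsertion(el, gene.id, gene.symbol, position, orientation, tss_flag, tss_distance)
        )
    return insertions


def candidate_insertions(insertions: Iterable[AluInsertion]) -> list[AluInsertion]:
    """Drop insertions sitting in protein-coding exon sequence: candidate
    Alu-lncRNAs come from introns and UTRs."""
    return [ins for ins in insertions if ins.position != "CDS_exon"]


def write_insertions_tsv(path, insertions: Iterable[AluInsertion]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "insertion_id\tgene_id\tgene_symbol\tsubfamily\tfamily\tlocus\t"
            "strand\tposition\torientation\ttss_flag\ttss_distance\n"
        )
        for ins in insertions:
            dist = "" if ins.tss_distance is None else str(ins.tss_distance)
            fh.write(
                f"{ins.insertion_id}\t{ins.gene_id}\t{ins.gene_symbol}\t"
                f"{ins.repeat.subfamily}\t{ins.repeat.family}\t"
                f"{ins.repeat.interval.locus_string()}\t{ins.repeat.interval.strand}\t"
                f"{ins.position}\t{ins.orientation}\t{ins.tss_flag}\t{dist}\n"
            )
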