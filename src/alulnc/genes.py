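"""Gene models from Ensembl-dialect GTF annotation, and the derived
intron / 5'UTR / 3'UTR / CDS-exon feature geometry used to classify where
an Alu insertion sits inside its host gene.

Feature derivation works on a single reference transcript per gene (the
one with the largest summed exon length) because the candidate report
assigns one position label per insertion; a per-transcript multi-label
would not reproduce that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import GenomicInterval, GtfRecord

logger = logging.getLogger(__name__)


@dataclass
class TranscriptModel:
    id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    cds_span: GenomicInterval | None = None

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class GeneModel:
    id: str
    symbol: str
    interval: GenomicInterval
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)


@dataclass
class FeatureSet:
    """Disjoint sub-gene features derived from one reference transcript.

    For transcripts without an annotated CDS all exonic sequence sits in
    the ``cds_exons`` slot under the surrogate label ``exonic_noncoding``.
    """

    gene_id: str
    introns: list[GenomicInterval]
    utr5: list[GenomicInterval]
    utr3: list[GenomicInterval]
    cds_exons: list[GenomicInterval]
    cds_label: str = "CDS_exon"


def build_gene_models(
    records: Iterable[GtfRecord], symbol_key: str = "gene_name"
) -> list[GeneModel]:
    """Assemble one GeneModel per gene_id from exon and CDS GTF records.

    The gene symbol comes from the ``gene_name`` attribute when present,
    falling back to the gene id. Transcripts with zero exon records are
    an error.
    """
    exons: dict[str, list[GtfRecord]] = {}
    cds: dict[str, list[GtfRecord]] = {}
    tx_gene: dict[str, str] = {}
    tx_order: list[str] = []
    gene_symbol: dict[str, str] = {}
    gene_order: list[str] = []

    for rec in records:
        gid = rec.attributes["gene_id"]
        if gid not in gene_symbol:
            gene_order.append(gid)
            gene_symbol[gid] = rec.attributes.get(symbol_key, gid)
        elif symbol_key in rec.attributes:
            gene_symbol[gid] = rec.attributes[symbol_key]
        if rec.feature not in ("exon", "CDS"):
            continue
        tid = rec.attributes.get("transcript_id")
        if tid is None:
            raise ValueError(f"{rec.feature} record for {gid} missing transcript_id")
        if tid not in tx_gene:
            tx_gene[tid] = gid
            tx_order.append(tid)
        (exons if rec.feature == "exon" else cds).setdefault(tid, []).append(rec)

    tx_by_gene: dict[str, list[TranscriptModel]] = {}
    for tid in tx_order:
        gid = tx_gene[tid]
        if tid not in exons:
            raise ValueError(f"transcript {tid} of gene {gid} has zero exons")
        recs = sorted(exons[tid], key=lambda r: r.interval.start)
        strand = recs[0].strand
        exon_ivs = [r.interval for r in recs]
        cds_span = None
        if tid in cds:
            cstart = min(r.interval.start for r in cds[tid])
            cend = max(r.interval.end for r in cds[tid])
            cds_span = GenomicInterval(exon_ivs[0].chrom, cstart, cend, strand)
        tx_by_gene.setdefault(gid, []).append(
            TranscriptModel(tid, gid, strand, exon_ivs, cds_span)
        )

    models: list[GeneModel] = []
    for gid in gene_order:
        txs = tx_by_gene.get(gid)
        if not txs:
            continue
        start = min(tx.exons[0].start for tx in txs)
        end = max(tx.exons[-1].end for tx in txs)
        strand = txs[0].strand
        interval = GenomicInterval(txs[0].exons[0].chrom, start, end, strand)
        models.append(GeneModel(gid, gene_symbol[gid], interval, strand, txs))
    return models


def select_reference_transcript(gene: GeneModel) -> TranscriptModel:
    """The transcript with the largest summed exon length; ties go to the
    lexicographically smallest transcript id."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.id} has no transcripts")
    return min(gene.transcripts, key=lambda tx: (-tx.exonic_length, tx.id))


def _clip(intervals: Sequence[GenomicInterval], lo: int, hi: int) -> list[GenomicInterval]:
    """Exonic sequence restricted to [lo, hi)."""
    out = []
    for iv in intervals:
        s, e = max(iv.start, lo), min(iv.end, hi)
        if s < e:
            out.append(GenomicInterval(iv.chrom, s, e, iv.strand))
    return out


def derive_features(tx: TranscriptModel) -> FeatureSet:
    """Split a transcript into introns, 5'UTR, 3'UTR and CDS exon pieces.

    Introns are the gaps between consecutive exons. With a CDS span, the
    exonic sequence 5' of it (in transcription direction) is the 5'UTR and
    the sequence 3' of it the 3'UTR; exon∩CDS is the coding portion. On
    the minus strand the genomic left/right sides of the CDS swap labels.
    """
    introns = [
        GenomicInterval(a.chrom, a.end, b.start, tx.strand)
        for a, b in zip(tx.exons, tx.exons[1:])
        if a.end < b.start
    ]
    if tx.cds_span is None:
        return FeatureSet(
            tx.gene_id,
            introns=introns,
            utr5=[],
            utr3=[],
            cds_exons=list(tx.exons),
            cds_label="exonic_noncoding",
        )
    span = tx.span
    left = _clip(tx.exons, span.start, tx.cds_span.start)
    right = _clip(tx.exons, tx.cds_span.end, span.end)
    coding = _clip(tx.exons, tx.cds_span.start, tx.cds_span.end)
    if tx.strand == "-":
        left, right = right, left
    return FeatureSet(tx.gene_id, introns=introns, utr5=left, utr3=right, cds_exons=coding)


def load_symbol_list(path) -> set[str]:
    """Immune-gene symbol list: one symbol per line, ``#`` comments allowed.
    Symbols are upper-cased on load."""
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                symbols.add(sym.upper())
    return symbols


def restrict_to_symbols(genes: list[GeneModel], symbols: set[str]) -> list[GeneModel]:
    """Keep genes whose symbol is in the set (case-insensitive exact match)."""
    if not symbols:
        raise ValueError("empty symbol set")
    wanted = {s.upper() for s in symbols}
    kept = [g for g in genes if g.symbol.upper() in wanted]
    matched = {g.symbol.upper() for g in kept}
    unmatched = wanted - matched
    if unmatched:
        logger.warning("%d immune-gene symbols not found in annotation", len(unmatched))
    if not kept:
        logger.warning("no annotation genes matched the symbol list")
    return kept
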