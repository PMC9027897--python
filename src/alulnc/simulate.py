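"""Synthetic fixtures with known ground truth: toy gene annotation with
planted Alu insertions, CAGE-style TSS tracks, negative-binomial count
matrices with planted group effects, and SAM emission whose per-interval
fragment tallies equal the drawn counts.

The count generator mirrors the statistical structure of the study
cohort it emulates: a healthy group (default n=40) against a pooled
inflammation group (default n=48: infection 12, sepsis 18, septic shock
18), overdispersed counts (negative binomial, dispersion 0.1), and a
differentially expressed subset with a planted fold change. Geometry is
noiseless: planted position labels, orientations and TSS offsets are
exactly re-derivable from the emitted files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .genome_io import GenomicInterval, GtfRecord, write_bed, write_gtf
from .quantify import CountMatrix, SampleSheet

SUBFAMILY_POOL = (
    "AluJb", "AluJo", "AluSx", "AluSx1", "AluSz", "AluSc", "AluSg", "AluSp",
    "AluY", "AluYa5",
)

#: minimum distance between planted-element midpoints inside one gene, so
#: a TSS planted for one element can never qualify for another
_MIN_PLANT_SEPARATION = 2700


@dataclass
class PlantedAlu:
    """Ground truth for one planted Alu insertion."""

    gene_id: str
    gene_symbol: str
    subfamily: str
    interval: GenomicInterval
    position: str  # "Intron" or "UTR3"
    orientation: str  # "Sense" or "Inverted"
    tss_offset: int | None = None  # upstream distance in nt, or None

    @property
    def insertion_id(self) -> str:
        return f"{self.gene_symbol}|{self.subfamily}|{self.interval.locus_string()}"


@dataclass
class ExpressionTruth:
    """Ground truth of a simulated count matrix."""

    seed: int
    dispersion: float
    fc: float
    n_per_group: tuple[int, int]
    baseline: dict[str, float]
    de_ids: set[str]
    up_in_inflammation: dict[str, bool]


@dataclass
class SimTruth:
    """Everything planted by the generators, re-derivable from the files."""

    seed: int
    planted: list[PlantedAlu]
    chrom_sizes: dict[str, int]
    expression: ExpressionTruth | None = None

    @property
    def insertion_ids(self) -> list[str]:
        return [p.insertion_id for p in self.planted]


@dataclass
class SimulatedAnnotation:
    """In-memory simulated annotation plus writers for the pipeline's
    input dialects (Ensembl-style GTF, BED6 repeat and TSS tracks)."""

    gtf_records: list[GtfRecord]
    repeat_bed: list[tuple[GenomicInterval, str, float]]
    tss_bed: list[tuple[GenomicInterval, str, float]]
    truth: SimTruth

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes_gtf": out / "genes.gtf",
            "alu_bed": out / "alu.bed",
            "tss_bed": out / "tss.bed",
        }
        write_gtf(paths["genes_gtf"], self.gtf_records)
        write_bed(paths["alu_bed"], self.repeat_bed)
        write_bed(paths["tss_bed"], self.tss_bed)
        return paths


def _plan_gene(rng: np.random.Generator, chrom: str, cursor: int, strand: str):
    """Exon/intron/CDS geometry for one gene, left-to-right in genomic
    coordinates. Returns (exons, cds_span, gene_end, slots) where slots
    are the intervals Alus may be planted into, labelled Intron/UTR3."""
    n_exons = int(rng.integers(2, 7))
    # the genomic-left terminal exon carries the 5'UTR on + genes and the
    # 3'UTR on - genes; sizes chosen so the 3' side always fits an Alu
    u5_len = int(rng.integers(100, 201))
    u3_len = int(rng.integers(400, 601))
    left_utr = u5_len if strand == "+" else u3_len
    right_utr = u3_len if strand == "+" else u5_len
    first_len = left_utr + int(rng.integers(100, 301))
    last_len = right_utr + int(rng.integers(100, 301))
    mid_lens = [int(rng.integers(150, 401)) for _ in range(n_exons - 2)]
    exon_lens = [first_len, *mid_lens, last_len]
    intron_lens = [int(rng.integers(800, 2501)) for _ in range(n_exons - 1)]

    exons: list[GenomicInterval] = []
    pos = cursor
    for i, elen in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < len(intron_lens):
            pos += intron_lens[i]
    gene_end = exons[-1].end
    cds_span = GenomicInterval(chrom, exons[0].start + left_utr, gene_end - right_utr, strand)
    utr3_region = (
        GenomicInterval(chrom, cds_span.end, gene_end, strand)
        if strand == "+"
        else GenomicInterval(chrom, exons[0].start, cds_span.start, strand)
    )
    slots = [("UTR3", utr3_region)]
    for a, b in zip(exons, exons[1:]):
        slots.append(("Intron", GenomicInterval(chrom, a.end, b.start, strand)))
    return exons, cds_span, gene_end, slots


def simulate_annotation(
    n_genes: int,
    seed: int,
    tss_fraction: float = 0.6,
    utr3_fraction: float = 0.5,
    tss_window: int = 1000,
) -> SimulatedAnnotation:
    """Simulate genes with exon/CDS structure and planted Alu insertions.

    Each gene gets 2-6 exons, a CDS leaving a 5'UTR and an Alu-sized
    3'UTR, and one or two Alus planted wholly inside introns or the 3'UTR
    (a ``utr3_fraction`` of genes place their first Alu in the 3'UTR). A
    ``tss_fraction`` of planted elements receive an upstream TSS on the
    gene strand at a drawn offset of 50-949 nt (< the linkage window).
    Deterministic per seed; same seed gives byte-identical files.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    gtf_records: list[GtfRecord] = []
    repeat_bed: list[tuple[GenomicInterval, str, float]] = []
    tss_bed: list[tuple[GenomicInterval, str, float]] = []
    planted: list[PlantedAlu] = []
    cursors = {f"chr{c}": 10_000 for c in (1, 2, 3)}

    for i in range(n_genes):
        chrom = f"chr{(i % 3) + 1}"
        gene_id, tx_id, symbol = f"SIMG{i + 1:04d}", f"SIMT{i + 1:04d}", f"GENE{i + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons, cds_span, gene_end, slots = _plan_gene(rng, chrom, cursors[chrom], strand)
        cursors[chrom] = gene_end + 10_000

        attrs = {"gene_id": gene_id, "transcript_id": tx_id, "gene_name": symbol}
        for exon in exons:
            gtf_records.append(
                GtfRecord(chrom, "sim", "exon", exon, strand, dict(attrs))
            )
            cs, ce = max(exon.start, cds_span.start), min(exon.end, cds_span.end)
            if cs < ce:
                gtf_records.append(
                    GtfRecord(chrom, "sim", "CDS",
                              GenomicInterval(chrom, cs, ce, strand), strand, dict(attrs))
                )

        # choose planting slots far enough apart that TSS windows never
        # bleed from one planted element onto another
        n_alus = int(rng.integers(1, 3))
        want_utr3 = rng.random() < utr3_fraction
        ordered = sorted(slots, key=lambda s: (s[0] != "UTR3") if want_utr3 else (s[0] == "UTR3"))
        chosen: list[tuple[str, GenomicInterval]] = []
        for label, region in ordered:
            if len(chosen) == n_alus:
                break
            mid = (region.start + region.end) // 2
            if all(
                abs(mid - (r.start + r.end) // 2) >= _MIN_PLANT_SEPARATION
                for _, r in chosen
            ):
                chosen.append((label, region))

        for label, region in chosen:
            alu_len = int(rng.integers(250, 321))
            margin = region.length - alu_len
            offset = int(rng.integers(1, margin)) if margin > 1 else 0
            alu_strand = "+" if rng.random() < 0.5 else "-"
            alu_iv = GenomicInterval(
                chrom, region.start + offset, region.start + offset + alu_len, alu_strand
            )
            subfamily = str(rng.choice(SUBFAMILY_POOL))
            orientation = "Sense" if alu_strand == strand else "Inverted"
            tss_offset = None
            if rng.random() < tss_fraction:
                tss_offset = int(rng.integers(50, min(950, tss_window)))
                tss_pos = (
                    alu_iv.start - tss_offset if strand == "+" else (alu_iv.end - 1) + tss_offset
                )
                tss_bed.append(
                    (
                        GenomicInterval(chrom, tss_pos, tss_pos + 1, strand),
                        f"tss_{gene_id}_{len(tss_bed)}",
                        0.0,
                    )
                )
            repeat_bed.append((alu_iv, subfamily, 0.0))
            planted.append(
                PlantedAlu(gene_id, symbol, subfamily, alu_iv, label, orientation, tss_offset)
            )

    chrom_sizes = {chrom: cursor + 10_000 for chrom, cursor in cursors.items()}
    truth = SimTruth(seed=seed, planted=planted, chrom_sizes=chrom_sizes)
    repeat_bed.sort(key=lambda r: (r[0].chrom, r[0].start))
    tss_bed.sort(key=lambda r: (r[0].chrom, r[0].start))
    return SimulatedAnnotation(gtf_records, repeat_bed, tss_bed, truth)


_INFLAMMATION_CYCLE = ("sepsis", "septic_shock", "infection")


def simulate_counts(
    truth: SimTruth | Sequence[str],
    n_per_group: tuple[int, int] = (40, 48),
    seed: int = 0,
    fc: float = 4.0,
    dispersion: float = 0.1,
    de_fraction: float = 0.5,
    baseline_range: tuple[float, float] = (500.0, 5000.0),
) -> tuple[CountMatrix, SampleSheet, ExpressionTruth]:
    """Draw a negative-binomial count matrix with planted group effects.

    ``truth`` is either a SimTruth from :func:`simulate_annotation` (its
    expression slot is filled in) or a plain list of insertion ids. Group
    sizes default to the emulated cohort (healthy 40, inflammation 48);
    a ``de_fraction`` of insertions get the planted fold change ``fc``
    applied to the inflammation group, direction drawn at random.
    """
    n_healthy, n_inflam = n_per_group
    if n_healthy < 2 or n_inflam < 2:
        raise ValueError("need >= 2 samples per group")
    ids = truth.insertion_ids if isinstance(truth, SimTruth) else list(truth)
    if not ids:
        raise ValueError("no insertions to simulate")
    rng = np.random.default_rng(seed)

    baseline = {
        rid: float(rng.uniform(*baseline_range)) for rid in ids
    }
    n_de = int(round(de_fraction * len(ids)))
    de_idx = rng.choice(len(ids), size=n_de, replace=False) if n_de else np.array([], int)
    de_ids = {ids[i] for i in de_idx}
    up = {rid: bool(rng.random() < 0.5) for rid in de_ids}

    col_ids = [f"H{j + 1:03d}" for j in range(n_healthy)] + [
        f"P{j + 1:03d}" for j in range(n_inflam)
    ]
    conditions = {c: "healthy" for c in col_ids[:n_healthy]}
    for j, c in enumerate(col_ids[n_healthy:]):
        conditions[c] = _INFLAMMATION_CYCLE[j % len(_INFLAMMATION_CYCLE)]

    size = 1.0 / dispersion  # NB shape parameter: var = mu + dispersion * mu^2
    counts = np.zeros((len(ids), len(col_ids)), dtype=np.int64)
    for i, rid in enumerate(ids):
        mu_h = baseline[rid]
        mu_i = mu_h
        if rid in de_ids:
            mu_i = mu_h * fc if up[rid] else mu_h / fc
        mus = np.array([mu_h] * n_healthy + [mu_i] * n_inflam)
        counts[i, :] = rng.negative_binomial(size, size / (size + mus))

    matrix = CountMatrix(list(ids), col_ids, counts)
    sheet = SampleSheet(conditions)
    expression = ExpressionTruth(
        seed=seed,
        dispersion=dispersion,
        fc=fc,
        n_per_group=(n_healthy, n_inflam),
        baseline=baseline,
        de_ids=de_ids,
        up_in_inflammation=up,
    )
    if isinstance(truth, SimTruth):
        truth.expression = expression
    return matrix, sheet, expression


def emit_alignments(
    matrix: CountMatrix,
    intervals: dict[str, GenomicInterval],
    chrom_sizes: dict[str, int],
    out_dir,
    read_len: int = 100,
) -> dict[str, Path]:
    """Write one SAM file per sample whose per-interval fragment tallies
    reproduce the count matrix exactly.

    Each count becomes that many single-end reads placed wholly inside
    the insertion interval (cycling start offsets); intervals must be
    disjoint for exact reproduction. Reads carry placeholder sequence.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs = sorted(chrom_sizes)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in refs],
        }
    )
    ref_index = {c: k for k, c in enumerate(refs)}
    paths: dict[str, Path] = {}
    for j, sample in enumerate(matrix.col_ids):
        path = out / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for i, rid in enumerate(matrix.row_ids):
                iv = intervals[rid]
                rlen = min(read_len, iv.length)
                span = iv.length - rlen
                for k in range(int(matrix.counts[i, j])):
                    read = pysam.AlignedSegment(header)
                    read.query_name = f"r{i}_{j}_{k}"
                    read.reference_id = ref_index[iv.chrom]
                    read.reference_start = iv.start + (k % (span + 1))
                    read.mapping_quality = 60
                    read.cigarstring = f"{rlen}M"
                    read.query_sequence = "A" * rlen
                    read.flag = 0
                    sam.write(read)
        paths[sample] = path
    return paths


def evaluate_recovery(
    called_ids: set[str], true_ids: set[str]
) -> tuple[float, float]:
    """(sensitivity, observed false-discovery proportion) of a call set
    against planted truth; FDP is 0 when nothing is called."""
    if not true_ids:
        raise ValueError("no planted truth to evaluate against")
    recovered = len(called_ids & true_ids)
    sensitivity = recovered / len(true_ids)
    fdp = (len(called_ids) - recovered) / len(called_ids) if called_ids else 0.0
    return sensitivity, fdp
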