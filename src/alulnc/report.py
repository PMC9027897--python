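"""Candidate tables: assemble, read, write, and summarize the
seven-column report of robust, significant Alu insertions in immune
genes (gene symbol, Alu subfamily, locus, position in gene, TSS
linkage, orientation, adjusted p-value)."""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .discovery import AluInsertion
from .genome_io import ParseError, parse_locus
from .repeats import alu_family
from .stats import DeResult

POSITIONS = ("Intron", "UTR3", "UTR5")
TSS_VALUES = ("no", "yes", "yes_5prime")
ORIENTATIONS = ("Sense", "Inverted")

# accept both ASCII and typographic primes/apostrophes in position tokens
_POSITION_TOKENS = {
    "intron": "Intron",
    "3'utr": "UTR3",
    "5'utr": "UTR5",
    "utr3": "UTR3",
    "utr5": "UTR5",
}
_TSS_TOKENS = {
    "no": "no",
    "yes": "yes",
    "yes ^1": "yes_5prime",
    "yes^1": "yes_5prime",
    "yes 1": "yes_5prime",
    "yes_5prime": "yes_5prime",
}

_SCI_NOTATION = re.compile(r"^\s*([0-9.]+)\s*[x×*]\s*10\s*\^?\s*([+-−]?\d+)\s*$")


def _parse_pvalue(text: str) -> float:
    """Accept plain/e-notation floats and printed '2 × 10^-5' forms."""
    m = _SCI_NOTATION.match(text)
    if m:
        exponent = m.group(2).replace("−", "-")
        return float(m.group(1)) * 10.0 ** int(exponent)
    return float(text)


def _normalize_position(token: str) -> str:
    key = token.strip().replace("′", "'").replace("’", "'").lower()
    if key not in _POSITION_TOKENS:
        raise ValueError(f"unknown position token {token!r}")
    return _POSITION_TOKENS[key]


@dataclass
class CandidateRecord:
    """One row of the candidate report."""

    gene_symbol: str
    subfamily: str
    locus: str  # 1-based inclusive "chrom:start-end"
    position: str
    tss: str
    orientation: str
    p_value: float

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"invalid position {self.position!r}")
        if self.tss not in TSS_VALUES:
            raise ValueError(f"invalid tss value {self.tss!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")

    @property
    def family(self) -> str:
        return alu_family(self.subfamily)

    @property
    def interval(self):
        return parse_locus(self.locus)


@dataclass
class CandidateSummary:
    n_rows: int
    n_genes: int
    by_position: dict[str, int]
    by_family: dict[str, int]
    by_orientation: dict[str, int]
    n_tss: int
    n_tss_intron: int
    n_tss_utr3: int
    max_p: float

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.__dict__, indent=indent)


_TSS_FROM_FLAG = {"none": "no", "upstream": "yes", "internal_5prime": "yes_5prime"}

_HEADER = [
    "gene_symbol", "subfamily", "locus", "position", "tss", "orientation", "p_value",
]


def build_candidate_table(
    insertions: Sequence[AluInsertion],
    de_results: Sequence[DeResult],
    selected_ids: Iterable[str],
) -> list[CandidateRecord]:
    """Assemble report rows for the selected insertion ids (the robust,
    significant set), sorted by (chromosome lexicographic, start) — the
    chr1, chr10, ..., chr2, chr21, chr3 order the report uses.

    Every insertion must carry a differential-expression result.
    """
    de_by_id = {r.insertion_id: r for r in de_results}
    by_id = {ins.insertion_id: ins for ins in insertions}
    selected = set(selected_ids)
    rows: list[CandidateRecord] = []
    for ins_id in selected:
        if ins_id not in by_id:
            raise ValueError(f"unknown insertion id {ins_id!r}")
        ins = by_id[ins_id]
        if ins_id not in de_by_id:
            raise ValueError(f"insertion {ins_id!r} has no differential-expression result")
        rows.append(
            CandidateRecord(
                gene_symbol=ins.gene_symbol,
                subfamily=ins.repeat.subfamily,
                locus=ins.repeat.interval.locus_string(),
                position=ins.position,
                tss=_TSS_FROM_FLAG[ins.tss_flag],
                orientation=ins.orientation,
                p_value=de_by_id[ins_id].p_adj,
            )
        )
    rows.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return rows


def karyotype_sort(records: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """Natural chromosome order (chr1, chr2, ... chr10, ..., chrX)."""

    def key(rec: CandidateRecord):
        chrom = rec.interval.chrom.removeprefix("chr")
        return (0, int(chrom)) if chrom.isdigit() else (1, chrom), rec.interval.start

    return sorted(records, key=key)


def write_candidate_table(path, records: Iterable[CandidateRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for rec in records:
            fh.write(
                f"{rec.gene_symbol}\t{rec.subfamily}\t{rec.locus}\t{rec.position}\t"
                f"{rec.tss}\t{rec.orientation}\t{rec.p_value:g}\n"
            )


def read_candidate_table(path) -> list[CandidateRecord]:
    """Read a seven-column candidate TSV.

    Position tokens may use ASCII or typographic primes ("3'UTR");
    p-values may be plain, e-notation, or printed "2 × 10^-5" form; a
    footnote-marked TSS field ("yes ^1") maps to yes_5prime (the TSS sits
    in the 5' end of the element itself).
    """
    records: list[CandidateRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 7:
            raise ParseError(f"expected 7 columns, got {len(header)}", 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(f"expected 7 fields, got {len(fields)}", lineno)
            symbol, subfamily, locus, position_s, tss_s, orientation, p_s = fields
            try:
                position = _normalize_position(position_s)
                tss_key = tss_s.strip().lower()
                if tss_key not in _TSS_TOKENS:
                    raise ValueError(f"unknown TSS token {tss_s!r}")
                record = CandidateRecord(
                    gene_symbol=symbol,
                    subfamily=subfamily,
                    locus=locus,
                    position=position,
                    tss=_TSS_TOKENS[tss_key],
                    orientation=orientation.strip().capitalize(),
                    p_value=_parse_pvalue(p_s),
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            records.append(record)
    return records


def summarize_candidates(records: Sequence[CandidateRecord]) -> CandidateSummary:
    """Tallies over a candidate table: row and distinct-gene counts,
    position/family/orientation breakdowns, TSS-positive counts split by
    position, and the largest p-value."""
    by_position = Counter(rec.position for rec in records)
    by_family = Counter(rec.family for rec in records)
    by_orientation = Counter(rec.orientation for rec in records)
    tss_positive = [rec for rec in records if rec.tss != "no"]
    return CandidateSummary(
        n_rows=len(records),
        n_genes=len({rec.gene_symbol for rec in records}),
        by_position={pos: by_position.get(pos, 0) for pos in POSITIONS},
        by_family=dict(sorted(by_family.items())),
        by_orientation={o: by_orientation.get(o, 0) for o in ORIENTATIONS},
        n_tss=len(tss_positive),
        n_tss_intron=sum(1 for rec in tss_positive if rec.position == "Intron"),
        n_tss_utr3=sum(1 for rec in tss_positive if rec.position == "UTR3"),
        max_p=max((rec.p_value for rec in records), default=0.0),
    )


def load_published_candidates() -> list[CandidateRecord]:
    """The packaged transcription of the published 48-row candidate table
    (48 Alu insertions in 26 immune genes from the sepsis cohort)."""
    ref = resources.files("alulnc").joinpath("data/published_candidates.tsv")
    with resources.as_file(ref) as path:
        return read_candidate_table(path)
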