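"""Alu element catalog: filter a RepeatMasker-style repeat track down to
Alu elements and classify each subfamily into one of the three families
(AluJ, AluS, AluY — oldest to youngest)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .genome_io import GenomicInterval, read_bed, read_gtf, write_bed

logger = logging.getLogger(__name__)

ALU_FAMILIES = ("AluJ", "AluS", "AluY")

_FAMILY_BY_LETTER = {"J": "AluJ", "S": "AluS", "Y": "AluY"}


class FamilyError(ValueError):
    """Subfamily name whose family letter is not one of J, S, Y."""


@dataclass(frozen=True)
class RepeatElement:
    """One genomic Alu copy: stranded interval, subfamily name, family."""

    interval: GenomicInterval
    subfamily: str
    family: str

    def __post_init__(self) -> None:
        if not self.subfamily.startswith("Alu"):
            raise ValueError(f"subfamily {self.subfamily!r} does not start with 'Alu'")
        if self.family != alu_family(self.subfamily):
            raise ValueError(
                f"family {self.family!r} inconsistent with subfamily {self.subfamily!r}"
            )


def is_alu(name: str) -> bool:
    """True iff the repeat name starts with the exact prefix ``Alu``.

    Free left/right Alu monomers (FLAM/FRAM) and other SINEs fail the
    prefix rule and are excluded.
    """
    return name.startswith("Alu")


def alu_family(subfamily: str) -> str:
    """Classify an Alu subfamily name into AluJ / AluS / AluY.

    The family is read from the character following the ``Alu`` prefix
    (e.g. AluSx1 -> AluS, AluJo -> AluJ, AluY -> AluY).
    """
    if not is_alu(subfamily):
        raise ValueError(f"{subfamily!r} is not an Alu subfamily name")
    letter = subfamily[3:4]
    try:
        return _FAMILY_BY_LETTER[letter]
    except KeyError:
        raise FamilyError(
            f"cannot classify {subfamily!r}: family letter {letter!r} not in J/S/Y"
        ) from None


def build_catalog(
    records: Iterable[tuple[GenomicInterval, str]],
) -> list[RepeatElement]:
    """Filter ``(interval, name)`` repeat records down to classified Alus.

    Non-Alu records are silently filtered (count logged); Alu-named
    records whose family letter cannot be classified are dropped with a
    warning. The catalog is sorted by (chrom, start).
    """
    catalog: list[RepeatElement] = []
    n_dropped_non_alu = 0
    for interval, name in records:
        if not is_alu(name):
            n_dropped_non_alu += 1
            continue
        try:
            family = alu_family(name)
        except FamilyError as exc:
            logger.warning("excluding repeat at %s: %s", interval.locus_string(), exc)
            continue
        catalog.append(RepeatElement(interval, name, family))
    if n_dropped_non_alu:
        logger.info("filtered %d non-Alu repeat records", n_dropped_non_alu)
    catalog.sort(key=lambda el: (el.interval.chrom, el.interval.start, el.interval.end))
    return catalog


def catalog_from_bed(path) -> list[RepeatElement]:
    """Build the Alu catalog from a BED repeat track (name column = subfamily)."""
    return build_catalog((interval, name) for interval, name, _ in read_bed(path))


def catalog_from_gtf(path) -> list[RepeatElement]:
    """Build the Alu catalog from a RepeatMasker-dialect GTF export."""
    records = read_gtf(path, dialect="repeatmasker")
    return build_catalog((rec.interval, rec.name or "") for rec in records)


def write_catalog(path, catalog: Iterable[RepeatElement]) -> None:
    """Write the catalog as BED6 with the subfamily in the name column."""
    write_bed(path, ((el.interval, el.subfamily, 0.0) for el in catalog))


def family_counts(catalog: Iterable[RepeatElement]) -> dict[str, int]:
    counts = {fam: 0 for fam in ALU_FAMILIES}
    for el in catalog:
        counts[el.family] += 1
    return counts
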