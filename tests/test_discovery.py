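"""Interval index, fractional-overlap intersection, position labels,
orientation calls, and CAGE-TSS linkage."""

import random

import pytest

from alulnc.discovery import (
    IntervalIndex,
    TssRecord,
    build_interval_index,
    call_orientation,
    candidate_insertions,
    classify_position,
    intersect_genes_alus,
    link_tss,
)
from alulnc.genes import FeatureSet, GeneModel, TranscriptModel
from alulnc.genome_io import GenomicInterval
from alulnc.repeats import RepeatElement


def _repeat(start, end, strand="+", subfamily="AluSx1", chrom="chr1"):
    return RepeatElement(
        GenomicInterval(chrom, start, end, strand), subfamily, "AluS"
    )


class TestIntervalIndex:
    def test_overlap_hit_and_halfopen_boundary(self):
        idx = build_interval_index([(GenomicInterval("chr1", 0, 10), "a")])
        assert [p for _, p in idx.query("chr1", 5, 6)] == ["a"]
        assert idx.query("chr1", 10, 20) == []
        assert idx.query("chr2", 0, 10) == []

    def test_matches_brute_force_scan(self):
        rng = random.Random(11)
        stored = []
        for i in range(200):
            chrom = f"chr{rng.randrange(1, 4)}"
            s = rng.randrange(0, 5000)
            stored.append((GenomicInterval(chrom, s, s + rng.randrange(1, 400)), i))
        idx = build_interval_index(stored)
        for _ in range(50):
            chrom = f"chr{rng.randrange(1, 4)}"
            qs = rng.randrange(0, 5000)
            qe = qs + rng.randrange(1, 400)
            expected = {
                payload
                for iv, payload in stored
                if iv.chrom == chrom and iv.start < qe and qs < iv.end
            }
            assert {p for _, p in idx.query(chrom, qs, qe)} == expected


def _gene(start, end, gene_id="G1", strand="+", chrom="chr1"):
    iv = GenomicInterval(chrom, start, end, strand)
    tx = TranscriptModel("T1", gene_id, strand, [iv])
    return GeneModel(gene_id, gene_id, iv, strand, [tx])


class TestIntersect:
    def test_default_fraction_reports_pair(self):
        pairs = intersect_genes_alus([_gene(0, 1000)], [_repeat(500, 800)])
        assert len(pairs) == 1 and pairs[0][2] == 300

    def test_long_gene_drops_short_alu(self):
        # gene fraction rule: floor = ceil(0.009 * 100000) = 900 > 300
        pairs = intersect_genes_alus([_gene(0, 100_000)], [_repeat(500, 800)])
        assert pairs == []

    def test_alu_denominator_mode_recovers_it(self):
        pairs = intersect_genes_alus(
            [_gene(0, 100_000)], [_repeat(500, 800)], overlap_denominator="alu"
        )
        assert len(pairs) == 1

    def test_alu_spanning_two_genes_reported_twice(self):
        genes = [_gene(0, 1000, "G1"), _gene(900, 2000, "G2")]
        pairs = intersect_genes_alus(genes, [_repeat(850, 1100)])
        assert {g.id for g, _, _ in pairs} == {"G1", "G2"}

    def test_matches_brute_force_fraction_scan(self):
        rng = random.Random(5)
        genes = []
        for i in range(200):
            s = rng.randrange(0, 200_000)
            genes.append(_gene(s, s + rng.randrange(500, 40_000), f"G{i}",
                               chrom=f"chr{rng.randrange(1, 3)}"))
        alus = []
        for i in range(200):
            s = rng.randrange(0, 200_000)
            alus.append(_repeat(s, s + rng.randrange(100, 350), chrom=f"chr{rng.randrange(1, 3)}"))
        import math

        expected = set()
        for g in genes:
            for a in alus:
                ov = g.interval.overlap_bp(a.interval)
                if ov >= math.ceil(0.009 * g.interval.length):
                    expected.add((g.id, a.interval.start, a.interval.chrom))
        got = {
            (g.id, a.interval.start, a.interval.chrom)
            for g, a, _ in intersect_genes_alus(genes, alus)
        }
        assert got == expected


def _features(introns=(), utr5=(), utr3=(), cds=()):
    mk = lambda spans: [GenomicInterval("chr1", s, e, "+") for s, e in spans]
    return FeatureSet("G1", mk(introns), mk(utr5), mk(utr3), mk(cds))


class TestClassifyPosition:
    def test_wholly_intronic(self):
        fs = _features(introns=[(1000, 3000)], cds=[(0, 1000), (3000, 4000)])
        assert classify_position(_repeat(1500, 1800), fs) == "Intron"

    def test_wholly_utr3(self):
        fs = _features(utr3=[(4000, 5000)], cds=[(0, 4000)])
        assert classify_position(_repeat(4100, 4400), fs) == "UTR3"

    def test_majority_rule(self):
        # 180 bp intron overlap vs 120 bp utr3 overlap -> Intron
        fs = _features(introns=[(0, 180)], utr3=[(180, 400)])
        assert classify_position(_repeat(0, 300), fs) == "Intron"

    def test_tie_prefers_utr3(self):
        fs = _features(introns=[(0, 150)], utr3=[(150, 300)])
        assert classify_position(_repeat(0, 300), fs) == "UTR3"

    def test_outside_features_inside_gene_is_intron(self):
        fs = _features(cds=[(0, 100)])
        gene_iv = GenomicInterval("chr1", 0, 10_000)
        assert classify_position(_repeat(5000, 5300), fs, gene_iv) == "Intron"

    def test_outside_gene_is_error(self):
        fs = _features(cds=[(0, 100)])
        with pytest.raises(ValueError):
            classify_position(_repeat(5000, 5300), fs, GenomicInterval("chr1", 0, 1000))

    def test_label_totality_on_random_pairs(self):
        rng = random.Random(3)
        fs = _features(
            introns=[(1000, 2000), (3000, 5000)],
            utr5=[(0, 200)],
            utr3=[(6000, 7000)],
            cds=[(200, 1000), (2000, 3000), (5000, 6000)],
        )
        labels = [
            classify_position(_repeat(s := rng.randrange(0, 6900), s + 300), fs)
            for _ in range(100)
        ]
        assert all(l in ("Intron", "UTR5", "UTR3", "CDS_exon") for l in labels)


class TestOrientation:
    @pytest.mark.parametrize(
        "r,g,expected",
        [("+", "+", "Sense"), ("-", "-", "Sense"), ("-", "+", "Inverted"), ("+", "-", "Inverted")],
    )
    def test_calls(self, r, g, expected):
        assert call_orientation(r, g) == expected

    def test_unstranded_repeat_is_error(self):
        with pytest.raises(ValueError):
            call_orientation(".", "+")


class TestLinkTss:
    def test_upstream_300(self):
        flag, dist = link_tss(_repeat(10_000, 10_300), "+", [TssRecord("chr1", 9700, "+")])
        assert (flag, dist) == ("upstream", 300)

    def test_exactly_window_not_linked(self):
        flag, dist = link_tss(_repeat(10_000, 10_300), "+", [TssRecord("chr1", 9000, "+")])
        assert (flag, dist) == ("none", None)

    def test_strand_mismatch_not_linked(self):
        flag, _ = link_tss(_repeat(10_000, 10_300), "+", [TssRecord("chr1", 9700, "-")])
        assert flag == "none"

    def test_unstranded_tss_matches_either(self):
        flag, dist = link_tss(_repeat(10_000, 10_300), "+", [TssRecord("chr1", 9700, ".")])
        assert (flag, dist) == ("upstream", 300)

    def test_internal_5prime_at_40_percent(self):
        # 300 bp element, TSS 120 bp in (40%) -> within the 5' half
        flag, dist = link_tss(_repeat(10_000, 10_300), "+", [TssRecord("chr1", 10_120, "+")])
        assert (flag, dist) == ("internal_5prime", None)

    def test_internal_3prime_half_not_linked(self):
        flag, _ = link_tss(_repeat(10_000, 10_300), "+", [TssRecord("chr1", 10_200, "+")])
        assert flag == "none"

    def test_upstream_takes_precedence_and_min_distance(self):
        tss = [TssRecord("chr1", 9_500, "+"), TssRecord("chr1", 9_900, "+"),
               TssRecord("chr1", 10_050, "+")]
        flag, dist = link_tss(_repeat(10_000, 10_300), "+", tss)
        assert (flag, dist) == ("upstream", 100)

    def test_minus_strand_mirror(self):
        # mirror of the upstream-300 case around L = 20,600
        flag, dist = link_tss(
            _repeat(10_300, 10_600, strand="-"), "-", [TssRecord("chr1", 10_899, "-")]
        )
        assert (flag, dist) == ("upstream", 300)

    def test_translation_invariance(self):
        shift = 123_456
        tss = [TssRecord("chr1", 9700, "+"), TssRecord("chr1", 10_120, "+")]
        base = link_tss(_repeat(10_000, 10_300), "+", tss)
        moved = link_tss(
            _repeat(10_000 + shift, 10_300 + shift), "+",
            [TssRecord("chr1", t.pos + shift, t.strand) for t in tss],
        )
        assert base == moved

    def test_full_mirror_invariance(self):
        """Mirroring the whole locus (coordinates reversed, strands flipped)
        leaves flags and distances unchanged."""
        L = 50_000
        tss = [TssRecord("chr1", 9700, "+"), TssRecord("chr1", 10_120, "+"),
               TssRecord("chr1", 11_000, "-")]
        for start, end in [(10_000, 10_300), (9_000, 9_290)]:
            base = link_tss(_repeat(start, end), "+", tss)
            mirrored = link_tss(
                _repeat(L - end, L - start, strand="-"),
                "-",
                [TssRecord("chr1", L - 1 - t.pos, "-" if t.strand == "+" else "+") for t in tss],
            )
            assert base == mirrored


def test_candidate_insertions_drop_cds(sim50):
    ann, genes, catalog, tss = sim50
    from alulnc.discovery import discover_insertions

    ins = discover_insertions(genes, catalog, tss)
    assert candidate_insertions(ins) == [i for i in ins if i.position != "CDS_exon"]
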