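"""Annotation parsing, flattening, two-step disjoin and disambiguation."""

import pytest

from catquant import (
    AnnotationError,
    GeneRecord,
    GenomicInterval,
    disambiguate,
    disjoin_cross_strand,
    disjoin_same_strand,
    filter_ambiguous,
    flatten_gene,
    normalize_chrom,
    overlap_positions,
    read_annotation,
    read_segments,
    write_segments,
)

from conftest import brute_force_retained, per_base_owners, random_annotation, segmap_base_sets


# ---------------------------------------------------------------- parsing


def test_bed12_two_blocks_one_transcript(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text("chr1\t100\t300\tgeneX\t0\t+\t100\t300\t0\t2\t50,60\t0,140\n")
    genes = read_annotation(bed, format="bed12")
    assert len(genes) == 1
    (g,) = genes
    assert g.gene_id == "geneX" and g.strand == "+"
    assert len(g.transcripts) == 1
    assert [(e.start, e.end) for e in g.transcripts[0]] == [(100, 150), (240, 300)]


def test_bed12_lines_sharing_name_become_transcripts(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text(
        "chr1\t100\t200\tA\t0\t+\t100\t200\t0\t1\t100\t0\n"
        "chr1\t150\t250\tA\t0\t+\t150\t250\t0\t1\t100\t0\n"
    )
    (g,) = read_annotation(bed, format="bed12")
    assert len(g.transcripts) == 2


def test_bed12_malformed_line_names_line_number(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text(
        "chr1\t100\t200\tA\t0\t+\t100\t200\t0\t1\t100\t0\n"
        "chr1\t100\tnot_an_int\tB\t0\t+\n"
    )
    with pytest.raises(AnnotationError, match=":2"):
        read_annotation(bed, format="bed12")


def test_bed12_unstranded_record_rejected_with_warning(tmp_path, caplog):
    bed = tmp_path / "a.bed"
    bed.write_text(
        "chr1\t100\t200\tA\t0\t.\t100\t200\t0\t1\t100\t0\n"
        "chr1\t300\t400\tB\t0\t+\t300\t400\t0\t1\t100\t0\n"
    )
    with caplog.at_level("WARNING", logger="catquant"):
        genes = read_annotation(bed, format="bed12")
    assert [g.gene_id for g in genes] == ["B"]
    assert any("rejecting" in r.message for r in caplog.records)


def test_gtf_coordinates_converted_and_transcripts_grouped(tmp_path):
    gtf = tmp_path / "a.gtf"
    gtf.write_text(
        'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "A"; transcript_id "A.1"; gene_type "mRNA";\n'
        'chr1\tx\texon\t151\t250\t.\t+\t.\tgene_id "A"; transcript_id "A.2"; gene_type "mRNA";\n'
    )
    (g,) = read_annotation(gtf, format="gtf")
    assert g.category == "mRNA"
    assert len(g.transcripts) == 2
    # 1-based closed [101,200] -> 0-based half-open [100,200)
    assert (g.transcripts[0][0].start, g.transcripts[0][0].end) == (100, 200)


def test_category_sidecar_and_map(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text("chr1\t0\t100\tA\t0\t+\t0\t100\t0\t1\t100\t0\n")
    side = tmp_path / "cats.tsv"
    side.write_text("gene_id\tcategory\tsymbol\nA\tenhancer\tSYM1\n")
    (g,) = read_annotation(
        bed, format="bed12", category_table=side,
        category_map={"enhancer": "e-lncRNA"},
    )
    assert g.category == "e-lncRNA" and g.symbol == "SYM1"
    # unmappable categories fall back to "other"
    (g2,) = read_annotation(bed, format="bed12", category_table=side)
    assert g2.category == "other"


@pytest.mark.parametrize(
    "name,style,expected",
    [("1", "ucsc", "chr1"), ("chr1", "ensembl", "1"), ("MT", "ucsc", "chrM"),
     ("chrM", "ensembl", "MT"), ("chr7", "as-is", "chr7")],
)
def test_chrom_style_normalization(name, style, expected):
    assert normalize_chrom(name, style) == expected


# ---------------------------------------------------------------- flatten


@pytest.mark.parametrize(
    "exon_sets,expected",
    [
        ([[(100, 200)], [(150, 250)]], [(100, 250)]),  # two overlapping isoforms
        ([[(5, 10)]], [(5, 10)]),
        ([[(0, 10), (20, 30)]], [(0, 10), (20, 30)]),  # untouched when disjoint
    ],
)
def test_flatten_gene_is_exon_union(exon_sets, expected):
    g = GeneRecord(
        "g", "chr1", "+",
        transcripts=[
            [GenomicInterval("chr1", s, e, "+") for s, e in tx] for tx in exon_sets
        ],
    )
    assert [(iv.start, iv.end) for iv in flatten_gene(g)] == expected


# ---------------------------------------------------------------- disjoin


def _gene(gid, strand, *exons):
    return GeneRecord(
        gid, "chr1", strand,
        transcripts=[[GenomicInterval("chr1", s, e, strand) for s, e in exons]],
    )


def test_disjoin_same_strand_splits_at_union_boundaries():
    a = GeneRecord(
        "A", "chr1", "+",
        transcripts=[[GenomicInterval("chr1", 100, 200, "+")],
                     [GenomicInterval("chr1", 150, 250, "+")]],
    )
    b = _gene("B", "+", (180, 220))
    segs = disjoin_same_strand([a, b], "+")
    got = {(s.interval.start, s.interval.end): set(s.owners) for s in segs}
    assert got == {(100, 180): {"A"}, (180, 220): {"A", "B"}, (220, 250): {"A"}}


def test_disjoin_same_strand_identical_genes_share_one_segment():
    a, b = _gene("A", "+", (10, 50)), _gene("B", "+", (10, 50))
    (seg,) = disjoin_same_strand([a, b], "+")
    assert seg.owners == {"A", "B"}


def test_disjoin_cross_strand_splits_and_pools_owners():
    plus = disjoin_same_strand([_gene("A", "+", (220, 250))], "+")
    minus = disjoin_same_strand([_gene("C", "-", (230, 300))], "-")
    segs = disjoin_cross_strand(plus, minus)
    got = {(s.interval.start, s.interval.end): set(s.owners) for s in segs}
    assert got == {(220, 230): {"A"}, (230, 250): {"A", "C"}, (250, 300): {"C"}}
    mixed = [s for s in segs if s.interval.start == 230]
    assert mixed[0].origin_strands == {"+", "-"}


def test_disjoin_cross_strand_empty_minus_is_identity():
    plus = disjoin_same_strand([_gene("A", "+", (0, 100)), _gene("B", "+", (50, 150))], "+")
    assert disjoin_cross_strand(plus, []) == sorted(
        plus, key=lambda s: (s.interval.chrom, s.interval.start)
    )


def test_disjoin_idempotent_on_disambiguated_segments():
    genes = random_annotation(3)
    segmap = disambiguate(genes)
    # feed retained single-owner segments back through both steps
    strand_of = {g.gene_id: g.strand for g in genes}
    from catquant import LabeledSegment
    plus, minus = [], []
    for iv, gid in segmap.segments:
        seg = LabeledSegment(iv, frozenset({gid}), frozenset({strand_of[gid]}))
        (plus if strand_of[gid] == "+" else minus).append(seg)
    again = filter_ambiguous(disjoin_cross_strand(plus, minus), genes)
    assert segmap_base_sets(again) == segmap_base_sets(segmap)
    assert again.gene_length == segmap.gene_length


# ------------------------------------------------------------ filter + map


def test_figure5_disambiguation(figure5):
    segmap = disambiguate(figure5)
    assert [(iv.start, iv.end, g) for iv, g in segmap.segments] == [
        (100, 180, "geneA"), (220, 230, "geneA"), (250, 300, "geneC")
    ]
    assert segmap.gene_length == {"geneA": 90, "geneC": 50}
    assert segmap.dropped_genes == {"geneB": "fully ambiguous"}
    assert segmap.dropped_bases == 60


def test_fully_coincident_genes_both_dropped():
    genes = [_gene("A", "+", (10, 50)), _gene("B", "-", (10, 50))]
    segmap = disambiguate(genes)
    assert segmap.segments == []
    assert set(segmap.dropped_genes) == {"A", "B"}
    assert segmap.dropped_bases == 40


def test_single_gene_nothing_dropped():
    g = _gene("A", "+", (10, 50), (60, 80))
    segmap = disambiguate([g])
    assert segmap.dropped_bases == 0 and not segmap.dropped_genes
    assert segmap.gene_length == {"A": 60}


@pytest.mark.parametrize("seed", range(40))
def test_disambiguation_matches_per_base_oracle(seed):
    """Retained base sets equal the brute-force 'covered by exactly one
    gene, strand ignored' labeling, and the partition accounting holds."""
    genes = random_annotation(seed)
    segmap = disambiguate(genes)
    assert segmap_base_sets(segmap) == brute_force_retained(genes)
    # partition: retained + dropped = all covered bases
    covered = len(per_base_owners(genes))
    retained = sum(segmap.gene_length.values())
    assert retained + segmap.dropped_bases == covered
    # disjointness
    seen = set()
    for iv, _ in segmap.segments:
        bases = {(iv.chrom, b) for b in range(iv.start, iv.end)}
        assert not bases & seen
        seen |= bases


@pytest.mark.parametrize("seed", [1, 11, 23])
def test_gene_order_invariance(seed):
    genes = random_annotation(seed)
    a = disambiguate(genes)
    b = disambiguate(list(reversed(genes)))
    assert a.segments == b.segments
    assert a.gene_length == b.gene_length
    assert a.dropped_genes == b.dropped_genes


def test_segment_map_round_trip(tmp_path, figure5):
    segmap = disambiguate(figure5)
    prefix = tmp_path / "fig5"
    write_segments(segmap, prefix)
    back = read_segments(prefix)
    assert back.segments == segmap.segments
    assert back.gene_length == segmap.gene_length
    assert back.dropped_genes == segmap.dropped_genes
    assert back.dropped_bases == segmap.dropped_bases
    assert back.gene_meta == segmap.gene_meta


def test_empty_segment_map_round_trip(tmp_path):
    from catquant import SegmentMap
    empty = SegmentMap([], {}, {}, 0, {})
    write_segments(empty, tmp_path / "empty")
    back = read_segments(tmp_path / "empty")
    assert back.segments == [] and back.gene_length == {}


def test_duplicate_segment_rows_rejected(tmp_path, figure5):
    prefix = tmp_path / "dup"
    write_segments(disambiguate(figure5), prefix)
    bed = prefix.with_name("dup.segments.bed")
    line = bed.read_text().splitlines()[0]
    bed.write_text(bed.read_text() + line + "\n")
    with pytest.raises(AnnotationError, match="duplicate"):
        read_segments(prefix)


# ---------------------------------------------------------- SNP overlap


def test_position_overlap_boundary_convention():
    """1-based p overlaps 0-based [s,e) iff s < p <= e: position 100 sits
    just left of [100,300) while 101 is its first base."""
    regions = {"G": GenomicInterval("chr1", 100, 300, "+")}
    hits = overlap_positions(regions, [("chr1", 100), ("chr1", 101),
                                       ("chr1", 120), ("chr1", 300), ("chr1", 301)])
    assert hits["G"].count == 3
    assert [p for _, p in hits["G"].positions] == [101, 120, 300]


def test_position_overlap_zero_counts_and_unknown_chrom(caplog):
    regions = {
        "G": GenomicInterval("chr1", 100, 300, "+"),
        "H": GenomicInterval("chr2", 0, 10, "-"),
    }
    with caplog.at_level("WARNING", logger="catquant"):
        hits = overlap_positions(regions, [("chrX", 5)])
    assert hits["G"].count == 0 and hits["H"].count == 0
    assert any("chrX" in r.message for r in caplog.records)
    assert overlap_positions(regions, [])["G"].count == 0
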