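"""Gene models: annotation parsing, exon disjoin, and cross-strand disambiguation.

Unstranded coverage tracks cannot attribute signal at a base that is exonic
for more than one gene, whether those genes overlap on the same strand or on
opposite strands.  This module implements the two-step procedure that makes
gene-level quantification from such tracks well defined:

1. within each strand, flatten every gene's isoforms to an exon union and
   disjoin overlapping unions into maximal segments labeled with the exact
   set of covering genes;
2. split those segments again at every boundary of the opposite strand's
   segments, pooling owners across strands;
3. discard every segment owned by more than one gene.

What survives is a :class:`SegmentMap`: pairwise-disjoint exonic segments,
each attributable to exactly one gene, together with each gene's retained
length ``L_g`` (the effective length used downstream for TPM) and a log of
what was dropped and why.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("catquant")

CATEGORIES = ("mRNA", "e-lncRNA", "dp-lncRNA", "ip-lncRNA", "other")

#: strand tokens accepted on input; the unicode minus shows up in hand-edited files
_MINUS_ALIASES = {"-", "−"}


class AnnotationError(ValueError):
    """Malformed annotation input (carries the offending line number)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome.

    ``strand`` is "+", "-" or "." (the latter for strand-pooled segments).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneRecord:
    """One annotated gene: its transcripts' exons, strand and RNA category."""

    gene_id: str
    chrom: str
    strand: str
    category: str = "other"
    symbol: str | None = None
    transcripts: list[list[GenomicInterval]] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        for tx in self.transcripts:
            if not tx:
                raise ValueError(f"gene {self.gene_id}: empty transcript")
            for ex in tx:
                if ex.chrom != self.chrom:
                    raise ValueError(
                        f"gene {self.gene_id}: exon on {ex.chrom} != {self.chrom}"
                    )

    @property
    def span(self) -> GenomicInterval:
        """Gene span: min exon start to max exon end."""
        exons = [ex for tx in self.transcripts for ex in tx]
        return GenomicInterval(
            self.chrom,
            min(ex.start for ex in exons),
            max(ex.end for ex in exons),
            self.strand,
        )


@dataclass(frozen=True)
class LabeledSegment:
    """A disjoint exonic segment with the exact set of genes covering it."""

    interval: GenomicInterval
    owners: frozenset[str]
    origin_strands: frozenset[str]

    def __post_init__(self) -> None:
        if not self.owners:
            raise ValueError("segment with no owners")


@dataclass
class SegmentMap:
    """Disambiguated segments, each owned by exactly one gene.

    ``gene_length`` maps each surviving gene to its retained length L_g;
    ``gene_meta`` carries (symbol, category, strand) per gene including
    dropped ones, so the sidecar tables can be written.
    """

    segments: list[tuple[GenomicInterval, str]]
    gene_length: dict[str, int]
    dropped_genes: dict[str, str]
    dropped_bases: int
    gene_meta: dict[str, tuple[str | None, str, str]] = field(default_factory=dict)

    def validate(self) -> None:
        lengths: dict[str, int] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv, gid in self.segments:
            lengths[gid] = lengths.get(gid, 0) + len(iv)
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        if lengths != self.gene_length:
            raise ValueError("gene_length inconsistent with segments")
        if any(v <= 0 for v in self.gene_length.values()):
            raise ValueError("non-positive retained gene length")
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping segments on {chrom}")

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_length)


@dataclass
class PositionOverlap:
    """SNP positions falling inside one gene's region."""

    count: int
    positions: list[tuple[str, int]]


# ---------------------------------------------------------------------------
# chromosome-name dialects
# ---------------------------------------------------------------------------


def normalize_chrom(name: str, style: str = "as-is") -> str:
    """Convert a chromosome name to the requested dialect.

    ``ucsc`` prefixes "chr" (MT -> chrM); ``ensembl`` strips it
    (chrM -> MT); ``as-is`` leaves the name alone.  Applied identically to
    annotation, coverage, and SNP inputs so the dialects can never disagree.
    """
    if style == "as-is":
        return name
    if style == "ensembl":
        if name.startswith("chr"):
            name = name[3:]
        return "MT" if name == "M" else name
    if style == "ucsc":
        if name in ("MT", "chrMT"):
            return "chrM"
        return name if name.startswith("chr") else "chr" + name
    raise ValueError(f"unknown chrom style {style!r}")


def _norm_strand(token: str) -> str:
    return "-" if token in _MINUS_ALIASES else token


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------


def _map_category(raw: str | None, category_map: Mapping[str, str] | None) -> str:
    if raw is None:
        return "other"
    if category_map is not None and raw in category_map:
        return category_map[raw]
    return raw if raw in CATEGORIES else "other"


def read_annotation(
    path: str | Path,
    format: str = "bed12",
    category_map: Mapping[str, str] | None = None,
    category_table: str | Path | None = None,
    category_attr: str = "gene_type",
    chrom_style: str = "as-is",
) -> list[GeneRecord]:
    """Read a gene annotation into :class:`GeneRecord` objects.

    BED12: one line per transcript; the name column is the gene_id, so lines
    sharing a name become transcripts of one gene.  Categories and symbols
    come from an optional sidecar TSV (``gene_id<TAB>category[<TAB>symbol]``).

    GTF: 1-based closed exon coordinates are converted to 0-based half-open;
    transcripts are grouped by ``transcript_id`` under ``gene_id``; the
    category is read from ``category_attr`` (default ``gene_type``).

    Records with a strand other than +/- are rejected with a logged warning:
    unstranded genes cannot take part in cross-strand disambiguation.
    """
    path = Path(path)
    sidecar: dict[str, tuple[str, str | None]] = {}
    if category_table is not None:
        for lineno, line in enumerate(Path(category_table).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "gene_id\t")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise AnnotationError(
                    f"{category_table}:{lineno}: expected gene_id<TAB>category"
                )
            sidecar[parts[0]] = (parts[1], parts[2] if len(parts) > 2 else None)

    if format == "bed12":
        genes = _read_bed12(path, chrom_style)
    elif format == "gtf":
        genes = _read_gtf(path, category_attr, chrom_style)
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    out = []
    for g in genes:
        if g.category == "__sidecar__":
            raw, symbol = sidecar.get(g.gene_id, (None, None))
            g.category = _map_category(raw, category_map)
            g.symbol = symbol
        else:
            g.category = _map_category(g.category, category_map)
        g.validate()
        out.append(g)
    return out


def _read_bed12(path: Path, chrom_style: str) -> list[GeneRecord]:
    genes: dict[str, GeneRecord] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise AnnotationError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
        try:
            chrom = normalize_chrom(f[0], chrom_style)
            start, end = int(f[1]), int(f[2])
            name = f[3]
            strand = _norm_strand(f[5])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise AnnotationError(
                f"{path}:{lineno}: blockCount={n_blocks} but "
                f"{len(sizes)} sizes / {len(offsets)} starts"
            )
        if strand not in ("+", "-"):
            logger.warning("%s:%d: rejecting %s (strand %r)", path, lineno, name, f[5])
            continue
        exons = []
        for size, off in zip(sizes, offsets):
            ex_start = start + off
            if ex_start + size > end:
                raise AnnotationError(f"{path}:{lineno}: block exceeds chromEnd")
            exons.append(GenomicInterval(chrom, ex_start, ex_start + size, strand))
        rec = genes.get(name)
        if rec is None:
            rec = GeneRecord(name, chrom, strand, category="__sidecar__")
            genes[name] = rec
        rec.transcripts.append(exons)
    return list(genes.values())


def _parse_gtf_attrs(blob: str) -> dict[str, str]:
    attrs = {}
    for chunk in blob.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def _read_gtf(path: Path, category_attr: str, chrom_style: str) -> list[GeneRecord]:
    genes: dict[str, GeneRecord] = {}
    tx_index: dict[tuple[str, str], list[GenomicInterval]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 9:
            raise AnnotationError(f"{path}:{lineno}: GTF needs 9 columns, got {len(f)}")
        if f[2] != "exon":
            continue
        try:
            chrom = normalize_chrom(f[0], chrom_style)
            start1, end1 = int(f[3]), int(f[4])
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
        strand = _norm_strand(f[6])
        attrs = _parse_gtf_attrs(f[8])
        gid = attrs.get("gene_id")
        tid = attrs.get("transcript_id")
        if gid is None or tid is None:
            raise AnnotationError(f"{path}:{lineno}: missing gene_id/transcript_id")
        if strand not in ("+", "-"):
            logger.warning("%s:%d: rejecting %s (strand %r)", path, lineno, gid, f[6])
            continue
        # GTF is 1-based closed: [start1, end1] -> [start1-1, end1)
        exon = GenomicInterval(chrom, start1 - 1, end1, strand)
        rec = genes.get(gid)
        if rec is None:
            rec = GeneRecord(
                gid, chrom, strand,
                category=attrs.get(category_attr, "other"),
                symbol=attrs.get("gene_name"),
            )
            genes[gid] = rec
        key = (gid, tid)
        if key not in tx_index:
            tx_index[key] = []
            rec.transcripts.append(tx_index[key])
        tx_index[key].append(exon)
    return list(genes.values())


# ---------------------------------------------------------------------------
# flatten + two-step disjoin
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[GenomicInterval], strand: str | None = None
) -> list[GenomicInterval]:
    """Union of intervals on one chromosome: merged, sorted, pairwise disjoint."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        s = strand if strand is not None else iv.strand
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end, s)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end, s))
    return out


def flatten_gene(gene: GeneRecord) -> list[GenomicInterval]:
    """Exon union over all isoforms of one gene.

    Isoform overlap within a gene is resolved here, before any cross-gene
    step, so it never creates ambiguity.
    """
    gene.validate()
    return merge_intervals(
        (ex for tx in gene.transcripts for ex in tx), strand=gene.strand
    )


def _atoms(
    per_gene: Mapping[str, Sequence[GenomicInterval]],
    strand_of: Mapping[str, str],
) -> list[LabeledSegment]:
    """Split exon unions at every boundary; label each atom with its owners.

    Because breakpoints include every union start/end, each atom is covered
    all-or-nothing by each gene, so per-atom ownership is exact.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, ivs in per_gene.items():
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gid))
    out: list[LabeledSegment] = []
    for chrom, triples in by_chrom.items():
        bps = sorted({p for s, e, _ in triples for p in (s, e)})
        owners: list[set[str]] = [set() for _ in range(len(bps) - 1)]
        for s, e, gid in triples:
            for i in range(bisect_left(bps, s), bisect_right(bps, e) - 1):
                owners[i].add(gid)
        for i, own in enumerate(owners):
            if own:
                out.append(
                    LabeledSegment(
                        GenomicInterval(chrom, bps[i], bps[i + 1]),
                        frozenset(own),
                        frozenset(strand_of[g] for g in own),
                    )
                )
    return _merge_bookended(out)


def _merge_bookended(segments: list[LabeledSegment]) -> list[LabeledSegment]:
    """Merge adjacent segments with identical owner sets.

    The breakpoint split can cut a run of bases with unchanged ownership;
    merging back keeps segment granularity from affecting per-gene totals.
    """
    segments = sorted(segments, key=lambda s: (s.interval.chrom, s.interval.start))
    out: list[LabeledSegment] = []
    for seg in segments:
        if (
            out
            and out[-1].interval.chrom == seg.interval.chrom
            and out[-1].interval.end == seg.interval.start
            and out[-1].owners == seg.owners
            and out[-1].origin_strands == seg.origin_strands
        ):
            out[-1] = LabeledSegment(
                GenomicInterval(
                    seg.interval.chrom, out[-1].interval.start, seg.interval.end
                ),
                seg.owners,
                seg.origin_strands,
            )
        else:
            out.append(seg)
    return out


def disjoin_same_strand(
    genes: Sequence[GeneRecord], strand: str
) -> list[LabeledSegment]:
    """Step 1: disjoin overlapping exon unions on one strand."""
    for g in genes:
        if g.strand != strand:
            raise ValueError(f"gene {g.gene_id} is not on strand {strand}")
    per_gene = {g.gene_id: flatten_gene(g) for g in genes}
    return _atoms(per_gene, {g.gene_id: strand for g in genes})


def disjoin_cross_strand(
    plus_segments: Sequence[LabeledSegment],
    minus_segments: Sequence[LabeledSegment],
) -> list[LabeledSegment]:
    """Step 2: split at opposite-strand boundaries and pool owners.

    The output is strand-pooled: each segment's owners are every gene, on
    either strand, whose exon union covers it, mirroring what an unstranded
    coverage track can and cannot tell apart.
    """
    per_gene: dict[str, list[GenomicInterval]] = {}
    strand_of: dict[str, str] = {}
    for segs in (plus_segments, minus_segments):
        for seg in segs:
            for gid in seg.owners:
                per_gene.setdefault(gid, []).append(seg.interval)
                (strand,) = seg.origin_strands
                strand_of[gid] = strand
    per_gene = {gid: merge_intervals(ivs) for gid, ivs in per_gene.items()}
    return _atoms(per_gene, strand_of)


def filter_ambiguous(
    segments: Sequence[LabeledSegment], genes: Sequence[GeneRecord]
) -> SegmentMap:
    """Step 3: discard every segment owned by more than one gene.

    Genes left with no segment at all are recorded in ``dropped_genes`` as
    "fully ambiguous" — they are unmeasurable, which is not the same as
    unexpressed, so they never appear as zero rows downstream.
    """
    strand_of = {g.gene_id: g.strand for g in genes}
    kept: list[tuple[GenomicInterval, str]] = []
    gene_length: dict[str, int] = {}
    dropped_bases = 0
    for seg in segments:
        if len(seg.owners) == 1:
            (gid,) = seg.owners
            iv = GenomicInterval(
                seg.interval.chrom,
                seg.interval.start,
                seg.interval.end,
                strand_of.get(gid, "."),
            )
            kept.append((iv, gid))
            gene_length[gid] = gene_length.get(gid, 0) + len(iv)
        else:
            dropped_bases += len(seg.interval)
    dropped = {
        g.gene_id: "fully ambiguous" for g in genes if g.gene_id not in gene_length
    }
    kept.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))
    meta = {g.gene_id: (g.symbol, g.category, g.strand) for g in genes}
    return SegmentMap(kept, gene_length, dropped, dropped_bases, meta)


def disambiguate(genes: Sequence[GeneRecord]) -> SegmentMap:
    """Full pipeline: flatten -> same-strand disjoin -> cross-strand -> filter."""
    plus = disjoin_same_strand([g for g in genes if g.strand == "+"], "+")
    minus = disjoin_same_strand([g for g in genes if g.strand == "-"], "-")
    return filter_ambiguous(disjoin_cross_strand(plus, minus), genes)


# ---------------------------------------------------------------------------
# segment map I/O (BED6 + sidecar TSVs)
# ---------------------------------------------------------------------------


def write_segments(segmap: SegmentMap, prefix: str | Path) -> None:
    """Write ``<prefix>.segments.bed`` (BED6, name = gene_id),
    ``<prefix>.genes.tsv`` and ``<prefix>.drops.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.segments.bed", "w") as fh:
        for iv, gid in segmap.segments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gid}\t0\t{iv.strand}\n")
    n_seg: dict[str, int] = {}
    for _, gid in segmap.segments:
        n_seg[gid] = n_seg.get(gid, 0) + 1
    with open(f"{prefix}.genes.tsv", "w") as fh:
        fh.write("gene_id\tsymbol\tcategory\tstrand\tlength\tn_segments\n")
        for gid in segmap.gene_ids:
            symbol, category, strand = segmap.gene_meta.get(gid, (None, "other", "."))
            fh.write(
                f"{gid}\t{symbol or ''}\t{category}\t{strand}\t"
                f"{segmap.gene_length[gid]}\t{n_seg[gid]}\n"
            )
    with open(f"{prefix}.drops.tsv", "w") as fh:
        fh.write(f"# dropped_bases={segmap.dropped_bases}\n")
        fh.write("gene_id\tsymbol\tcategory\tstrand\treason\n")
        for gid in sorted(segmap.dropped_genes):
            symbol, category, strand = segmap.gene_meta.get(gid, (None, "other", "."))
            fh.write(
                f"{gid}\t{symbol or ''}\t{category}\t{strand}\t"
                f"{segmap.dropped_genes[gid]}\n"
            )


def read_segments(prefix: str | Path) -> SegmentMap:
    """Read a segment map written by :func:`write_segments` (round-trip)."""
    prefix = Path(prefix)
    segments: list[tuple[GenomicInterval, str]] = []
    seen: set[tuple[str, int, int, str]] = set()
    bed = Path(f"{prefix}.segments.bed")
    for lineno, line in enumerate(bed.read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise AnnotationError(f"{bed}:{lineno}: BED6 needs 6 columns")
        chrom, start, end, gid, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        key = (chrom, start, end, gid)
        if key in seen:
            raise AnnotationError(f"{bed}:{lineno}: duplicate segment {key}")
        seen.add(key)
        segments.append((GenomicInterval(chrom, start, end, strand), gid))
    gene_length: dict[str, int] = {}
    meta: dict[str, tuple[str | None, str, str]] = {}
    for line in Path(f"{prefix}.genes.tsv").read_text().splitlines()[1:]:
        gid, symbol, category, strand, length, _ = line.split("\t")
        gene_length[gid] = int(length)
        meta[gid] = (symbol or None, category, strand)
    dropped: dict[str, str] = {}
    dropped_bases = 0
    for line in Path(f"{prefix}.drops.tsv").read_text().splitlines():
        if line.startswith("# dropped_bases="):
            dropped_bases = int(line.split("=")[1])
            continue
        if not line.strip() or line.startswith("gene_id\t"):
            continue
        gid, symbol, category, strand, reason = line.split("\t")
        dropped[gid] = reason
        meta[gid] = (symbol or None, category, strand)
    segmap = SegmentMap(segments, gene_length, dropped, dropped_bases, meta)
    segmap.validate()
    return segmap


# ---------------------------------------------------------------------------
# SNP / position overlap
# ---------------------------------------------------------------------------


def overlap_positions(
    regions: Mapping[str, GenomicInterval],
    positions: Sequence[tuple[str, int]],
) -> dict[str, PositionOverlap]:
    """Count 1-based positions (e.g. GWAS SNPs) inside each gene's region.

    A 1-based position ``p`` overlaps the 0-based half-open region
    ``[s, e)`` iff ``s < p <= e`` (position p occupies 0-based base p-1).
    Genes with zero overlaps are included; positions on chromosomes absent
    from the regions are counted as non-overlapping and logged.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, iv in regions.items():
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gid))
    out = {gid: PositionOverlap(0, []) for gid in regions}
    missing: set[str] = set()
    for chrom, pos in positions:
        if chrom not in by_chrom:
            if chrom not in missing:
                logger.warning("position chromosome %s not in annotation", chrom)
                missing.add(chrom)
            continue
        for s, e, gid in by_chrom[chrom]:
            if s < pos <= e:
                out[gid].count += 1
                out[gid].positions.append((chrom, pos))
    return out
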