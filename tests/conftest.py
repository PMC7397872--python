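"""Shared fixtures and the brute-force per-base labeling oracle."""

from __future__ import annotations

import numpy as np
import pytest

from catquant import GeneRecord, GenomicInterval, figure5_genes


def per_base_owners(genes):
    """Label every base with the set of genes whose exons cover it,
    strand ignored — the independent oracle for the disjoin pipeline."""
    cover: dict[tuple[str, int], set[str]] = {}
    for g in genes:
        for tx in g.transcripts:
            for ex in tx:
                for b in range(ex.start, ex.end):
                    cover.setdefault((ex.chrom, b), set()).add(g.gene_id)
    return cover


def brute_force_retained(genes):
    """Per-gene retained base sets: bases covered by exactly that gene."""
    retained: dict[str, set[tuple[str, int]]] = {}
    for base, owners in per_base_owners(genes).items():
        if len(owners) == 1:
            (gid,) = owners
            retained.setdefault(gid, set()).add(base)
    return retained


def segmap_base_sets(segmap):
    """Per-gene base sets actually retained by a SegmentMap."""
    out: dict[str, set[tuple[str, int]]] = {}
    for iv, gid in segmap.segments:
        out.setdefault(gid, set()).update((iv.chrom, b) for b in range(iv.start, iv.end))
    return out


def random_annotation(seed: int, max_genes: int = 10, max_coord: int = 2000):
    """Small random two-strand annotation with <=3 isoforms per gene."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, max_genes + 1))
    genes = []
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts = []
        for _ in range(int(rng.integers(1, 4))):
            exons = []
            pos = int(rng.integers(0, max_coord - 200))
            for _ in range(int(rng.integers(1, 4))):
                start = pos + int(rng.integers(0, 40))
                if start >= max_coord - 1:
                    break
                end = min(start + int(rng.integers(1, 60)), max_coord)
                exons.append(GenomicInterval("chr1", start, end, strand))
                pos = end + int(rng.integers(0, 30))
            if exons:
                transcripts.append(exons)
        if not transcripts:
            transcripts.append(
                [GenomicInterval("chr1", 0, int(rng.integers(1, 50)), strand)]
            )
        genes.append(GeneRecord(f"g{i}", "chr1", strand, transcripts=transcripts))
    return genes


@pytest.fixture
def figure5():
    return figure5_genes()
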