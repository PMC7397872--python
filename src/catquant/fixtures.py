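"""Synthetic annotations, coverage tracks and designs with known truth.

Everything downstream of alignment is emulated directly at the coverage
level: each gene draws one Poisson count per sample, centered on
``rate * depth``, laid down as constant coverage along the gene's exon
union; per-base track values are the strand-summed signal of all genes
covering the base, mirroring the unstranded property of real coverage
tracks.  Truth tables record the generating rates so that recovery can be
checked end to end.

Overlap scenarios:

* ``none`` — pairwise non-overlapping genes;
* ``same_strand`` — gene pairs overlapping on one strand;
* ``cross_strand`` — gene pairs overlapping on opposite strands;
* ``figure5`` — the canonical three-gene topology: gene A (strand +, two
  isoforms [100,200) and [150,250)), gene B (strand +, exon [180,220)),
  gene C (strand -, exon [230,300)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_models import GeneRecord, GenomicInterval, flatten_gene

SCENARIOS = ("none", "same_strand", "cross_strand", "figure5")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 8
    genome_length: int = 100_000
    chrom: str = "chr1"
    n_facets: int = 4
    samples_per_facet: int = 3
    depth: float = 50.0
    scenario: str = "none"
    #: fraction of genes generated single-facet (the rest uniform)
    single_facet_fraction: float = 0.5
    base_rate: float = 2.0
    categories: tuple[str, ...] = ("mRNA", "e-lncRNA", "dp-lncRNA", "ip-lncRNA")

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_facets < 2:
            raise ValueError("need at least 2 facets")


def figure5_genes(chrom: str = "chr1") -> list[GeneRecord]:
    """The fixed three-gene overlap fixture (two isoforms of A, B on the
    same strand inside A, C across strands past A's end)."""
    return [
        GeneRecord(
            "geneA", chrom, "+", category="mRNA",
            transcripts=[
                [GenomicInterval(chrom, 100, 200, "+")],
                [GenomicInterval(chrom, 150, 250, "+")],
            ],
        ),
        GeneRecord(
            "geneB", chrom, "+", category="e-lncRNA",
            transcripts=[[GenomicInterval(chrom, 180, 220, "+")]],
        ),
        GeneRecord(
            "geneC", chrom, "-", category="dp-lncRNA",
            transcripts=[[GenomicInterval(chrom, 230, 300, "-")]],
        ),
    ]


def _random_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    category: str,
    max_isoforms: int = 3,
    max_exons: int = 3,
) -> GeneRecord:
    n_iso = int(rng.integers(1, max_isoforms + 1))
    body = int(rng.integers(200, 800))
    transcripts = []
    for _ in range(n_iso):
        n_ex = int(rng.integers(1, max_exons + 1))
        # exon starts within the gene body, non-overlapping within a transcript
        cuts = np.sort(rng.choice(np.arange(0, body - 20, 10), size=n_ex, replace=False))
        exons = []
        for c in cuts:
            lo = start + int(c)
            hi = lo + int(rng.integers(20, 80))
            if exons and lo < exons[-1].end:
                lo = exons[-1].end + 1
                hi = max(hi, lo + 10)
            exons.append(GenomicInterval(chrom, lo, hi, strand))
        transcripts.append(exons)
    return GeneRecord(gene_id, chrom, strand, category=category, transcripts=transcripts)


def make_genes(config: SimulationConfig) -> list[GeneRecord]:
    """Generate the gene records for the configured scenario."""
    if config.scenario == "figure5":
        return figure5_genes(config.chrom)
    rng = np.random.default_rng(config.seed)
    genes: list[GeneRecord] = []
    spacing = config.genome_length // max(config.n_genes, 1)
    if spacing < 1200:
        raise ValueError("genome too small for requested number of genes")
    for i in range(config.n_genes):
        cat = config.categories[i % len(config.categories)]
        anchor = i * spacing + 100
        if config.scenario == "none":
            strand = "+" if i % 2 == 0 else "-"
            genes.append(
                _random_gene(rng, f"g{i:03d}", config.chrom, anchor, strand, cat)
            )
        elif config.scenario == "same_strand":
            g = _random_gene(rng, f"g{i:03d}", config.chrom, anchor, "+", cat)
            genes.append(g)
            if i % 2 == 1:
                # overlap the previous gene's tail on the same strand
                prev_end = max(ex.end for tx in genes[-2].transcripts for ex in tx)
                ov = GeneRecord(
                    f"g{i:03d}ov", config.chrom, "+", category=cat,
                    transcripts=[[
                        GenomicInterval(
                            config.chrom, max(100, prev_end - 50), prev_end + 80, "+"
                        )
                    ]],
                )
                genes.append(ov)
        elif config.scenario == "cross_strand":
            g = _random_gene(rng, f"g{i:03d}", config.chrom, anchor, "+", cat)
            genes.append(g)
            prev_end = max(ex.end for tx in g.transcripts for ex in tx)
            ov = GeneRecord(
                f"g{i:03d}rev", config.chrom, "-", category=cat,
                transcripts=[[
                    GenomicInterval(
                        config.chrom, max(100, prev_end - 60), prev_end + 100, "-"
                    )
                ]],
            )
            genes.append(ov)
    return genes


def write_bed12(genes: list[GeneRecord], path: str | Path) -> None:
    """One BED12 line per transcript, name = gene_id."""
    with open(path, "w") as fh:
        for g in genes:
            for tx in g.transcripts:
                exons = sorted(tx, key=lambda e: e.start)
                start = exons[0].start
                end = exons[-1].end
                sizes = ",".join(str(len(e)) for e in exons)
                offsets = ",".join(str(e.start - start) for e in exons)
                fh.write(
                    f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t"
                    f"{start}\t{end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
                )


def write_category_table(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\tsymbol\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.category}\t{g.symbol or ''}\n")


def make_annotation(config: SimulationConfig, out_dir: str | Path) -> list[GeneRecord]:
    """Write BED12 + category TSV for the configured scenario; return genes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = make_genes(config)
    write_bed12(genes, out_dir / "annotation.bed12")
    write_category_table(genes, out_dir / "categories.tsv")
    return genes


def make_design(
    n_facets: int,
    samples_per_facet: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample-to-facet table: facets f0..f{T-1}, samples f{t}_s{k}."""
    if n_facets < 2:
        raise ValueError("need at least 2 facets")
    rows = [
        {"sample_id": f"f{t}_s{k}", "facet": f"f{t}"}
        for t in range(n_facets)
        for k in range(samples_per_facet)
    ]
    return pd.DataFrame(rows)


def make_facet_profiles(
    genes: list[GeneRecord], config: SimulationConfig
) -> pd.DataFrame:
    """Per-gene generating rates per facet (the truth table).

    The first ``single_facet_fraction`` of genes express in exactly one
    facet (rotating); the rest are uniform across facets.  Rates are in
    coverage units per base before the depth multiplier.
    """
    rng = np.random.default_rng(config.seed + 1)
    facets = [f"f{t}" for t in range(config.n_facets)]
    rows = []
    n_single = int(round(config.single_facet_fraction * len(genes)))
    for i, g in enumerate(genes):
        if i < n_single:
            profile = {f: 0.0 for f in facets}
            profile[facets[i % config.n_facets]] = config.base_rate * float(
                rng.uniform(0.5, 2.0)
            )
            truth = "single_facet"
        else:
            level = config.base_rate * float(rng.uniform(0.5, 2.0))
            profile = {f: level for f in facets}
            truth = "uniform"
        rows.append({"gene_id": g.gene_id, "truth": truth, **profile})
    return pd.DataFrame(rows).set_index("gene_id")


def make_coverage(
    genes: list[GeneRecord],
    rates: pd.Series,
    depth: float,
    seed: int,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Generate one sample's unstranded bedGraph from per-gene rates.

    Each gene draws Poisson(rate * depth) once and contributes that value
    as constant coverage along its exon union; per-base coverage is the sum
    over genes (either strand) covering the base.  Returns the bedGraph as
    a DataFrame and optionally writes it.
    """
    rng = np.random.default_rng(seed)
    events: dict[str, list[tuple[int, float]]] = {}
    for g in genes:
        lam = float(rates[g.gene_id]) * depth
        draw = float(rng.poisson(lam)) if lam > 0 else 0.0
        if draw == 0:
            continue
        for iv in flatten_gene(g):
            events.setdefault(iv.chrom, []).append((iv.start, draw))
            events[iv.chrom].append((iv.end, -draw))
    rows = []
    for chrom in sorted(events):
        pts = sorted(events[chrom])
        level = 0.0
        pos = None
        for p, delta in pts:
            if pos is not None and p > pos and level > 0:
                rows.append((chrom, pos, p, level))
            level += delta
            pos = p
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    # merge adjacent equal-value runs for a canonical bedGraph
    merged = []
    for row in df.itertuples(index=False):
        if (
            merged
            and merged[-1][0] == row.chrom
            and merged[-1][2] == row.start
            and merged[-1][3] == row.value
        ):
            merged[-1][2] = row.end
        else:
            merged.append([row.chrom, row.start, row.end, row.value])
    df = pd.DataFrame(merged, columns=["chrom", "start", "end", "value"])
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False)
    return df


def simulate(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Full fixture: annotation, design, truth, one bedGraph per sample.

    Byte-identical for identical configs.  Returns paths plus the in-memory
    genes, design and truth tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = make_annotation(config, out_dir)
    design = make_design(config.n_facets, config.samples_per_facet, config.seed)
    design.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    truth = make_facet_profiles(genes, config)
    truth.to_csv(out_dir / "truth_rates.tsv", sep="\t")
    coverage_paths = {}
    for j, row in enumerate(design.itertuples(index=False)):
        path = out_dir / f"{row.sample_id}.bedgraph"
        make_coverage(
            genes,
            truth[row.facet],
            config.depth,
            seed=config.seed * 100_003 + j + 7,
            path=path,
        )
        coverage_paths[row.sample_id] = path
    return {
        "genes": genes,
        "design": design,
        "truth": truth,
        "annotation": out_dir / "annotation.bed12",
        "categories": out_dir / "categories.tsv",
        "design_path": out_dir / "design.tsv",
        "coverage": coverage_paths,
    }
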