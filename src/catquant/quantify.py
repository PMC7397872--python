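"""Coverage-based gene quantification over disambiguated segments.

The measurement unit is area under coverage: a gene's raw "count" is the sum
of per-base coverage over its retained segments, so counts are real-valued
and exactly additive over segments.  Two transformations are offered:

* AUC scaling — rescale each sample to a common total coverage area
  (default target 4e9, i.e. 40 million reads of 100 bp), the convention
  used by coverage-track repositories;
* TPM — length-normalize by the retained gene length L_g and rescale each
  sample to sum to 1e6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gene_models import GenomicInterval, SegmentMap

logger = logging.getLogger("catquant")

#: recount2-style library size target: 40e6 reads x 100 bp
DEFAULT_TARGET_AUC = 4.0e9

UNITS = ("raw_coverage", "scaled_coverage", "tpm")


@dataclass
class CoverageTrack:
    """Run-length encoded, unstranded per-base coverage.

    ``runs[chrom] = (starts, ends, values)`` with non-overlapping sorted
    runs; bases outside every run have coverage 0.
    """

    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    _warned: set = field(default_factory=set, repr=False)

    @property
    def auc(self) -> float:
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.runs.values())
        )

    def value_at(self, chrom: str, base: int) -> float:
        """Coverage at a single base (0-based); brute-force lookup."""
        if chrom not in self.runs:
            return 0.0
        starts, ends, values = self.runs[chrom]
        i = np.searchsorted(starts, base, side="right") - 1
        if i >= 0 and base < ends[i]:
            return float(values[i])
        return 0.0


def _normalize_runs(
    df: pd.DataFrame,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    runs = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        values = sub["value"].to_numpy(dtype=np.float64)
        if (values < 0).any():
            raise ValueError(f"negative coverage value on {chrom}")
        if (starts >= ends).any():
            raise ValueError(f"degenerate coverage interval on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping coverage intervals on {chrom}")
        # drop zero runs, merge adjacent equal-value runs
        keep = values > 0
        starts, ends, values = starts[keep], ends[keep], values[keep]
        ms, me, mv = [], [], []
        for s, e, v in zip(starts, ends, values):
            if mv and ms is not None and me[-1] == s and mv[-1] == v:
                me[-1] = e
            else:
                ms.append(s)
                me.append(e)
                mv.append(v)
        if ms:
            runs[str(chrom)] = (
                np.array(ms, dtype=np.int64),
                np.array(me, dtype=np.int64),
                np.array(mv, dtype=np.float64),
            )
    return runs


def read_coverage(path: str | Path, format: str = "bedgraph") -> CoverageTrack:
    """Read a coverage track from bedGraph (0-based half-open) or bigWig.

    bigWig needs the optional pyBigWig dependency; bedGraph is the
    dependency-free dialect.
    """
    path = Path(path)
    if format == "bedgraph":
        try:
            df = pd.read_csv(
                path,
                sep=r"\s+",
                comment="#",
                header=None,
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str},
            )
        except pd.errors.EmptyDataError:
            return CoverageTrack()
        df = df[~df["chrom"].isin(["track", "browser"])]
        if df.empty:
            return CoverageTrack()
        return CoverageTrack(_normalize_runs(df))
    if format == "bigwig":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(str(path))
        frames = []
        for chrom in bw.chroms():
            ivs = bw.intervals(chrom)
            if ivs:
                frames.append(
                    pd.DataFrame(ivs, columns=["start", "end", "value"]).assign(
                        chrom=chrom
                    )
                )
        bw.close()
        if not frames:
            return CoverageTrack()
        return CoverageTrack(_normalize_runs(pd.concat(frames)))
    raise ValueError(f"unknown coverage format {format!r}")


def segment_count(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Sum of per-base coverage over ``[start, end)``; strand ignored."""
    if interval.chrom not in track.runs:
        if interval.chrom not in track._warned:
            logger.warning("chromosome %s absent from coverage track", interval.chrom)
            track._warned.add(interval.chrom)
        return 0.0
    starts, ends, values = track.runs[interval.chrom]
    lo = np.searchsorted(ends, interval.start, side="right")
    hi = np.searchsorted(starts, interval.end, side="left")
    if lo >= hi:
        return 0.0
    s = np.maximum(starts[lo:hi], interval.start)
    e = np.minimum(ends[lo:hi], interval.end)
    return float(((e - s) * values[lo:hi]).sum())


def gene_counts(track: CoverageTrack, segmap: SegmentMap) -> dict[str, float]:
    """Per-gene coverage sums: count(g) = sum over g's segments.

    Dropped genes are absent, never zero.
    """
    counts = {gid: 0.0 for gid in segmap.gene_length}
    for iv, gid in segmap.segments:
        counts[gid] += segment_count(track, iv)
    return counts


def scale_counts(
    counts: Mapping[str, float],
    sample_auc: float,
    target_auc: float = DEFAULT_TARGET_AUC,
) -> dict[str, float]:
    """Rescale counts to a common library area: count * target_auc / sample_auc."""
    if sample_auc <= 0:
        if any(v != 0 for v in counts.values()):
            raise ValueError("sample AUC is zero but counts are nonzero")
        return dict(counts)
    f = target_auc / sample_auc
    return {g: c * f for g, c in counts.items()}


def tpm(
    counts: Mapping[str, float], gene_length: Mapping[str, int]
) -> dict[str, float]:
    """Transcripts per million from coverage counts and retained lengths.

    rate(g) = count(g) / L_g; TPM(g) = 1e6 * rate(g) / sum of rates.
    The denominator runs over the genes present in the segment map only.
    An all-zero sample yields all-zero TPM.
    """
    for g in counts:
        if gene_length[g] <= 0:
            raise ValueError(f"gene {g}: non-positive length")
    rates = {g: c / gene_length[g] for g, c in counts.items()}
    total = sum(rates.values())
    if total == 0:
        return {g: 0.0 for g in counts}
    return {g: 1.0e6 * r / total for g, r in rates.items()}


@dataclass
class CountMatrix:
    """Genes x samples expression matrix with lengths and scaling metadata."""

    values: pd.DataFrame  # rows = gene_id, columns = sample_id
    gene_length: pd.Series
    categories: pd.Series
    unit: str
    scaling: pd.DataFrame | None = None  # per-sample sample_auc / target_auc / applied

    def validate(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        if self.unit == "tpm":
            sums = self.values.sum(axis=0)
            nonzero = sums[sums > 0]
            if not np.allclose(nonzero, 1.0e6, rtol=1e-9, atol=0):
                raise ValueError("TPM columns do not sum to 1e6")

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @staticmethod
    def from_tsv(
        path: str | Path,
        gene_length: pd.Series | None = None,
        categories: pd.Series | None = None,
        unit: str = "tpm",
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        n = len(df.index)
        if gene_length is None:
            gene_length = pd.Series(np.ones(n), index=df.index)
        if categories is None:
            categories = pd.Series(["other"] * n, index=df.index)
        return CountMatrix(df, gene_length, categories, unit)


def build_matrix(
    tracks: Mapping[str, CoverageTrack],
    segmap: SegmentMap,
    unit: str = "tpm",
    target_auc: float = DEFAULT_TARGET_AUC,
) -> CountMatrix:
    """Assemble the genes x samples matrix in the requested unit.

    Rows are exactly the surviving genes of the segment map, in sorted
    order; columns follow the mapping's sample order.
    """
    if unit not in UNITS:
        raise ValueError(f"unknown unit {unit!r}")
    sample_ids = list(tracks)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id")
    if not sample_ids:
        raise ValueError("need at least one sample")
    gene_ids = segmap.gene_ids
    cols = {}
    scaling_rows = []
    for sid in sample_ids:
        track = tracks[sid]
        counts = gene_counts(track, segmap)
        sample_auc = track.auc
        scaling_rows.append(
            {
                "sample_id": sid,
                "sample_auc": sample_auc,
                "target_auc": target_auc,
                "applied": unit == "scaled_coverage",
            }
        )
        if unit == "scaled_coverage":
            counts = scale_counts(counts, sample_auc, target_auc)
        elif unit == "tpm":
            counts = tpm(counts, segmap.gene_length)
        cols[sid] = [counts[g] for g in gene_ids]
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    meta = segmap.gene_meta
    categories = pd.Series(
        [meta.get(g, (None, "other", "."))[1] for g in gene_ids], index=values.index
    )
    lengths = pd.Series([segmap.gene_length[g] for g in gene_ids], index=values.index)
    cm = CountMatrix(
        values,
        lengths,
        categories,
        unit,
        pd.DataFrame(scaling_rows).set_index("sample_id"),
    )
    cm.validate()
    return cm


def qc_table(tracks: Mapping[str, CoverageTrack], segmap: SegmentMap) -> pd.DataFrame:
    """Per-sample QC: total AUC, coverage in retained bases, retained fraction."""
    rows = []
    for sid, track in tracks.items():
        retained = sum(segment_count(track, iv) for iv, _ in segmap.segments)
        auc = track.auc
        rows.append(
            {
                "sample_id": sid,
                "auc": auc,
                "retained_coverage": retained,
                "retained_fraction": retained / auc if auc > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
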