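"""Facet-level analytics: tissue specificity, detection rates, validation.

A *facet* is a sample grouping, e.g. a tissue type.  Given a TPM matrix and
a sample-to-facet design this module computes:

* per-gene expression level (max TPM over all samples) and entropy-based
  specificity over the per-facet summary profile;
* percent of genes detected (TPM strictly above a threshold, default 0.01)
  per facet and RNA category, with very wide Student-t confidence intervals
  (default level 99.99%) so that only gross facet differences stand out;
* per-gene Pearson correlation between two quantifications of the same
  samples, summarized by the median over genes;
* a global Benjamini-Hochberg adjustment over p-values pooled across strata
  (e.g. cancer types) and the consensus gene set significant in every
  stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix


@dataclass
class FacetDesign:
    """Sample-to-facet assignment with a stable facet order."""

    facet_of: dict[str, str]
    facet_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = list(dict.fromkeys(self.facet_of.values()))
        if not self.facet_order:
            self.facet_order = seen
        missing = set(seen) - set(self.facet_order)
        if missing:
            raise ValueError(f"facets missing from facet_order: {sorted(missing)}")

    def samples_in(self, facet: str) -> list[str]:
        return [s for s, f in self.facet_of.items() if f == facet]

    @staticmethod
    def from_tsv(path: str | Path) -> "FacetDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "facet"} <= set(df.columns):
            raise ValueError("design table needs sample_id and facet columns")
        return FacetDesign(dict(zip(df["sample_id"], df["facet"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.facet_of), "facet": list(self.facet_of.values())}
        ).to_csv(path, sep="\t", index=False)


def _check_design(matrix: pd.DataFrame, design: FacetDesign) -> None:
    missing = [c for c in matrix.columns if c not in design.facet_of]
    if missing:
        raise ValueError(f"samples without a facet: {missing}")


def summarize_by_facet(
    matrix: CountMatrix | pd.DataFrame, design: FacetDesign, stat: str = "median"
) -> pd.DataFrame:
    """Per-gene, per-facet summary (median by default, mean by flag)."""
    df = matrix.values if isinstance(matrix, CountMatrix) else matrix
    _check_design(df, design)
    out = {}
    for facet in design.facet_order:
        cols = [s for s in design.samples_in(facet) if s in df.columns]
        if not cols:
            raise ValueError(f"facet {facet!r} has zero samples in the matrix")
        sub = df[cols]
        out[facet] = sub.median(axis=1) if stat == "median" else sub.mean(axis=1)
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown stat {stat!r}")
    return pd.DataFrame(out)


def gene_max_expression(
    matrix: CountMatrix | pd.DataFrame, design: FacetDesign | None = None
) -> pd.Series:
    """Expression level per gene: the maximum TPM over all samples."""
    df = matrix.values if isinstance(matrix, CountMatrix) else matrix
    if design is not None:
        _check_design(df, design)
    return df.max(axis=1)


def entropy_specificity(summary: Sequence[float]) -> tuple[float, float]:
    """Shannon entropy (bits) and specificity of one gene's facet profile.

    The profile is normalized to a distribution P over the T facets;
    H = -sum P log2 P (with 0 log 0 = 0) and S = 1 - H / log2 T, so S = 0
    for a uniform (ubiquitous) gene and S = 1 for a single-facet gene.
    An all-zero profile has no distribution: (NaN, NaN).
    """
    e = np.asarray(summary, dtype=float)
    if e.size < 2:
        raise ValueError("specificity needs at least 2 facets")
    if (e < 0).any():
        raise ValueError("negative expression in facet summary")
    total = e.sum()
    if total == 0:
        return (float("nan"), float("nan"))
    p = e / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return (h, 1.0 - h / np.log2(e.size))


def specificity_table(
    matrix: CountMatrix | pd.DataFrame,
    design: FacetDesign,
    stat: str = "median",
    categories: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene table: category, max TPM (raw and log2(x+1)), entropy, specificity."""
    df = matrix.values if isinstance(matrix, CountMatrix) else matrix
    if categories is None and isinstance(matrix, CountMatrix):
        categories = matrix.categories
    summary = summarize_by_facet(df, design, stat=stat)
    hs = np.array([entropy_specificity(row) for row in summary.to_numpy()])
    max_tpm = gene_max_expression(df, design)
    out = pd.DataFrame(
        {
            "category": categories.reindex(df.index)
            if categories is not None
            else "other",
            "max_tpm": max_tpm,
            "log2_max_tpm": np.log2(max_tpm + 1.0),
            "entropy": hs[:, 0],
            "specificity": hs[:, 1],
        },
        index=df.index,
    )
    out.index.name = "gene_id"
    return out


def percent_expressed(
    matrix: CountMatrix | pd.DataFrame,
    design: FacetDesign,
    categories: pd.Series | None = None,
    tau: float = 0.01,
    ci_level: float = 0.9999,
) -> pd.DataFrame:
    """Percent of each category's genes detected, per facet, with t CIs.

    A gene counts as expressed in a sample iff its TPM is strictly greater
    than ``tau``.  Per facet the mean over its samples is reported with a
    two-sided Student-t interval at ``ci_level``, clamped to [0, 100]; with
    a single sample the interval degenerates to the mean.
    """
    df = matrix.values if isinstance(matrix, CountMatrix) else matrix
    if categories is None and isinstance(matrix, CountMatrix):
        categories = matrix.categories
    if categories is None:
        categories = pd.Series(["other"] * len(df.index), index=df.index)
    # genes absent from the matrix (e.g. fully ambiguous, hence unmeasurable)
    # do not enter any category's denominator
    categories = categories[categories.index.isin(df.index)]
    _check_design(df, design)
    detected = df > tau
    rows = []
    for cat, genes in categories.groupby(categories):
        idx = genes.index
        if len(idx) == 0:
            raise ValueError(f"category {cat!r} has no genes")
        pct_per_sample = 100.0 * detected.loc[idx].mean(axis=0)  # per sample
        for facet in design.facet_order:
            cols = [s for s in design.samples_in(facet) if s in df.columns]
            vals = pct_per_sample[cols].to_numpy(dtype=float)
            n = len(vals)
            mean = float(vals.mean())
            if n > 1:
                sd = float(vals.std(ddof=1))
                tcrit = float(stats.t.ppf((1.0 + ci_level) / 2.0, df=n - 1))
                half = tcrit * sd / np.sqrt(n)
                lower, upper = max(0.0, mean - half), min(100.0, mean + half)
            else:
                lower = upper = mean
            rows.append(
                {
                    "facet": facet,
                    "category": cat,
                    "mean_pct_expressed": mean,
                    "ci_lower": lower,
                    "ci_upper": upper,
                    "n_samples": n,
                    "tau": tau,
                    "ci_level": ci_level,
                }
            )
    return pd.DataFrame(rows)


def per_gene_correlation(
    matrix_a: CountMatrix | pd.DataFrame, matrix_b: CountMatrix | pd.DataFrame
) -> tuple[pd.Series, float]:
    """Pearson correlation per shared gene over shared samples, plus median.

    Genes constant in either matrix have undefined correlation: reported as
    NaN and excluded from the median.
    """
    a = matrix_a.values if isinstance(matrix_a, CountMatrix) else matrix_a
    b = matrix_b.values if isinstance(matrix_b, CountMatrix) else matrix_b
    genes = a.index.intersection(b.index)
    samples = a.columns.intersection(b.columns)
    if len(genes) == 0 or len(samples) == 0:
        raise ValueError("matrices share no genes or no samples")
    x = a.loc[genes, samples].to_numpy(dtype=float)
    y = b.loc[genes, samples].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r = np.where((sx == 0) | (sy == 0), np.nan, r)
    series = pd.Series(r, index=genes, name="pearson_r")
    return series, float(np.nanmedian(r)) if np.isfinite(r).any() else float("nan")


def global_bh(
    pvalues: pd.DataFrame, by: str | None = None
) -> pd.DataFrame:
    """Benjamini-Hochberg over p-values pooled across strata.

    ``pvalues`` has columns gene_id, stratum, p.  With ``by`` (e.g. an RNA
    category column) the adjustment runs within each group as a separate
    family; otherwise the whole table is one pooled family.
    """
    df = pvalues.copy()
    p = df["p"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if by is None:
        df["q"] = multipletests(p, method="fdr_bh")[1]
    else:
        df["q"] = np.nan
        for _, idx in df.groupby(by).groups.items():
            df.loc[idx, "q"] = multipletests(
                df.loc[idx, "p"].to_numpy(dtype=float), method="fdr_bh"
            )[1]
    return df


def consensus_genes(
    qvalues: pd.DataFrame,
    strata: Sequence[str] | None = None,
    cutoff: float = 1e-6,
    direction: str | None = None,
) -> set[str]:
    """Genes significant (q <= cutoff) in *every* stratum.

    A gene must have been tested in all strata — untested is not the same
    as non-significant.  If ``direction`` names a column, the gene must
    additionally have a consistent sign across strata (off by default).
    """
    df = qvalues
    if strata is None:
        strata = sorted(df["stratum"].unique())
    strata = set(strata)
    out = set()
    for gid, sub in df.groupby("gene_id"):
        if set(sub["stratum"]) != strata:
            continue
        if (sub["q"] > cutoff).any():
            continue
        if direction is not None:
            signs = np.sign(sub[direction].to_numpy(dtype=float))
            if not (np.all(signs > 0) or np.all(signs < 0)):
                continue
        out.add(gid)
    return out
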