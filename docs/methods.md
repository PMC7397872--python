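# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention). GTF
exons (1-based closed) are converted on read: `[start, end]` →
`[start−1, end)`. Chromosome-name dialects are reconciled by a single
`chrom-style` flag (`ucsc` / `ensembl` / `as-is`) applied identically to
annotation, coverage and SNP inputs, so the three can never silently
disagree. A 1-based SNP position `p` overlaps a 0-based half-open region
`[s, e)` iff `s < p ≤ e`; SNP overlap uses the gene span (min exon start
to max exon end) as the gene region, since exon-only overlap would be a
stricter, different question.

## Disjoin and cross-strand disambiguation

The model of the measurement is: an unstranded coverage track reports, at
each base, the summed signal of every transcript overlapping that base on
either strand. A base is therefore attributable to a gene g only when g
is the *only* gene (strand ignored) whose exons cover it. The pipeline
computes exactly that set, but segment-wise rather than base-wise:

1. *Flatten*: per gene, the union of all isoforms' exons. Within-gene
   isoform overlap is resolved here and never causes a drop.
2. *Same-strand disjoin*: on each strand, all flattened unions are split
   at every union boundary. Each resulting atom is covered all-or-nothing
   by each gene (boundaries include every start/end), so the owner set
   per atom is exact.
3. *Cross-strand disjoin*: atoms from both strands are split again at
   each other's boundaries and owner sets are pooled across strands.
4. *Filter*: atoms with more than one owner are discarded; adjacent
   atoms with identical owner sets are merged back (bookended merge), so
   segment granularity never changes per-gene totals.

Genes that lose every base are reported in a drop log as "fully
ambiguous" and excluded from all downstream matrices — never emitted as
zero rows, because *unmeasurable* must not be conflated with
*unexpressed*. Unstranded annotation records (strand "." ) are rejected
with a warning: the procedure is defined on two strands and guessing a
strand would corrupt the cross-strand step.

Output ordering is deterministic: segments sorted by
(chrom, start, end, gene_id), so reruns are byte-identical.

The tests verify the whole pipeline against an independent brute-force
oracle that labels every base with its covering gene set and keeps the
bases owned by exactly one gene; they also check the partition identity
(retained bases + dropped bases = all exon-covered bases), pairwise
disjointness, idempotence, and input-order invariance.

## Quantification

A gene's raw count is the per-base coverage summed over its retained
segments — a real number, never rounded, and exactly additive over
segments (conservation: Σ_g count_g equals the coverage summed over all
retained bases). Two transformations:

* **AUC scaling**: `count × target_AUC / sample_AUC` with default
  `target_AUC = 4e9` (40 million reads × 100 bp), the convention used by
  coverage-track repositories. Exposed as `--target-auc`.
* **TPM**: `rate_g = count_g / L_g`, `TPM_g = 1e6 · rate_g / Σ rate`.
  The effective length `L_g` is the *retained disambiguated* length, not
  the full exon-union length, because counts are collected only over
  retained segments; this is a deliberate, documented divergence from
  transcript-length TPM and a source of (small) systematic differences
  when comparing against other quantifications. The denominator runs over
  the genes present in the segment map only. An all-zero sample yields
  all-zero TPM rather than NaN.

TPM is invariant to scaling the coverage by a constant; nonzero TPM
columns sum to 1e6 within 1e-9 relative tolerance (validated on every
matrix build).

bedGraph is the dependency-free input dialect; bigWig sits behind an
optional flag (pyBigWig). Coverage runs are run-length encoded, validated
(non-negative, non-overlapping) and canonicalized (adjacent equal-value
runs merged, zero runs implicit).

## Facet analytics

* **Facet summary**: per gene, the median TPM over each facet's samples
  by default, mean by flag. Median was chosen as the default because it
  is robust to single outlier samples within a tissue; both are exposed
  since either convention appears in atlas-scale analyses.
* **Expression level**: max TPM over all samples; log2(x+1) is provided
  alongside for display, raw values are kept in all tables.
* **Entropy specificity**: the facet profile is normalized to a
  distribution, `H = −Σ P log2 P` (bits, 0·log 0 = 0),
  `S = 1 − H/log2 T`. Base-2 with the `log2 T` normalizer puts S exactly
  in [0,1]: 0 = uniform, 1 = single-facet. No pseudocount is added; an
  all-zero profile has no distribution and is reported NA rather than
  forced to either extreme. S is invariant to positive rescaling and to
  facet permutation (property-tested).
* **Percent expressed**: a gene counts as detected in a sample iff
  TPM strictly exceeds τ = 0.01. Per facet and RNA category the mean of
  per-sample percentages is reported with a two-sided Student-t interval
  at level 0.9999, clamped to [0,100]; with one sample the interval
  degenerates to the mean. The t construction was chosen because the
  per-sample percentages are approximately normal averages over many
  genes; the extreme level makes only gross facet differences stand out.
* **Cross-quantification validation**: per shared gene, Pearson
  correlation across shared samples; genes constant in either matrix are
  NA and excluded from the median summary.
* **Global BH / consensus**: p-values pooled across strata (one family,
  or one family per category via `--by`) are adjusted with
  Benjamini–Hochberg (statsmodels implementation, cross-checked in tests
  against the brute-force step-up definition). The consensus set contains
  genes with q ≤ cutoff in *every* stratum and *tested* in every stratum
  — untested is not non-significant. Requiring a consistent direction of
  change is available via `--direction` but off by default, since
  significance-in-all-strata is the weaker, safer default.

## Synthetic data generator

The generator emulates the measurement process directly at the coverage
level. Each gene draws one Poisson count per sample, centered on
`rate × depth`, laid down as *constant* coverage along its exon union;
the per-base track value is the strand-summed signal of all genes
covering the base. This is the simplest model consistent with coverage
additivity and it exercises exactly the ambiguity the disjoin step
exists to remove (the `cross_strand` and `figure5` scenarios place genes
on opposite strands over the same bases). Facet structure: a configurable
fraction of genes (default half) express in exactly one facet, the rest
uniformly, with per-gene levels drawn uniformly in [0.5, 2]× a base rate
of 2 coverage units per base. Defaults — 4 facets × 3 samples, depth 50×,
8 genes per run — are desk-scale study conditions; the acceptance script
uses 4 facets × 5 samples × 20 replicate seeds.

What the generator does **not** emulate: read-level sampling noise along
the gene body (coverage is flat per gene), 3'/5' coverage bias,
junction-spanning reads, overdispersion beyond Poisson, and library
composition effects. Passing recovery tests therefore demonstrates the
correctness of the segment accounting and the estimators under the
stated noise model, not robustness to every artifact of real RNA-seq.

Identical configurations produce byte-identical files; all randomness is
seeded explicitly (the CLI has no wall-clock seed default).

## Numerical choices and degenerate inputs

* Counts and TPM are float64 throughout; no rounding anywhere.
* TPM column-sum tolerance: 1e-9 relative.
* Entropy: terms with P = 0 contribute exactly 0; specificity with fewer
  than 2 facets is an error (undefined normalizer).
* Zero-AUC samples: scaling is an error if counts are nonzero, identity
  otherwise; all-zero TPM columns are reported as zeros.
* Coverage on chromosomes absent from a track counts 0 and is logged
  once per chromosome.
* Bookended retained segments of the same gene are merged; segments of
  different genes never are.

## Problem sizes

The test suite and acceptance script run on synthetic annotations of
≤10 genes over ≤2 kb (disjoin oracle), 8–10-gene genomes of ~100 kb with
20 samples (recovery), 200 oracle replicates and 100 BH vectors — sizes
chosen so the full verification completes in seconds while still
exercising every code path, including both overlap directions. The
algorithms themselves are sweep/searchsorted-based and scale to
full-genome annotations (hundreds of thousands of segments) without
modification.

## Known limitations

* Gene-level only; no isoform quantification is attempted (coverage
  tracks cannot resolve isoforms sharing bases).
* Retained-length TPM differs systematically from transcript-length TPM
  for genes losing a large ambiguous fraction.
* The consensus operation consumes externally produced p-values; no
  differential-expression model is fitted here.
* bigWig reading requires pyBigWig; without it, convert to bedGraph.
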