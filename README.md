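# catquant

Annotation-agnostic requantification of RNA-seq data from unstranded
per-base coverage tracks, for any multi-gene, multi-isoform, two-strand
gene annotation — including very broad catalogs rich in long noncoding
RNAs (enhancer, divergent-promoter and intergenic-promoter lncRNAs) that
standard annotation-locked pipelines never measure.

## The problem and the method

Uniformly processed RNA-seq repositories distribute per-sample coverage
tracks (bigWig/bedGraph): the per-base count of aligned reads. These
tracks allow requantifying tens of thousands of samples under a *new*
gene annotation without re-aligning any reads — but they are unstranded,
so a base that is exonic for more than one gene (on either strand) cannot
be attributed. `catquant` makes gene-level quantification from such
tracks well defined with a two-step disjoin:

1. **Within each strand**, every gene's isoforms are flattened to their
   exon union (isoform overlap inside one gene is never ambiguous), and
   overlapping unions are split into maximal *disjoint exonic segments*,
   each labeled with the exact set of covering genes.
2. **Across strands**, segments are split again at every boundary of the
   opposite strand's segments, and owners are pooled across strands —
   mirroring exactly what an unstranded track can and cannot distinguish.

Segments owned by more than one gene are discarded; what remains maps
back to exactly one gene each. A gene's raw count in a sample is then the
coverage summed over its retained segments, and

```
rate_g = count_g / L_g          L_g = retained (disambiguated) length
TPM_g  = 1e6 * rate_g / Σ_h rate_h
```

Counts may alternatively be scaled to a common library area
(`count * target_AUC / sample_AUC`, default target 4×10⁹ = 40 M reads ×
100 bp).

Downstream, per-gene tissue profiles over sample *facets* (tissue types)
are summarized by the entropy-based specificity

```
P_t = e_t / Σ e,   H = −Σ_t P_t log2 P_t,   S = 1 − H / log2 T
```

so S = 0 for a ubiquitous gene and S = 1 for a single-facet gene;
detection rates (TPM > 0.01) per facet and RNA category come with
Student-t 99.99% confidence intervals; two quantifications of the same
samples are compared by per-gene Pearson correlation (median summary);
and p-values pooled across strata (e.g. cancer types) get a global
Benjamini–Hochberg adjustment plus an all-strata consensus gene set.

## Worked example

Simulate the canonical three-gene overlap fixture — gene A (strand +, two
isoforms [100,200) and [150,250)), gene B (strand +, exon [180,220)
inside A), gene C (strand −, exon [230,300) crossing A's tail) — then
disjoin and quantify:

```sh
catquant simulate --scenario figure5 --seed 3 --facets 2 \
    --samples-per-facet 2 --out-dir demo
catquant disjoin --annotation demo/annotation.bed12 \
    --categories demo/categories.tsv --out-prefix demo/seg
# retained 3 segments over 2 genes; dropped 60 ambiguous bases and 1 fully ambiguous genes
catquant quantify --segments demo/seg \
    --coverage demo/f0_s0.bedgraph,demo/f0_s1.bedgraph,demo/f1_s0.bedgraph,demo/f1_s1.bedgraph \
    --sample-ids f0_s0,f0_s1,f1_s0,f1_s1 --unit tpm --out demo/tpm.tsv
# wrote 2 x 4 matrix (tpm)
catquant specificity --matrix demo/tpm.tsv --design demo/design.tsv \
    --categories demo/categories.tsv --out demo/spec.tsv
# wrote specificity for 2 genes across 2 facets
```

The disjoin output is the heart of the method: gene A keeps
[100,180) and [220,230) (90 bases), gene C keeps [250,300) (50 bases),
while [180,220) (A∩B, same strand) and [230,250) (A∩C, across strands)
— 60 bases — are dropped, and gene B, entirely contained in A, is
reported *fully ambiguous* rather than emitted as a zero row: it is
unmeasurable, not unexpressed. Each TPM column of `demo/tpm.tsv` sums to
exactly 10⁶, and `demo/spec.tsv` carries each gene's max TPM, entropy
H (bits) and specificity S ∈ [0,1].

The same operations are available as a library
(`from catquant import disambiguate, build_matrix, specificity_table, ...`).

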