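# crossde

Tools for asking a question that a direct two-subtype comparison cannot
answer: when a gene differs between two disease subtypes — say ER+ and
ER− breast cancer — is that because it is dysregulated *more strongly*
in one subtype relative to normal tissue, or because it is dysregulated
in *opposite directions* in the two subtypes?

`crossde` implements the full comparison pipeline for two subtypes
measured against a shared normal control group on two platforms (a
probe-level microarray and an RNA-seq run):

1. **Preprocessing.** Microarray probes are filtered at a 20% missing
   rate, imputed by K-nearest-neighbour row imputation (k = 15,
   Euclidean distance over co-observed columns), and collapsed
   probe→gene (multi-mapped and unmapped probes deleted, same-gene
   probes averaged). RNA-seq counts are log2(x+1)-transformed.
2. **Differential expression.** A SAM-style two-class statistic
   d = (x̄₁ − x̄₂)/(s + s₀), with the Tusher pooled standard error s and
   a fudge factor s₀ chosen by coefficient-of-variation minimisation.
   FDR is estimated by label permutation: FDR(Δ) = median over
   permutations of #{|d*| ≥ Δ} / #{|d| ≥ Δ}; a gene's q-value is the
   smallest such FDR at which it is called. Direction is the sign of the
   case-minus-control mean difference.
3. **Classification.** Genes DE in both subtypes split into **class 1**
   (same direction) and **class 2** (opposite directions). Class 1 genes
   are subclassified by *extent*: a shared-up gene whose subtype-A mean
   exceeds its subtype-B mean (or a shared-down gene further below
   normal in A) is dysregulated to a larger extent in A.
4. **Cross-platform validation.** Class memberships are confirmed in the
   second platform; agreement is quantified by hypergeometric overlap
   tests and fair-coin binomial tests on direction/extent concordance.
5. **Enrichment.** GO biological-process enrichment (hypergeometric +
   Benjamini–Yekutieli, with ancestor/offspring redundancy resolution),
   gene-set enrichment against curated catalogues, and
   direct-interaction-neighbour enrichment on a PPI graph.

A synthetic-cohort generator with planted class structure (effect sizes
shared across platforms, platform-specific noise, probe artefacts,
missing values, RNA-seq zero inflation) makes every stage testable
end-to-end without external data.

## Worked example

```python
from crossde import (GeneratorConfig, SAMConfig, generate_cohort,
                     transform_rnaseq, analyze_cohort, summarize_counts)
from crossde.pipeline import preprocess_microarray

cohort = generate_cohort(GeneratorConfig(seed=7, n_genes=800))
ma = preprocess_microarray(cohort.probe_matrix, cohort.annotation,
                           cohort.groups_microarray)
rs = transform_rnaseq(cohort.rnaseq_counts, groups=cohort.groups_rnaseq)
report = analyze_cohort(ma, rs, SAMConfig(seed=11, n_permutations=500,
                                          target_fdr=0.01))
print(summarize_counts(report).to_string(index=False))
```

Selected lines of the printed summary:

```
          microarray.N1_subtypeA_DE  152
          microarray.N2_subtypeB_DE  137
               microarray.N_overlap  119
                microarray.n_class1   75
                microarray.n_class2   44
      microarray.pct_same_direction   63
                   confirmed.class2   44
      class2_orientation.concordant   44
class2_orientation.log10_p_binomial  -13.2453
```

Reading: 152 genes were called DE in subtype A vs normal and 137 in
subtype B vs normal on the microarray; 119 genes were shared, of which
75 (63%) changed in the same direction (class 1) and 44 in opposite
directions (class 2). All 44 class 2 genes were confirmed with the same
orientation in the RNA-seq data — agreement that a fair-coin null puts
at p ≈ 10⁻¹³, i.e. the opposite-direction calls replicate far beyond
chance. (This cohort plants 5% of genes per class kind, so the counts
track the planted truth.)

The same analysis runs from the shell:

```sh
crossde simulate --seed 7 --out sim/
crossde run-all --config config.yaml --out results/
```

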