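# Methods

## The question and the model

Comparing two disease subtypes directly (subtype A vs subtype B) cannot
distinguish three situations that produce the same between-subtype
difference: a gene dysregulated in the same direction in both subtypes
but more strongly in one; a gene dysregulated in opposite directions;
and a gene dysregulated in only one subtype. `crossde` therefore anchors
both subtypes to the *same* normal control group. Genes called DE in
both subtype-vs-normal contrasts are partitioned by the agreement of
their directions:

* **class 1** (same direction), subclassified by *extent*;
* **class 2** (opposite directions), recorded with orientation.

Single-subtype DE genes are reported but not analysed further: with
finite power, "DE in A only" cannot be distinguished from "DE in both
but missed in B", so the class is not well defined.

The extent rule is deliberately a sign rule, not a second significance
call: a class 1 gene is "dysregulated to a larger extent in A" when the
between-subtype mean difference Δ_AB = x̄_A − x̄_B points the same way as
the shared direction (above for shared-up genes, below for shared-down
genes). This guarantees the extent subclasses partition class 1, which
keeps the downstream bookkeeping (counts, concordance denominators)
exact. A `significant_ab` argument optionally restricts labels to genes
whose A-vs-B contrast is itself significant; the default is off.

Because any one dataset captures only part of the true DE genes, class
memberships are *confirmed* against an independent platform: identical
shared direction for class 1, identical orientation for class 2.
Agreement beyond chance is quantified two ways: a hypergeometric tail on
the list overlap (universe = genes measured on both platforms after
preprocessing, configurable) and a fair-coin binomial tail on per-gene
direction/extent agreement. A gene's direction under the null has no
reason to replicate, so p = 1/2 per gene is the natural reference.

## Differential expression

The two-class unpaired SAM statistic is

    d = (x̄₁ − x̄₂) / (s + s₀),
    s = sqrt( ((1/n₁ + 1/n₂) / (n₁ + n₂ − 2)) · (SS₁ + SS₂) )

with s₀ a fudge factor that keeps low-variance genes from dominating the
ranking. Two estimators are provided: `tusher_cv_minimization` (default)
scans candidates at the 0, 5, …, 100 percentiles of s and picks the one
minimising the coefficient of variation of the per-window median |d|
over 10 s-quantile windows; `fixed_percentile` simply takes a quantile
of s (fast; used widely in the test suite where the fudge factor is not
the property under test).

FDR is estimated by permuting group labels. For a grid of symmetric
thresholds at the observed |d| values,

    FDR(Δ) = median over permutations of #{|d*| ≥ Δ} / #{|d| ≥ Δ},

and a gene's q-value is the smallest FDR over the thresholds it passes
(a suffix minimum over the descending grid, so q is monotone in |d|).
When C(n, n₁) is smaller than the requested permutation count, all
distinct label assignments are enumerated, making small designs exact —
the test suite exploits this with a 4-vs-4 design whose 70 assignments
are checked against a from-scratch oracle.

Numerical choices worth stating:

* The permutation pass computes group sums by matrix multiplication on
  row-centred data; centring keeps the `sum of squares = Σx² − n·x̄²`
  identity well conditioned.
* Threshold exceedances are counted with a 10⁻⁹ relative tolerance so a
  permuted statistic equal to an observed threshold up to rounding still
  counts as "≥" (ties are included by definition).
* A called gene with an exactly zero mean difference has no defined
  direction and is excluded from the DE gene set with a warning.
* The median-based FDR can assign FDR 0 to the top-ranked gene even on
  null data (about half of permutations show no exceedance of the
  observed maximum). This is inherent to the estimator, not a bug; the
  calibrated guarantee is on the false-call *rate*, which the acceptance
  suite bounds at twice nominal on null cohorts.

## Preprocessing

Microarray probes with a missing rate strictly above 20% are deleted
(exactly 20% is retained). Remaining gaps are filled by row-wise KNN
imputation, k = 15: neighbours ranked by Euclidean distance over
co-observed columns, candidates must observe the target column, the fill
is the unweighted mean of the k nearest, ties break by row order (stable
sort) for determinism. Row neighbours — genes, not samples — follow the
classical expression-imputation algorithm. A probe sharing no observed
column with any other row falls back to its own row mean. Probes mapping
to zero or multiple gene IDs are deleted; probes sharing a gene are
averaged per sample. RNA-seq counts are log2(x+1)-transformed, keeping
zeros at 0 while linearising the roughly log-normal body.

## Enrichment

GO biological-process terms are tested with the hypergeometric tail on
annotations propagated up the is_a DAG, restricted to the analysis
universe; terms outside [5, 2000] genes are excluded (both bounds
configurable). Adjustment is Benjamini–Yekutieli, valid under the
arbitrary dependence of nested terms. Redundancy resolution runs
bottom-up: each significant term with significant offspring is re-tested
after removing the offspring's genes from both query and term, and kept
only if the residual raw p ≤ 0.05 (threshold configurable; raw p is used
because the residual test is a conditional follow-up, not a member of
the original family). Note that dropping a redundant ancestor can leave
a selected set whose query-gene union is smaller than the ancestor's own
overlap — that is the intended behaviour of offspring-only selection,
not an invariant violation.

Gene-set enrichment and PPI direct-neighbour enrichment are the same
hypergeometric tail; for the neighbour test the reference set is the
union of the seeds' direct neighbours minus the seeds, and the query
must have seed members removed first (enforced).

All tail probabilities are summed in log space (`logsumexp` over log
pmfs), so values far below double-precision underflow remain
representable as finite log10 p; the linear p_value may round to 0.0.

## Synthetic cohorts

The generator encodes the study conditions the pipeline targets: two
platforms sharing one truth, three groups per platform (defaults
n_A = n_B = 40, n_normal = 25), and 2,000 genes of which 5% each are
planted as class1-larger-in-A, class1-larger-in-B, class2, and
single-subtype DE (the remaining 80% null). Effect sizes are log2
shifts drawn once per gene: class 1 genes get a base magnitude
U(1.0, 1.4) plus an extent gap U(0.5, 1.0); class 2 and single-subtype
magnitudes are U(1.0, 1.8) with random shared sign. These are clearly
detectable effects by design — the recovery suite asks whether the
*classification machinery* preserves and confirms them across platforms,
not whether SAM can find marginal effects.

The microarray layer adds per-probe multiplicity (80/15/5% for 1/2/3
probes), probe offsets N(0, 0.3), measurement noise N(0, 0.4), 3%
multi-mapped and 5% unmapped extra probes, and 5% missing entries. The
RNA-seq layer exponentiates the latent log2 values back to normalized
counts with noise N(0, 0.5) on the log scale. Its near-zero peak arises
from two mechanisms: 15% of (null) genes drawn from a low-expression
baseline component, and technical zeros whose probability decays
exponentially with the count (0.3 at zero counts, halved every 8
counts) — so well-expressed entries are essentially never zeroed, as in
real bulk data. Only null genes use the low component, because a planted
log2 shift presupposes an expressed gene. An optional per-gene platform
bias (default 0) perturbs RNA-seq effects to stress the concordance
tests.

What the generator does *not* model: batch effects, copy-number
coupling, tumour-purity/cell-composition mixtures, and library-size
variation. Passing recovery tests therefore demonstrates the pipeline's
internal correctness and cross-platform logic under clean planted
signal; they do not certify performance on confounded real cohorts.

## Problem sizes and determinism

Simulation-heavy checks use 500 permutations, 400–2,000 genes, and 5–20
seeds — sizes chosen so the whole suite exercises every stage, including
full end-to-end recovery, in well under a minute per run while leaving
the permutation null densely sampled relative to the thresholds in play.
Every random draw flows from an explicit seed through
`numpy.random.default_rng` / `SeedSequence`; re-running any stage with
the same config reproduces every output file byte-identically.

## Known limitations

* The sign-based extent rule labels every confirmed class 1 gene, even
  ones whose between-subtype difference is within noise; use the
  significance-restricted variant if a conservative labelling matters.
* The permutation FDR inherits the median estimator's granularity at
  very small call counts (see above).
* GO input is a term/is_a-edge/annotation table triple, not full OBO;
  relations other than is_a are out of scope.
* The Fisher exact wrapper is experimental and limited to 2×2 tables.
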