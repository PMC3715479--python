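"""Classification of genes dysregulated in both disease subtypes.

Given the DE gene sets of subtype A vs normal and subtype B vs normal,
the genes called in both contrasts are partitioned by direction:

* class 1 — dysregulated in the same direction in both subtypes; these
  are further split by *extent*: a class 1 gene is dysregulated to a
  larger extent in subtype A if its between-subtype mean difference
  points the same way as the shared direction (further above normal for
  shared-up genes, further below for shared-down genes), and to a larger
  extent in subtype B otherwise.
* class 2 — dysregulated in opposite directions in the two subtypes,
  recorded with their orientation (up in A / down in B, or the reverse).

Because each dataset captures only part of the true DE genes, the
classification is validated across an independent platform: a gene is
*confirmed* if it lands in the same class with the same direction (class
1) or the same orientation (class 2) in both datasets.  Agreement beyond
chance is quantified by a hypergeometric overlap test and a fair-coin
binomial test on direction concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .preprocess import ExpressionMatrix
from .sam import DOWN, UP, DEGeneSet
from .stats import TailTestResult, binom_tail, hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = [
    "ClassComparison",
    "ExtentSubclass",
    "ConcordanceResult",
    "ConfirmedSets",
    "compare_de_sets",
    "subclassify_extent",
    "cross_dataset_overlap",
    "direction_concordance",
    "confirm_across_datasets",
]

UP_A_DOWN_B = "up_in_A_down_in_B"
DOWN_A_UP_B = "down_in_A_up_in_B"

LARGER_IN_A = "larger_in_A"
LARGER_IN_B = "larger_in_B"
UNCLASSIFIED = "unclassified"


@dataclass
class ClassComparison:
    """Partition of the DE genes shared by the two subtype contrasts."""

    n1: int  # subtype-A DE genes
    n2: int  # subtype-B DE genes
    class1: dict[str, str]  # gene -> shared direction (up/down)
    class2: dict[str, str]  # gene -> orientation

    @property
    def n_overlap(self) -> int:
        return len(self.class1) + len(self.class2)

    @property
    def n_same_direction(self) -> int:
        return len(self.class1)


@dataclass
class ExtentSubclass:
    """Extent partition of the class 1 genes."""

    larger_in_a: set[str]
    larger_in_b: set[str]
    unclassified: set[str]

    def label_of(self, gene: str) -> str:
        if gene in self.larger_in_a:
            return LARGER_IN_A
        if gene in self.larger_in_b:
            return LARGER_IN_B
        return UNCLASSIFIED


@dataclass
class ConcordanceResult:
    """Overlap and direction-concordance evidence between two gene lists."""

    overlap: int
    size_a: int
    size_b: int
    universe: int
    hypergeom: TailTestResult
    concordant: int | None = None
    binomial: TailTestResult | None = None


@dataclass
class ConfirmedSets:
    """Class memberships confirmed in both datasets."""

    class1: dict[str, str]  # gene -> shared direction
    class2: dict[str, str]  # gene -> orientation


def compare_de_sets(set_a: DEGeneSet, set_b: DEGeneSet) -> ClassComparison:
    """Partition the genes DE in both subtypes into class 1 and class 2."""
    if not set_a.directions or not set_b.directions:
        raise ValueError("both DE gene sets must be nonempty")
    class1: dict[str, str] = {}
    class2: dict[str, str] = {}
    for gene in set_a.genes & set_b.genes:
        da, db = set_a.directions[gene], set_b.directions[gene]
        if da == db:
            class1[gene] = da
        else:
            class2[gene] = UP_A_DOWN_B if da == UP else DOWN_A_UP_B
    logger.info(
        "compare_de_sets: N1=%d, N2=%d, N=%d shared, n=%d class 1, %d class 2",
        len(set_a), len(set_b), len(class1) + len(class2), len(class1), len(class2),
    )
    return ClassComparison(
        n1=len(set_a), n2=len(set_b), class1=class1, class2=class2
    )


def subclassify_extent(
    cc: ClassComparison,
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    significant_ab: set[str] | None = None,
) -> ExtentSubclass:
    """Split class 1 genes by which subtype departs further from normal.

    For each class 1 gene, Δ_AB = mean(subtype A) − mean(subtype B).  A
    shared-up gene with Δ_AB > 0, or a shared-down gene with Δ_AB < 0, is
    dysregulated to a larger extent in subtype A; the opposite signs give
    subtype B.  Δ_AB = 0 leaves the gene unclassified.

    ``significant_ab``, if given, restricts extent labels to genes whose
    A-vs-B contrast is itself significant (the default labels every class
    1 gene by the sign of Δ_AB alone, which is what makes the extent
    subclasses partition class 1).
    """
    missing = [g for g in cc.class1 if g not in matrix.gene_ids]
    if missing:
        raise ValueError(f"class 1 genes missing from matrix: {missing[:10]}")
    genes = list(cc.class1)
    sub = matrix.subset_genes(genes)
    delta_ab = sub.group_values(group_a).mean(axis=1) - sub.group_values(group_b).mean(axis=1)

    larger_a: set[str] = set()
    larger_b: set[str] = set()
    unclassified: set[str] = set()
    for gene, dab in zip(genes, delta_ab):
        if significant_ab is not None and gene not in significant_ab:
            unclassified.add(gene)
            continue
        shared_up = cc.class1[gene] == UP
        if dab == 0:
            unclassified.add(gene)
        elif (dab > 0) == shared_up:
            larger_a.add(gene)
        else:
            larger_b.add(gene)
    logger.info(
        "subclassify_extent: %d larger in %s, %d larger in %s, %d unclassified",
        len(larger_a), group_a, len(larger_b), group_b, len(unclassified),
    )
    return ExtentSubclass(larger_a, larger_b, unclassified)


def cross_dataset_overlap(
    list_a: set[str], list_b: set[str], universe: set[str]
) -> ConcordanceResult:
    """Hypergeometric test of the overlap of two gene lists in a universe."""
    for name, lst in (("list_a", list_a), ("list_b", list_b)):
        outside = lst - universe
        if outside:
            raise ValueError(f"{name} not a subset of universe: {sorted(outside)[:10]}")
    k = len(list_a & list_b)
    res = hypergeom_tail(k, len(list_a), len(list_b), len(universe))
    return ConcordanceResult(
        overlap=k, size_a=len(list_a), size_b=len(list_b),
        universe=len(universe), hypergeom=res,
    )


def direction_concordance(
    dirs_a: dict[str, str], dirs_b: dict[str, str]
) -> tuple[int, int, TailTestResult]:
    """Fair-coin binomial test of per-gene label agreement in two datasets.

    Both dicts must label the same genes (any hashable labels — up/down
    directions, extent labels, or class 2 orientations).  Returns
    (concordant count c, total k, binomial upper tail of c at p=0.5).
    """
    if set(dirs_a) != set(dirs_b):
        raise ValueError("the two datasets must label the same genes")
    k = len(dirs_a)
    c = sum(dirs_a[g] == dirs_b[g] for g in dirs_a)
    return c, k, binom_tail(c, k, 0.5)


def confirm_across_datasets(
    cc_a: ClassComparison, cc_b: ClassComparison
) -> ConfirmedSets:
    """Genes with identical classification in two independent datasets.

    A class 1 gene is confirmed when both datasets place it in class 1
    with the same shared direction; a class 2 gene when both record the
    same orientation.
    """
    class1 = {
        g: d for g, d in cc_a.class1.items() if cc_b.class1.get(g) == d
    }
    class2 = {
        g: o for g, o in cc_a.class2.items() if cc_b.class2.get(g) == o
    }
    logger.info(
        "confirm_across_datasets: %d class 1 and %d class 2 genes confirmed",
        len(class1), len(class2),
    )
    return ConfirmedSets(class1=class1, class2=class2)
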