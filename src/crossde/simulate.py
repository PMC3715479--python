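"""Synthetic two-platform cohorts with planted class structure.

The generator emulates the data situation the pipeline is built for: two
platforms (a microarray with probe-level artefacts and an RNA-seq run)
measuring an overlapping gene universe in three sample groups — two
disease subtypes and a shared normal control group.  Genes are planted in
five kinds:

* ``class1_larger_A`` / ``class1_larger_B`` — dysregulated in the same
  direction in both subtypes but further from normal in one of them;
* ``class2`` — dysregulated in opposite directions in the two subtypes;
* ``single_subtype`` — dysregulated in only one subtype;
* ``null`` — no effect.

Effect sizes (log2 shifts) are drawn once per gene and shared by both
platforms — direction is a property of the gene, not of the platform —
while measurement noise is platform-specific and independent.  The
microarray layer adds probe multiplicity (including multi-mapped and
unmapped probes), probe offsets, and randomly missing entries; the
RNA-seq layer exponentiates back to normalized counts with multiplicative
noise and zero-inflation, producing the characteristic roughly log-normal
marginal with an extra peak near zero.

Small companion generators provide a toy GO DAG with a term enriched for
a designated query, and an interaction network with planted seed-to-target
edges, so enrichment stages are testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GODag
from .preprocess import ProbeAnnotation, ProbeMatrix

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "SyntheticGO",
    "generate_cohort",
    "generate_go",
    "generate_ppi",
    "KINDS",
]

KINDS = ("class1_larger_A", "class1_larger_B", "class2", "single_subtype", "null")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Group sizes apply per platform; fractions of planted kinds must sum to
    at most 1 (the remainder is null).  Effect magnitudes are log2 shifts:
    class 1 genes get a base magnitude in ``class1_base_range`` for the
    lesser subtype plus a gap in ``class1_gap_range`` for the larger one;
    class 2 and single-subtype magnitudes come from ``effect_range``.
    ``platform_bias_sd`` perturbs RNA-seq effect sizes per gene to stress
    the cross-platform concordance tests (0 = both platforms share the
    exact effects).

    The RNA-seq near-zero peak arises from two mechanisms: a fraction
    ``low_expression_fraction`` of (null) genes drawn from a low baseline
    component, and technical zeros whose per-entry probability decays
    exponentially in the count (``rnaseq_dropout`` at zero counts, halved
    every ``rnaseq_dropout_halfscale`` counts) — so well-expressed entries
    are essentially never zeroed, as in real bulk data.
    """

    seed: int
    n_genes: int = 2000
    n_a: int = 40
    n_b: int = 40
    n_normal: int = 25
    fractions: dict = field(
        default_factory=lambda: {
            "class1_larger_A": 0.05,
            "class1_larger_B": 0.05,
            "class2": 0.05,
            "single_subtype": 0.05,
        }
    )
    class1_base_range: tuple[float, float] = (1.0, 1.4)
    class1_gap_range: tuple[float, float] = (0.5, 1.0)
    effect_range: tuple[float, float] = (1.0, 1.8)
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    microarray_noise_sd: float = 0.4
    probe_offset_sd: float = 0.3
    missing_rate: float = 0.05
    probe_multiplicity: dict = field(default_factory=lambda: {1: 0.8, 2: 0.15, 3: 0.05})
    unmapped_probe_fraction: float = 0.05
    multimapped_probe_fraction: float = 0.03
    rnaseq_noise_sd: float = 0.5
    low_expression_fraction: float = 0.15
    low_baseline_mean: float = 1.0
    low_baseline_sd: float = 0.7
    rnaseq_dropout: float = 0.3
    rnaseq_dropout_halfscale: float = 8.0
    platform_bias_sd: float = 0.0
    group_names: tuple[str, str, str] = ("ERpos", "ERneg", "normal")

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_normal) < 2:
            raise ValueError("every group needs >= 2 samples")
        if sum(self.fractions.values()) > 1 + 1e-12:
            raise ValueError("planted-kind fractions must sum to <= 1")
        for name in self.fractions:
            if name not in KINDS:
                raise ValueError(f"unknown planted kind: {name!r}")
        for rate in (self.missing_rate, self.rnaseq_dropout,
                     self.low_expression_fraction,
                     self.unmapped_probe_fraction, self.multimapped_probe_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Generated inputs for both platforms plus the planted truth."""

    probe_matrix: ProbeMatrix
    annotation: ProbeAnnotation
    rnaseq_counts: pd.DataFrame
    groups_microarray: pd.Series
    groups_rnaseq: pd.Series
    truth: pd.DataFrame  # per gene: kind, effect_a, effect_b, extent, orientation


@dataclass
class SyntheticGO:
    """Toy GO DAG plus its direct (unpropagated) annotations."""

    dag: GODag
    direct_annotations: dict[str, set[str]]
    target_term: str


def _plant_effects(cfg: GeneratorConfig, rng: np.random.Generator):
    n = cfg.n_genes
    names = [k for k in KINDS if k != "null"]
    probs = [cfg.fractions.get(k, 0.0) for k in names]
    probs.append(1.0 - sum(probs))
    kinds = rng.choice(names + ["null"], size=n, p=probs)

    eff_a = np.zeros(n)
    eff_b = np.zeros(n)
    extent = np.array([""] * n, dtype=object)
    orientation = np.array([""] * n, dtype=object)
    sign = rng.choice([-1.0, 1.0], size=n)
    for i, kind in enumerate(kinds):
        if kind == "null":
            continue
        if kind in ("class1_larger_A", "class1_larger_B"):
            base = rng.uniform(*cfg.class1_base_range)
            gap = rng.uniform(*cfg.class1_gap_range)
            if kind == "class1_larger_A":
                eff_a[i], eff_b[i] = sign[i] * (base + gap), sign[i] * base
                extent[i] = "larger_in_A"
            else:
                eff_a[i], eff_b[i] = sign[i] * base, sign[i] * (base + gap)
                extent[i] = "larger_in_B"
        elif kind == "class2":
            eff_a[i] = sign[i] * rng.uniform(*cfg.effect_range)
            eff_b[i] = -sign[i] * rng.uniform(*cfg.effect_range)
            orientation[i] = (
                "up_in_A_down_in_B" if sign[i] > 0 else "down_in_A_up_in_B"
            )
        elif kind == "single_subtype":
            effect = sign[i] * rng.uniform(*cfg.effect_range)
            if rng.random() < 0.5:
                eff_a[i] = effect
            else:
                eff_b[i] = effect
    return kinds, eff_a, eff_b, extent, orientation


def _group_layout(cfg: GeneratorConfig, prefix: str):
    a, b, norm = cfg.group_names
    samples = (
        [f"{prefix}_{a}_{i:03d}" for i in range(cfg.n_a)]
        + [f"{prefix}_{b}_{i:03d}" for i in range(cfg.n_b)]
        + [f"{prefix}_{norm}_{i:03d}" for i in range(cfg.n_normal)]
    )
    groups = pd.Series(
        [a] * cfg.n_a + [b] * cfg.n_b + [norm] * cfg.n_normal,
        index=samples, name="group",
    )
    return samples, groups


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Generate a reproducible two-platform cohort with planted truth."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    kinds, eff_a, eff_b, extent, orientation = _plant_effects(cfg, rng)
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    # A fraction of genes is essentially unexpressed, giving the RNA-seq
    # marginal its near-zero peak.  Only null genes are drawn from the low
    # component: planted log2 effects presuppose an expressed gene.
    null_idx = np.where(kinds == "null")[0]
    n_low = min(int(round(cfg.low_expression_fraction * cfg.n_genes)), null_idx.size)
    low_idx = rng.choice(null_idx, size=n_low, replace=False) if n_low else []
    mu[low_idx] = np.maximum(
        rng.normal(cfg.low_baseline_mean, cfg.low_baseline_sd, n_low), 0.0
    )

    def latent(eff_a_p, eff_b_p):
        # gene × sample latent log2 values, groups ordered A, B, normal
        shift = np.concatenate([
            np.tile(eff_a_p[:, None], (1, cfg.n_a)),
            np.tile(eff_b_p[:, None], (1, cfg.n_b)),
            np.zeros((cfg.n_genes, cfg.n_normal)),
        ], axis=1)
        return mu[:, None] + shift

    # --- microarray layer ---------------------------------------------------
    samples_ma, groups_ma = _group_layout(cfg, "MA")
    L = latent(eff_a, eff_b)
    mult_vals = np.array(sorted(cfg.probe_multiplicity))
    mult_p = np.array([cfg.probe_multiplicity[v] for v in mult_vals], dtype=float)
    mult_p /= mult_p.sum()
    multiplicity = rng.choice(mult_vals, size=cfg.n_genes, p=mult_p)
    gene_idx = np.repeat(np.arange(cfg.n_genes), multiplicity)
    n_mapped = gene_idx.size
    n_multi = int(round(cfg.multimapped_probe_fraction * n_mapped))
    n_unmapped = int(round(cfg.unmapped_probe_fraction * n_mapped))

    probe_ids = [f"P{i:06d}" for i in range(n_mapped + n_multi + n_unmapped)]
    mapping: dict[str, frozenset[str]] = {}
    values = np.empty((len(probe_ids), len(samples_ma)))

    offsets = rng.normal(0.0, cfg.probe_offset_sd, n_mapped)
    values[:n_mapped] = (
        L[gene_idx]
        + offsets[:, None]
        + rng.normal(0.0, cfg.microarray_noise_sd, (n_mapped, len(samples_ma)))
    )
    for p, g in zip(probe_ids[:n_mapped], gene_idx):
        mapping[p] = frozenset([genes[g]])
    for j in range(n_multi):
        p = probe_ids[n_mapped + j]
        g1, g2 = rng.choice(cfg.n_genes, size=2, replace=False)
        mapping[p] = frozenset([genes[g1], genes[g2]])
        values[n_mapped + j] = L[g1] + rng.normal(
            0.0, cfg.microarray_noise_sd, len(samples_ma)
        )
    base_extra = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_unmapped)
    values[n_mapped + n_multi:] = base_extra[:, None] + rng.normal(
        0.0, cfg.microarray_noise_sd, (n_unmapped, len(samples_ma))
    )

    mask = rng.random(values.shape) < cfg.missing_rate
    fully_missing = mask.all(axis=1)
    mask[fully_missing, 0] = False  # keep the >=1-observed invariant
    values = np.where(mask, np.nan, values)
    probe_frame = pd.DataFrame(values, index=probe_ids, columns=samples_ma)
    probe_frame.index.name = "probe_id"

    # --- RNA-seq layer ------------------------------------------------------
    samples_rs, groups_rs = _group_layout(cfg, "RS")
    if cfg.platform_bias_sd > 0:
        eff_a_rs = eff_a + rng.normal(0.0, cfg.platform_bias_sd, cfg.n_genes)
        eff_b_rs = eff_b + rng.normal(0.0, cfg.platform_bias_sd, cfg.n_genes)
    else:
        eff_a_rs, eff_b_rs = eff_a, eff_b
    Lr = latent(eff_a_rs, eff_b_rs) + rng.normal(
        0.0, cfg.rnaseq_noise_sd, (cfg.n_genes, len(samples_rs))
    )
    counts = np.maximum(np.exp2(Lr) - 1.0, 0.0)
    # expression-dependent technical zeros: likely for near-zero counts,
    # vanishing for well-expressed entries
    p_zero = cfg.rnaseq_dropout * np.exp(-counts / cfg.rnaseq_dropout_halfscale)
    counts[rng.random(counts.shape) < p_zero] = 0.0
    counts_frame = pd.DataFrame(counts, index=genes, columns=samples_rs)
    counts_frame.index.name = "gene_id"

    truth = pd.DataFrame(
        {
            "kind": kinds,
            "effect_a": eff_a,
            "effect_b": eff_b,
            "extent": extent,
            "orientation": orientation,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return SyntheticCohort(
        probe_matrix=ProbeMatrix(probe_frame),
        annotation=ProbeAnnotation(mapping),
        rnaseq_counts=counts_frame,
        groups_microarray=groups_ma,
        groups_rnaseq=groups_rs,
        truth=truth,
    )


def generate_go(
    n_terms: int,
    depth: int,
    universe: list[str],
    query: set[str],
    enrichment_rate: float = 0.8,
    seed: int = 0,
    term_size_range: tuple[int, int] = (5, 30),
) -> SyntheticGO:
    """Toy is_a DAG with one leaf term enriched for a designated query.

    Terms are spread over ``depth`` levels below a single root; each term
    gets a random parent one level up.  The designated target term (the
    first deepest leaf) directly annotates a fraction ``enrichment_rate``
    of the query plus a little background; other terms annotate random
    universe genes.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= enrichment_rate <= 1:
        raise ValueError("enrichment_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    levels = {terms[0]: 0}
    edges: list[tuple[str, str]] = []
    for i, t in enumerate(terms[1:], start=1):
        level = 1 + (i - 1) % depth
        levels[t] = level
        parents = [u for u in terms[:i] if levels[u] == level - 1]
        edges.append((t, str(rng.choice(parents))))

    deepest = max(levels.values())
    target = next(t for t in terms if levels[t] == deepest)
    query_list = sorted(query)
    n_hit = int(round(enrichment_rate * len(query_list)))
    hits = list(rng.choice(query_list, size=n_hit, replace=False)) if n_hit else []

    annotations: dict[str, set[str]] = {}
    lo, hi = term_size_range
    for t in terms:
        if t == target:
            background = [g for g in universe if g not in query]
            extra = list(rng.choice(background, size=min(3, len(background)),
                                    replace=False))
            members = hits + extra
        else:
            size = int(rng.integers(lo, hi + 1))
            members = list(rng.choice(universe, size=min(size, len(universe)),
                                      replace=False))
        for g in members:
            annotations.setdefault(str(g), set()).add(t)
    return SyntheticGO(
        dag=GODag(edges, annotations), direct_annotations=annotations,
        target_term=target,
    )


def generate_ppi(
    nodes: list[str],
    seed_genes: set[str],
    target_genes: set[str],
    planted_neighbor_overlap: float = 0.0,
    edge_prob: float = 0.005,
    seed: int = 0,
) -> nx.Graph:
    """Random interaction graph with optional planted seed→target edges.

    A G(n, p) background over ``nodes`` is augmented so that a fraction
    ``planted_neighbor_overlap`` of the target genes is adjacent to at
    least one seed gene.  The result is a simple graph with no self-loops
    and minimum degree 1 (isolated nodes are attached to a random partner).
    """
    if not 0 <= planted_neighbor_overlap <= 1:
        raise ValueError("planted_neighbor_overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = list(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    n = len(nodes)
    n_pairs = n * (n - 1) // 2
    n_edges = rng.binomial(n_pairs, edge_prob)
    idx_a = rng.integers(0, n, size=2 * n_edges + 8)
    idx_b = rng.integers(0, n, size=2 * n_edges + 8)
    added = 0
    for i, j in zip(idx_a, idx_b):
        if added >= n_edges:
            break
        if i != j:
            g.add_edge(nodes[i], nodes[j])
            added += 1
    seeds = sorted(seed_genes)
    if seeds and planted_neighbor_overlap > 0:
        targets = sorted(target_genes - seed_genes)
        n_plant = int(round(planted_neighbor_overlap * len(targets)))
        chosen = rng.choice(targets, size=n_plant, replace=False) if n_plant else []
        for t in chosen:
            g.add_edge(str(t), seeds[int(rng.integers(len(seeds)))])
    for node in [v for v in g.nodes if g.degree(v) == 0]:
        partner = nodes[int(rng.integers(n))]
        while partner == node:
            partner = nodes[int(rng.integers(n))]
        g.add_edge(node, partner)
    return g
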