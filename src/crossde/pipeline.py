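"""End-to-end orchestration: preprocess → DE → classify → concord → enrich.

:func:`analyze_cohort` is the in-memory engine: given the processed
expression matrices of the two platforms it runs the subtype-vs-normal
contrasts, partitions the shared DE genes into class 1 / class 2,
subclassifies class 1 by extent, confirms both classes across platforms,
and computes the overlap and direction-concordance statistics.

:func:`run_full_analysis` is the file-based wrapper used by the CLI: it
reads the platform inputs, applies the preprocessing chain, calls the
engine, optionally adds the enrichment stage, and writes TSV reports plus
a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .classify import (
    ClassComparison,
    ConcordanceResult,
    ConfirmedSets,
    ExtentSubclass,
    compare_de_sets,
    confirm_across_datasets,
    cross_dataset_overlap,
    direction_concordance,
    subclassify_extent,
)
from .enrichment import geneset_enrich, go_enrich, ppi_neighbor_enrich
from .preprocess import (
    ExpressionMatrix,
    collapse_probes_to_genes,
    filter_probes_by_missing,
    knn_impute,
    transform_rnaseq,
)
from .sam import DEGeneSet, SAMConfig, permutation_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "PlatformResult",
    "PipelineReport",
    "analyze_cohort",
    "run_full_analysis",
    "summarize_counts",
    "percent_half_up",
    "preprocess_microarray",
]


def percent_half_up(numerator: int, denominator: int) -> int:
    """Integer percentage with half-up rounding (the usual print rendering)."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class PlatformResult:
    """Per-platform DE and classification results."""

    de_tables: dict[str, pd.DataFrame]  # contrast label -> SAM table
    de_sets: dict[str, DEGeneSet]  # "A" / "B" -> called genes
    comparison: ClassComparison
    extent: ExtentSubclass


@dataclass
class PipelineReport:
    """Everything the analysis produced, ready for summarisation or writing."""

    universe: list[str]
    platforms: dict[str, PlatformResult]
    confirmed: ConfirmedSets
    concordance: dict[str, ConcordanceResult | tuple]
    extent_concordant: dict[str, set[str]]  # label -> genes concordant in both
    enrichment: dict[str, object] | None = None


def _contrast_seeds(base_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(base_seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _platform_analysis(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    normal: str,
    sam_cfg: SAMConfig,
    seeds: list[int],
) -> PlatformResult:
    tables: dict[str, pd.DataFrame] = {}
    sets: dict[str, DEGeneSet] = {}
    for key, case, seed in (("A", group_a, seeds[0]), ("B", group_b, seeds[1])):
        cfg = SAMConfig(
            seed=seed,
            n_permutations=sam_cfg.n_permutations,
            target_fdr=sam_cfg.target_fdr,
            s0_method=sam_cfg.s0_method,
            s0_percentile=sam_cfg.s0_percentile,
        )
        table = permutation_fdr(matrix, case, normal, cfg)
        called = table[table["called"] & (table["direction"] != "")]
        tables[key] = table
        sets[key] = DEGeneSet(
            contrast=f"{case}_vs_{normal}",
            directions=dict(zip(called.index.astype(str), called["direction"])),
        )
    comparison = compare_de_sets(sets["A"], sets["B"])
    extent = subclassify_extent(comparison, matrix, group_a, group_b)
    return PlatformResult(tables, sets, comparison, extent)


def analyze_cohort(
    microarray: ExpressionMatrix,
    rnaseq: ExpressionMatrix,
    sam_cfg: SAMConfig,
    group_a: str = "ERpos",
    group_b: str = "ERneg",
    normal: str = "normal",
    universe: list[str] | None = None,
) -> PipelineReport:
    """Run the full two-platform comparison on processed matrices.

    The gene universe defaults to the genes measured on both platforms
    after preprocessing; both matrices are restricted to it before DE.
    """
    if universe is None:
        universe = sorted(set(microarray.gene_ids) & set(rnaseq.gene_ids))
    if not universe:
        raise ValueError("empty gene universe: no genes shared by both platforms")
    ma = microarray.subset_genes(universe)
    rs = rnaseq.subset_genes(universe)
    seeds = _contrast_seeds(sam_cfg.seed, 4)

    platforms = {
        "microarray": _platform_analysis(ma, group_a, group_b, normal, sam_cfg, seeds[:2]),
        "rnaseq": _platform_analysis(rs, group_a, group_b, normal, sam_cfg, seeds[2:]),
    }
    cc_ma = platforms["microarray"].comparison
    cc_rs = platforms["rnaseq"].comparison
    confirmed = confirm_across_datasets(cc_ma, cc_rs)
    uni = set(universe)

    concordance: dict[str, ConcordanceResult | tuple] = {}
    class1_ma, class1_rs = set(cc_ma.class1), set(cc_rs.class1)
    class2_ma, class2_rs = set(cc_ma.class2), set(cc_rs.class2)
    concordance["class1_overlap"] = cross_dataset_overlap(class1_ma, class1_rs, uni)
    concordance["class2_overlap"] = cross_dataset_overlap(class2_ma, class2_rs, uni)
    shared1 = class1_ma & class1_rs
    concordance["class1_direction"] = direction_concordance(
        {g: cc_ma.class1[g] for g in shared1},
        {g: cc_rs.class1[g] for g in shared1},
    )
    shared2 = class2_ma & class2_rs
    concordance["class2_orientation"] = direction_concordance(
        {g: cc_ma.class2[g] for g in shared2},
        {g: cc_rs.class2[g] for g in shared2},
    )
    ext_ma, ext_rs = platforms["microarray"].extent, platforms["rnaseq"].extent
    labelled = {
        g: ext_ma.label_of(g)
        for g in confirmed.class1
        if ext_ma.label_of(g) != "unclassified" and ext_rs.label_of(g) != "unclassified"
    }
    concordance["extent"] = direction_concordance(
        labelled, {g: ext_rs.label_of(g) for g in labelled}
    )
    extent_concordant = {
        label: {g for g, lab in labelled.items()
                if lab == label and ext_rs.label_of(g) == label}
        for label in ("larger_in_A", "larger_in_B")
    }
    return PipelineReport(
        universe=list(universe),
        platforms=platforms,
        confirmed=confirmed,
        concordance=concordance,
        extent_concordant=extent_concordant,
    )


def summarize_counts(report: PipelineReport) -> pd.DataFrame:
    """Headline counts, percentages (half-up integers) and p-values."""
    rows: list[dict] = []

    def add(metric: str, value) -> None:
        rows.append({"metric": metric, "value": value})

    for platform, res in report.platforms.items():
        cc = res.comparison
        add(f"{platform}.N1_subtypeA_DE", cc.n1)
        add(f"{platform}.N2_subtypeB_DE", cc.n2)
        add(f"{platform}.N_overlap", cc.n_overlap)
        add(f"{platform}.n_class1", cc.n_same_direction)
        add(f"{platform}.n_class2", len(cc.class2))
        if cc.n_overlap:
            add(
                f"{platform}.pct_same_direction",
                percent_half_up(cc.n_same_direction, cc.n_overlap),
            )
        add(f"{platform}.extent_larger_in_A", len(res.extent.larger_in_a))
        add(f"{platform}.extent_larger_in_B", len(res.extent.larger_in_b))
    add("confirmed.class1", len(report.confirmed.class1))
    add("confirmed.class2", len(report.confirmed.class2))
    for key in ("class1_overlap", "class2_overlap"):
        res = report.concordance[key]
        add(f"{key}.k", res.overlap)
        add(f"{key}.log10_p_hypergeom", round(res.hypergeom.log10_p, 4))
    for key in ("class1_direction", "class2_orientation", "extent"):
        c, k, tail = report.concordance[key]
        add(f"{key}.concordant", c)
        add(f"{key}.total", k)
        if k:
            add(f"{key}.pct_concordant", percent_half_up(c, k))
        add(f"{key}.log10_p_binomial", round(tail.log10_p, 4))
    return pd.DataFrame(rows, columns=["metric", "value"])


def preprocess_microarray(
    probes,
    annotation,
    groups: pd.Series,
    max_missing_fraction: float = 0.2,
    knn_k: int = 15,
) -> ExpressionMatrix:
    """Missing-rate filter → KNN imputation → probe-to-gene collapsing."""
    filtered = filter_probes_by_missing(probes, max_missing_fraction)
    imputed = knn_impute(filtered, k=knn_k)
    return collapse_probes_to_genes(imputed, annotation, groups=groups)


def _write_de_tables(report: PipelineReport, outdir: Path) -> list[str]:
    written = []
    for platform, res in report.platforms.items():
        for key, table in res.de_tables.items():
            name = f"de_{platform}_{'A' if key == 'A' else 'B'}_vs_normal.tsv"
            cio.write_matrix_tsv(table, outdir / name)
            written.append(name)
    return written


def _write_class_tables(report: PipelineReport, outdir: Path) -> None:
    cc_ma = report.platforms["microarray"].comparison
    cc_rs = report.platforms["rnaseq"].comparison
    ext_ma = report.platforms["microarray"].extent
    ext_rs = report.platforms["rnaseq"].extent
    rows1 = [
        {
            "gene_id": g,
            "direction": d,
            "extent_microarray": ext_ma.label_of(g),
            "extent_rnaseq": ext_rs.label_of(g) if g in cc_rs.class1 else "",
            "confirmed": g in report.confirmed.class1,
        }
        for g, d in sorted(cc_ma.class1.items())
    ]
    pd.DataFrame(
        rows1,
        columns=["gene_id", "direction", "extent_microarray", "extent_rnaseq", "confirmed"],
    ).to_csv(outdir / "class1.tsv", sep="\t", index=False)
    rows2 = [
        {
            "gene_id": g,
            "orientation_microarray": o,
            "orientation_rnaseq": cc_rs.class2.get(g, ""),
            "confirmed": g in report.confirmed.class2,
        }
        for g, o in sorted(cc_ma.class2.items())
    ]
    pd.DataFrame(
        rows2,
        columns=["gene_id", "orientation_microarray", "orientation_rnaseq", "confirmed"],
    ).to_csv(outdir / "class2.tsv", sep="\t", index=False)


def _concordance_rows(report: PipelineReport) -> pd.DataFrame:
    rows = []
    for key in ("class1_overlap", "class2_overlap"):
        res = report.concordance[key]
        rows.append({
            "test": f"{key}_hypergeom", "k": res.overlap, "K": res.size_a,
            "n": res.size_b, "N": res.universe,
            "p_value": res.hypergeom.p_value, "log10_p": res.hypergeom.log10_p,
        })
    for key in ("class1_direction", "class2_orientation", "extent"):
        c, k, tail = report.concordance[key]
        rows.append({
            "test": f"{key}_binomial", "k": c, "K": k, "n": k, "N": k,
            "p_value": tail.p_value, "log10_p": tail.log10_p,
        })
    return pd.DataFrame(rows)


def _enrichment_stage(report: PipelineReport, cfg: dict, outdir: Path) -> dict:
    out: dict[str, object] = {}
    universe = set(report.universe)
    ecfg = cfg.get("enrichment") or {}
    fdr = float(ecfg.get("fdr", 0.05))
    if "go" in ecfg:
        go = ecfg["go"]
        dag = cio.read_go_tables(go["terms"], go["edges"], go["annotations"])
        for label, genes in report.extent_concordant.items():
            records = go_enrich(
                genes & universe, universe, dag, fdr=fdr,
                min_term_size=int(ecfg.get("min_term_size", 5)),
                max_term_size=int(ecfg.get("max_term_size", 2000)),
            )
            frame = pd.DataFrame([r.__dict__ for r in records])
            frame.to_csv(outdir / f"go_{label}.tsv", sep="\t", index=False)
            out[f"go_{label}"] = records
    tests: list[dict] = []
    if "gene_sets" in ecfg:
        gene_sets = cio.read_gmt(ecfg["gene_sets"])
        class2 = set(report.confirmed.class2) & universe
        for name, ref in gene_sets.items():
            res = geneset_enrich(class2, ref & universe, universe)
            tests.append(res.as_row(f"geneset_{name}"))
            out[f"geneset_{name}"] = res
            if "ppi" in ecfg and class2 - ref:
                net = cio.read_edge_list(ecfg["ppi"])
                res2 = ppi_neighbor_enrich(class2 - ref, ref, net, universe)
                tests.append(res2.as_row(f"ppi_neighbors_{name}"))
                out[f"ppi_neighbors_{name}"] = res2
    if tests:
        pd.DataFrame(tests).to_csv(outdir / "set_enrichment.tsv", sep="\t", index=False)
    return out


def run_full_analysis(cfg: dict, outdir) -> PipelineReport:
    """File-based pipeline run; writes TSV reports and a JSON manifest.

    Required config keys: ``seed``; ``microarray`` (``probes``,
    ``annotation``, ``labels`` paths); ``rnaseq`` (``counts``, ``labels``);
    ``groups`` (``subtype_a``, ``subtype_b``, ``normal`` label names).
    Optional: ``sam`` (permutations, FDR, s0 method), ``preprocess``
    (missing threshold, k), ``enrichment`` (GO/GMT/PPI paths).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups_cfg = cfg.get("groups", {})
    group_a = groups_cfg.get("subtype_a", "ERpos")
    group_b = groups_cfg.get("subtype_b", "ERneg")
    normal = groups_cfg.get("normal", "normal")

    pre = cfg.get("preprocess", {})
    from .preprocess import ProbeMatrix  # local import to keep top tidy

    ma_cfg = cfg["microarray"]
    probes = ProbeMatrix(cio.read_matrix_tsv(ma_cfg["probes"]))
    ann = cio.read_annotation_tsv(ma_cfg["annotation"])
    ma_groups = cio.read_groups_tsv(ma_cfg["labels"])
    microarray = preprocess_microarray(
        probes, ann, ma_groups,
        max_missing_fraction=float(pre.get("max_missing_fraction", 0.2)),
        knn_k=int(pre.get("knn_k", 15)),
    )
    rs_cfg = cfg["rnaseq"]
    counts = cio.read_matrix_tsv(rs_cfg["counts"])
    rs_groups = cio.read_groups_tsv(rs_cfg["labels"])
    rnaseq = transform_rnaseq(counts, groups=rs_groups)

    sam_block = cfg.get("sam", {})
    sam_cfg = SAMConfig(
        seed=int(cfg["seed"]),
        n_permutations=int(sam_block.get("n_permutations", 10_000)),
        target_fdr=float(sam_block.get("target_fdr", 0.01)),
        s0_method=sam_block.get("s0_method", "tusher_cv_minimization"),
        s0_percentile=float(sam_block.get("s0_percentile", 0.5)),
    )
    report = analyze_cohort(
        microarray, rnaseq, sam_cfg,
        group_a=group_a, group_b=group_b, normal=normal,
    )
    _write_de_tables(report, outdir)
    _write_class_tables(report, outdir)
    _concordance_rows(report).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    summarize_counts(report).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    if cfg.get("enrichment"):
        report.enrichment = _enrichment_stage(report, cfg, outdir)

    import scipy

    manifest = {
        "package": "crossde 0.1.0",
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "seed": int(cfg["seed"]),
        "sam": {
            "n_permutations": sam_cfg.n_permutations,
            "target_fdr": sam_cfg.target_fdr,
            "s0_method": sam_cfg.s0_method,
        },
        "low_precision_fdr": sam_cfg.n_permutations < 1000,
        "groups": {"subtype_a": group_a, "subtype_b": group_b, "normal": normal},
        "universe_size": len(report.universe),
        "confirmed_class1": len(report.confirmed.class1),
        "confirmed_class2": len(report.confirmed.class2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("run_full_analysis: wrote reports to %s", outdir)
    return report
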