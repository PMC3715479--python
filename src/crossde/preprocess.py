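"""Platform-specific preprocessing into analysis-ready expression matrices.

Microarray path: probe-level log2 matrices with missing entries are
filtered by missing rate, imputed by K-nearest-neighbour row imputation,
and collapsed probe→gene using an annotation table (probes mapping to zero
or multiple gene IDs are discarded; probes sharing a gene are averaged).

RNA-seq path: normalized expression counts are log2(x+1)-transformed.

Both paths end in an :class:`ExpressionMatrix` — a complete genes × samples
log2-scale matrix tagged with its platform and per-sample group labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeMatrix",
    "ProbeAnnotation",
    "ExpressionMatrix",
    "filter_probes_by_missing",
    "knn_impute",
    "collapse_probes_to_genes",
    "transform_rnaseq",
]


@dataclass
class ProbeMatrix:
    """Probe × sample matrix of log2 expression values; NaN marks missing."""

    values: pd.DataFrame
    platform: str = "microarray"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=1)


@dataclass
class ProbeAnnotation:
    """Probe → set-of-GeneIDs mapping from a two-column annotation table.

    A probe appearing with several distinct gene IDs is multi-mapped; a
    probe absent from the mapping is unmapped.  Both are dropped at the
    collapsing step.
    """

    mapping: dict[str, frozenset[str]]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProbeAnnotation":
        """Build from a DataFrame whose first two columns are probe_id, gene_id."""
        probe_col, gene_col = frame.columns[:2]
        mapping: dict[str, set[str]] = {}
        for probe, gene in zip(frame[probe_col], frame[gene_col]):
            gene = str(gene)
            if not gene:
                raise ValueError(f"empty gene id for probe {probe!r}")
            mapping.setdefault(str(probe), set()).add(gene)
        return cls({p: frozenset(g) for p, g in mapping.items()})

    def genes_for(self, probe: str) -> frozenset[str]:
        return self.mapping.get(probe, frozenset())


@dataclass
class ExpressionMatrix:
    """Complete gene × sample log2 matrix with group labels.

    ``groups`` maps sample id → group label (e.g. ``"ERpos"``, ``"ERneg"``,
    ``"normal"``); it may be attached later via :meth:`with_groups` when the
    matrix is built before labels are known.
    """

    values: pd.DataFrame
    platform: str
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if self.values.isna().any().any():
            raise ValueError("ExpressionMatrix must not contain missing values")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)
            if self.groups.isna().any():
                missing = list(self.values.columns[self.groups.isna()])
                raise ValueError(f"samples without group label: {missing[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def with_groups(self, groups: Mapping[str, str] | pd.Series) -> "ExpressionMatrix":
        return replace(self, groups=pd.Series(dict(groups)))

    def group_samples(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("no group labels attached")
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> np.ndarray:
        """Gene × sample array restricted to one group."""
        return self.values[self.group_samples(group)].to_numpy(dtype=float)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(genes)])


def filter_probes_by_missing(
    m: ProbeMatrix, max_missing_fraction: float = 0.2
) -> ProbeMatrix:
    """Drop probes whose missing fraction exceeds ``max_missing_fraction``.

    The boundary is inclusive on the keep side: a probe missing exactly the
    threshold fraction is retained; strictly higher is deleted.  Probe
    order is preserved.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = m.missing_fraction()
    keep = frac <= max_missing_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "filter_probes_by_missing: dropped %d/%d probes (> %.0f%% missing)",
            dropped, len(frac), 100 * max_missing_fraction,
        )
    return replace(m, values=m.values.loc[keep])


def knn_impute(m: ProbeMatrix, k: int = 15) -> ProbeMatrix:
    """Replace missing entries by row-wise K-nearest-neighbour imputation.

    For a probe with missing entries, candidate neighbours are the other
    probe rows, ranked by Euclidean distance computed over the columns
    observed in both rows.  Each missing column is filled with the
    unweighted mean of that column's values in the k nearest candidates
    that observe it; if fewer than k such candidates exist, all available
    are used.  Distance ties break by row order (stable sort), making the
    result deterministic.  A probe sharing no observed column with any
    other row falls back to its own row mean (logged).

    Rows without missing values pass through bit-identically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        bad = list(m.probe_ids[~obs.any(axis=1)])
        raise ValueError(f"probes with no observed value: {bad[:5]}")

    out = X.copy()
    for i in np.where(~obs.all(axis=1))[0]:
        xi = X[i]
        both = obs & obs[i]
        diff = np.where(both, X - xi, 0.0)
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        dist[both.sum(axis=1) == 0] = np.inf
        dist[i] = np.inf
        order = np.argsort(dist, kind="stable")
        order = order[np.isfinite(dist[order])]
        row_mean = float(np.nanmean(xi))
        if order.size == 0:
            logger.warning(
                "knn_impute: probe %s shares no observed column with any other "
                "probe; using row mean", m.probe_ids[i],
            )
            out[i, ~obs[i]] = row_mean
            continue
        for j in np.where(~obs[i])[0]:
            cand = order[obs[order, j]][:k]
            if cand.size == 0:
                logger.warning(
                    "knn_impute: no neighbour observes column %s for probe %s; "
                    "using row mean", m.sample_ids[j], m.probe_ids[i],
                )
                out[i, j] = row_mean
            else:
                out[i, j] = float(X[cand, j].mean())
    frame = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return replace(m, values=frame)


def collapse_probes_to_genes(
    m: ProbeMatrix, ann: ProbeAnnotation, groups: pd.Series | None = None
) -> ExpressionMatrix:
    """Collapse a complete probe matrix to gene level.

    Probes mapping to zero or more than one gene ID are deleted; the
    remaining probes sharing a gene ID are averaged per sample.  Genes are
    emitted in sorted order.  Annotation entries for probes absent from
    the matrix are ignored with a warning.
    """
    if m.values.isna().any().any():
        raise ValueError("collapse_probes_to_genes requires a complete matrix")
    present = set(map(str, m.probe_ids))
    unknown = [p for p in ann.mapping if p not in present]
    if unknown:
        logger.warning(
            "collapse_probes_to_genes: %d annotation probes not in matrix "
            "(ignored)", len(unknown),
        )
    gene_of: dict[str, str] = {}
    n_multi = n_unmapped = 0
    for probe in m.probe_ids:
        genes = ann.genes_for(str(probe))
        if len(genes) == 1:
            gene_of[probe] = next(iter(genes))
        elif len(genes) == 0:
            n_unmapped += 1
        else:
            n_multi += 1
    logger.info(
        "collapse_probes_to_genes: %d probes kept, %d unmapped and %d "
        "multi-mapped deleted", len(gene_of), n_unmapped, n_multi,
    )
    kept = m.values.loc[list(gene_of)]
    collapsed = kept.groupby(pd.Series(gene_of), sort=True).mean()
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(collapsed, platform="microarray", groups=groups)


def transform_rnaseq(
    counts: pd.DataFrame, groups: pd.Series | None = None
) -> ExpressionMatrix:
    """log2(x+1)-transform normalized expression counts.

    Counts of this kind are roughly log-normal with an extra spike near
    zero, so the shifted log keeps zeros at 0.0 while linearising the body.
    """
    values = counts.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("RNA-seq counts must not contain missing values")
    if (values < 0).any():
        raise ValueError("RNA-seq counts must be non-negative")
    frame = pd.DataFrame(np.log2(values + 1.0), index=counts.index, columns=counts.columns)
    frame.index.name = "gene_id"
    return ExpressionMatrix(frame, platform="rnaseq", groups=groups)
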