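"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices are TSV with the id column first and sample ids as the header;
missing entries use a configurable token (default "NA").  Annotations,
group labels and interaction networks are two-column TSVs; gene sets use
GMT; GO arrives as three TSVs (terms, child-parent edges, gene-term
annotations).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import GODag, load_ppi_network
from .preprocess import ProbeAnnotation

NA_TOKEN = "NA"


def read_matrix_tsv(path, na_token: str = NA_TOKEN) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[na_token], keep_default_na=False
    )
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path, na_token: str = NA_TOKEN) -> None:
    df.to_csv(path, sep="\t", na_rep=na_token, float_format="%.6g")


def read_groups_tsv(path) -> pd.Series:
    """Two-column TSV (sample_id, group) → Series sample → group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def write_groups_tsv(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_annotation_tsv(path) -> ProbeAnnotation:
    """Two-column TSV (probe_id, gene_id); repeated probes mean multi-mapped."""
    return ProbeAnnotation.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation_tsv(ann: ProbeAnnotation, path) -> None:
    rows = [
        {"probe_id": p, "gene_id": g}
        for p in sorted(ann.mapping)
        for g in sorted(ann.mapping[p])
    ]
    pd.DataFrame(rows, columns=["probe_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "-") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path):
    """Two-column TSV of undirected edges → simple graph without self-loops."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return load_ppi_network(list(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_edge_list(graph, path) -> None:
    pd.DataFrame(sorted(graph.edges), columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_go_tables(terms_path, edges_path, annotations_path) -> GODag:
    """Assemble a GODag from term, is_a-edge, and gene-annotation TSVs."""
    terms = pd.read_csv(terms_path, sep="\t", dtype=str)
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    annot = pd.read_csv(annotations_path, sep="\t", dtype=str)
    names = dict(zip(terms.iloc[:, 0], terms.iloc[:, 1]))
    edge_pairs = list(zip(edges.iloc[:, 0], edges.iloc[:, 1]))
    gene_terms: dict[str, set[str]] = {}
    for gene, term in zip(annot.iloc[:, 0], annot.iloc[:, 1]):
        gene_terms.setdefault(gene, set()).add(term)
    return GODag(edge_pairs, gene_terms, names)


def write_go_tables(dag: GODag, direct_annotations: dict[str, set[str]],
                    terms_path, edges_path, annotations_path) -> None:
    pd.DataFrame(
        [{"term_id": t, "name": dag.name_of(t)} for t in sorted(dag.terms)]
    ).to_csv(terms_path, sep="\t", index=False)
    pd.DataFrame(
        sorted(dag.graph.edges), columns=["child", "parent"]
    ).to_csv(edges_path, sep="\t", index=False)
    rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(direct_annotations)
        for t in sorted(direct_annotations[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        annotations_path, sep="\t", index=False
    )
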