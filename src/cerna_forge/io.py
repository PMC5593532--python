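"""Readers and writers for every on-disk format the pipeline touches.

Formats: TSV expression matrix plus a sample/gene metadata sidecar, BED6 with
a biotype column (and GFF3 converted at the boundary), FASTA, two-column
term->gene maps, Ct tables, and network output as both a five-column edge
list and GraphML. Every reader/writer pair round-trips losslessly to six
decimals for reals and exactly for integers and strings.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, FormatError, MetadataError, ParseError
from .model import BIOTYPES, ExpressionMatrix, GeneAnnotation, SequenceSet

_NA = "."


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_table(path, labels) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its metadata sidecar.

    The matrix has sample ids in the header row and gene ids in the first
    column. The sidecar is a TSV with columns ``id, type, group, pair,
    biotype``; ``type`` is ``sample`` or ``gene`` and inapplicable fields
    hold ``"."``.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates or raw.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate gene or sample ids")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, (gene, cell) in enumerate(raw[col].items()):
            try:
                values.iloc[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell at row {gene!r} (line {i + 2}), "
                    f"column {col!r}"
                ) from None
    group_of, pair_of, biotype_of = _read_labels(labels)
    missing = [s for s in values.columns if s not in group_of]
    if missing:
        raise MetadataError(f"{labels}: samples missing from metadata: {missing}")
    return ExpressionMatrix(
        values=values,
        biotype_of={g: b for g, b in biotype_of.items() if g in values.index},
        group_of={s: group_of[s] for s in values.columns},
        pair_of={s: pair_of[s] for s in values.columns},
    )


def _read_labels(path):
    group_of: dict[str, str] = {}
    pair_of: dict[str, int] = {}
    biotype_of: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "type", "group", "pair", "biotype"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: metadata needs columns {sorted(required)}")
        for row in reader:
            if row["type"] == "sample":
                group_of[row["id"]] = row["group"]
                try:
                    pair_of[row["id"]] = int(row["pair"])
                except ValueError:
                    raise ParseError(
                        f"{path}: non-integer pair index for sample {row['id']!r}"
                    ) from None
            elif row["type"] == "gene":
                if row["biotype"] != _NA:
                    biotype_of[row["id"]] = row["biotype"]
            else:
                raise FormatError(f"{path}: unknown record type {row['type']!r}")
    return group_of, pair_of, biotype_of


def write_expression_table(matrix: ExpressionMatrix, path, labels) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6f", index_label="gene_id")
    with open(labels, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "type", "group", "pair", "biotype"])
        for s in matrix.sample_ids:
            writer.writerow([s, "sample", matrix.group_of[s], matrix.pair_of[s], _NA])
        for g in matrix.gene_ids:
            writer.writerow([g, "gene", _NA, _NA, matrix.biotype_of.get(g, _NA)])


# ---------------------------------------------------------------------------
# annotations


def read_annotation(path) -> list[GeneAnnotation]:
    """Read BED6 + biotype (column 7). Intervals stay 0-based half-open.

    Strand ``.`` is rejected: the promoter window needs an orientation.
    """
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            chrom, start, end, name, _score, strand, biotype = parts[:7]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start_i >= end_i:
                raise FormatError(f"{path}:{lineno}: start >= end ({start_i} >= {end_i})")
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: strand must be + or - (got {strand!r}); "
                    "strandless records cannot anchor a promoter window"
                )
            out.append(GeneAnnotation(name, chrom, start_i, end_i, strand, biotype))
    return out


def write_annotation(annotations: Sequence[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.gene_id}\t0\t{a.strand}\t{a.biotype}\n"
            )


def read_gff3_annotation(path) -> list[GeneAnnotation]:
    """Read gene records from GFF3; 1-based closed intervals become 0-based half-open."""
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _src, _type, start, end, _score, strand, _phase, attrs = parts
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("gene_id")
            biotype = attr_map.get("biotype", "")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
            out.append(
                GeneAnnotation(gene_id, chrom, int(start) - 1, int(end), strand, biotype)
            )
    return out


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path, role_of: Mapping[str, str] | None = None,
               default_role: str = "transcript") -> SequenceSet:
    sequences: dict[str, str] = {}
    roles: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
        role = default_role if role_of is None else role_of.get(rec.id, default_role)
        # a "role=" tag in the description wins over the default
        for token in rec.description.split():
            if token.startswith("role="):
                role = token[len("role="):]
        roles[rec.id] = role
    return SequenceSet(sequences, roles)


def write_fasta(seqs: SequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=f"role={seqs.role_of[name]}")
        for name, seq in seqs.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# term maps


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV ``term_id<TAB>gene_id`` -> term -> gene set."""
    term_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            term_map.setdefault(parts[0], set()).add(parts[1])
    return term_map


def write_term_map(term_map: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{term}\t{gene}\n")


# ---------------------------------------------------------------------------
# networks


def write_network(edges, path) -> None:
    """Write correlation edges as ``<path>.tsv`` and ``<path>.graphml``.

    The TSV carries (source, target, r, p, sign); GraphML carries the same
    attributes plus node biotypes for layout tools.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    known_nodes = set()
    for e in edges:
        known_nodes.update((e.gene_a, e.gene_b))
    graph = nx.Graph()
    with open(base.with_suffix(".tsv"), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "r", "p", "sign"])
        for e in edges:
            if e.gene_a not in known_nodes or e.gene_b not in known_nodes:
                raise ConsistencyError(f"edge references unknown node: {e}")
            writer.writerow([e.gene_a, e.gene_b, f"{e.r:.6f}", f"{e.p_value:.6g}", e.sign])
            graph.add_node(e.gene_a, biotype=e.biotype_a)
            graph.add_node(e.gene_b, biotype=e.biotype_b)
            graph.add_edge(e.gene_a, e.gene_b, r=float(e.r), p=float(e.p_value), sign=e.sign)
    nx.write_graphml(graph, base.with_suffix(".graphml"))


def read_network(path):
    """Read the five-column edge list written by :func:`write_network`."""
    from .coexpression import CorrelationEdge  # local import avoids a cycle

    base = Path(path)
    graphml = nx.read_graphml(base.with_suffix(".graphml"))
    edges = []
    with open(base.with_suffix(".tsv")) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            a, b = row["source"], row["target"]
            edges.append(
                CorrelationEdge(
                    gene_a=a,
                    gene_b=b,
                    biotype_a=graphml.nodes[a].get("biotype", ""),
                    biotype_b=graphml.nodes[b].get("biotype", ""),
                    r=float(row["r"]),
                    p_value=float(row["p"]),
                )
            )
    return edges


# ---------------------------------------------------------------------------
# Ct tables


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct TSV with columns sample_id, group, gene_id, ct, is_reference."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    required = {"sample_id", "group", "gene_id", "ct", "is_reference"}
    if not required.issubset(table.columns):
        raise FormatError(f"{path}: Ct table needs columns {sorted(required)}")
    if (table["ct"] <= 0).any():
        bad = table.loc[table["ct"] <= 0]
        raise FormatError(f"{path}: non-positive Ct values:\n{bad}")
    table["is_reference"] = table["is_reference"].astype(bool)
    return table


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
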