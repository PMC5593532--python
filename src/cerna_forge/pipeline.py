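"""End-to-end orchestration: simulate -> preprocess -> DE -> CNC -> targets
-> ceRNA -> validation, plus recovery scoring against the planted truth.

The analysis drivers and the CLI are thin wrappers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .cerna import CeRNATriplet, build_cerna_network, network_summary, triplets_to_frame
from .coexpression import CorrelationEdge, build_cnc_network
from .diffexpr import DifferentialRecord, compute_differential, records_to_frame, volcano_coordinates
from .model import Config, ExpressionMatrix
from .preprocess import filter_background, quantile_normalize
from .simulate import (
    SimulationSpec,
    TruthTable,
    simulate_annotations,
    simulate_expression,
    simulate_qpcr,
    simulate_sequences,
    simulate_term_map,
)
from .targets import seed_targets
from .validation import qpcr_summarize


@dataclass
class PipelineResult:
    matrices: dict[str, ExpressionMatrix]
    truth: TruthTable
    de_records: list[DifferentialRecord]
    edges: list[CorrelationEdge]
    triplets: list[CeRNATriplet]
    removed_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def passing_genes(self) -> set[str]:
        return {r.gene_id for r in self.de_records if r.passes}


def combine_matrices(matrices: dict[str, ExpressionMatrix]) -> ExpressionMatrix:
    """Stack per-biotype matrices sharing the same samples into one."""
    frames = [m.values for m in matrices.values()]
    biotype_of: dict[str, str] = {}
    for m in matrices.values():
        biotype_of.update(m.biotype_of)
    first = next(iter(matrices.values()))
    return ExpressionMatrix(
        values=pd.concat(frames, axis=0),
        biotype_of=biotype_of,
        group_of=dict(first.group_of),
        pair_of=dict(first.pair_of),
    )


def preprocess_matrices(
    matrices: dict[str, ExpressionMatrix], config: Config
) -> tuple[dict[str, ExpressionMatrix], dict[str, list[str]]]:
    """Background-filter every biotype; quantile-normalize per config."""
    out: dict[str, ExpressionMatrix] = {}
    removed: dict[str, list[str]] = {}
    for biotype, matrix in matrices.items():
        filtered, dropped = filter_background(
            matrix, config.background_level, config.background_min_samples
        )
        mode = (config.normalize_mirna if biotype == "miRNA"
                else config.normalize_lnc_mrna)
        out[biotype] = quantile_normalize(filtered) if mode == "quantile" else filtered
        removed[biotype] = dropped
    return out, removed


def run_pipeline(
    spec: SimulationSpec, config: Config | None = None
) -> PipelineResult:
    """Full synthetic run: generate, screen, correlate, intersect."""
    config = config or Config()
    matrices, truth = simulate_expression(spec)
    matrices, removed = preprocess_matrices(matrices, config)

    de_records: list[DifferentialRecord] = []
    for matrix in matrices.values():
        de_records.extend(compute_differential(matrix, config))
    passing = {r.gene_id for r in de_records if r.passes}

    combined = combine_matrices(matrices).subset_genes(passing)
    edges = build_cnc_network(combined, config=config)

    sequences = simulate_sequences(truth, spec)
    matches = seed_targets(sequences, sequences)
    matches = [m for m in matches
               if m.mirna_id in passing and m.target_id in passing]
    triplets = build_cerna_network(edges, matches)
    return PipelineResult(matrices, truth, de_records, edges, triplets, removed)


def score_recovery(result: PipelineResult) -> dict[str, float]:
    """Recall/precision of planted DE genes and planted triplets."""
    truth = result.truth
    planted_de = set(truth.de_genes)
    recovered_de = result.passing_genes
    planted_triplets = set(truth.planted_triplets)
    found_triplets = {t.key for t in result.triplets}

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "de_recall": _ratio(len(planted_de & recovered_de), len(planted_de)),
        "de_precision": _ratio(len(planted_de & recovered_de), len(recovered_de)),
        "triplet_recall": _ratio(
            len(planted_triplets & found_triplets), len(planted_triplets)
        ),
        "triplet_precision": _ratio(
            len(planted_triplets & found_triplets), len(found_triplets)
        ),
    }


def write_dataset(spec: SimulationSpec, out_dir) -> None:
    """Materialize a complete synthetic dataset in core_io formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, truth = simulate_expression(spec)
    for biotype, matrix in matrices.items():
        stem = biotype.lower()
        io.write_expression_table(
            matrix, out / f"{stem}_matrix.tsv", out / f"{stem}_labels.tsv"
        )
    sequences = simulate_sequences(truth, spec)
    io.write_fasta(sequences, out / "sequences.fasta")
    io.write_annotation(simulate_annotations(truth, spec), out / "annotation.bed")
    io.write_term_map(simulate_term_map(truth, spec), out / "term_map.tsv")
    qpcr_genes = [g for t in truth.planted_triplets for g in t]
    io.write_ct_table(
        simulate_qpcr(truth, qpcr_genes, n_pairs=spec.n_pairs, seed=spec.seed + 4,
                      noise_sd=spec.qpcr_noise_sd),
        out / "qpcr_ct.tsv",
    )
    truth.to_json(out / "truth.json")


def write_pipeline_outputs(result: PipelineResult, out_dir) -> list[str]:
    """Write the standard per-stage tables; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    frame = records_to_frame(result.de_records)
    frame.to_csv(out / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    frame[frame["passes"]].to_csv(
        out / "de_passing.tsv", sep="\t", index=False, float_format="%.6g"
    )
    volcano_coordinates(result.de_records).to_csv(
        out / "volcano.tsv", sep="\t", index=False, float_format="%.6g"
    )
    manifest += ["de_results.tsv", "de_passing.tsv", "volcano.tsv"]

    with open(out / "filtered_genes.txt", "w") as fh:
        for biotype, genes in result.removed_genes.items():
            for g in genes:
                fh.write(f"{biotype}\t{g}\n")
    manifest.append("filtered_genes.txt")

    io.write_network(result.edges, out / "cnc_network")
    manifest += ["cnc_network.tsv", "cnc_network.graphml"]

    triplets_to_frame(result.triplets).to_csv(
        out / "cerna_triplets.tsv", sep="\t", index=False, float_format="%.6g"
    )
    network_summary(result.triplets).to_csv(
        out / "cerna_summary.tsv", sep="\t", index=False
    )
    manifest += ["cerna_triplets.tsv", "cerna_summary.tsv"]
    return manifest
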