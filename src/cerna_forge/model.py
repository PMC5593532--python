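"""Shared in-memory data model.

The pipeline's substrate is a genes x samples matrix of log2 intensities with
paired case/control labels (``ExpressionMatrix``), BED-convention genomic
intervals (``GeneAnnotation``), tagged nucleotide sequence collections
(``SequenceSet``) and a flat threshold configuration (``Config``).

Coordinates are 0-based, half-open everywhere; expression values are log2
scale; id matching is case-sensitive and exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, MetadataError

BIOTYPES = ("lncRNA", "mRNA", "miRNA")
GROUPS = ("case", "control")
SEQUENCE_ROLES = ("transcript", "three_prime_utr", "promoter", "mirna", "genome")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-intensity table with paired group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns (log2 scale).
    biotype_of
        gene id -> one of :data:`BIOTYPES`. May be missing for genes the
        differential stage never sees.
    group_of
        sample id -> ``"case"`` or ``"control"``.
    pair_of
        sample id -> pair index; each pair index maps to exactly two samples,
        one per group.
    """

    values: pd.DataFrame
    biotype_of: dict[str, str]
    group_of: dict[str, str]
    pair_of: dict[str, int]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        for s in self.sample_ids:
            if s not in self.group_of:
                raise MetadataError(f"sample {s!r} has no group label")
            if self.group_of[s] not in GROUPS:
                raise MetadataError(f"sample {s!r}: bad group {self.group_of[s]!r}")
            if s not in self.pair_of:
                raise MetadataError(f"sample {s!r} has no pair index")
        pairs: dict[int, list[str]] = {}
        for s in self.sample_ids:
            pairs.setdefault(self.pair_of[s], []).append(s)
        for idx, members in pairs.items():
            groups = sorted(self.group_of[s] for s in members)
            if len(members) != 2 or groups != ["case", "control"]:
                raise MetadataError(
                    f"pair {idx} has members {members} with groups {groups}; "
                    "each pair needs exactly one case and one control"
                )
        for g, b in self.biotype_of.items():
            if b not in BIOTYPES:
                raise MetadataError(f"gene {g!r}: unknown biotype {b!r}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise FormatError("expression values must be numeric")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_pairs(self) -> int:
        return len(set(self.pair_of.values()))

    def paired_columns(self) -> tuple[list[str], list[str]]:
        """Case and control sample ids, aligned by ascending pair index."""
        by_pair: dict[int, dict[str, str]] = {}
        for s in self.sample_ids:
            by_pair.setdefault(self.pair_of[s], {})[self.group_of[s]] = s
        case, control = [], []
        for idx in sorted(by_pair):
            case.append(by_pair[idx]["case"])
            control.append(by_pair[idx]["control"])
        return case, control

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(
            values=self.values.loc[keep].copy(),
            biotype_of={g: b for g, b in self.biotype_of.items() if g in set(keep)},
            group_of=dict(self.group_of),
            pair_of=dict(self.pair_of),
        )

    def genes_of_biotype(self, biotype: str) -> list[str]:
        return [g for g in self.gene_ids if self.biotype_of.get(g) == biotype]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus: 0-based half-open interval plus strand and biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise FormatError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        """Transcription start: interval start on +, end-1 on -."""
        return self.start if self.strand == "+" else self.end - 1


DNA = set("ACGT")
RNA = set("ACGU")


@dataclass
class SequenceSet:
    """Mapping id -> nucleotide string, with one role tag per record.

    miRNA records are RNA (``ACGU``); everything else is DNA (``ACGT``).
    """

    sequences: dict[str, str]
    role_of: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            role = self.role_of.get(name)
            if role is None:
                raise MetadataError(f"sequence {name!r} has no role tag")
            if role not in SEQUENCE_ROLES:
                raise MetadataError(f"sequence {name!r}: unknown role {role!r}")
            if not seq:
                raise FormatError(f"sequence {name!r} is empty")
            alphabet = RNA if role == "mirna" else DNA
            bad = set(seq) - alphabet
            if bad:
                raise FormatError(
                    f"sequence {name!r} (role {role}) has illegal characters {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def ids_with_role(self, role: str) -> list[str]:
        return [n for n in self.sequences if self.role_of[n] == role]

    def merged_with(self, other: "SequenceSet") -> "SequenceSet":
        seqs = dict(self.sequences)
        roles = dict(self.role_of)
        seqs.update(other.sequences)
        roles.update(other.role_of)
        return SequenceSet(seqs, roles)


@dataclass
class Config:
    """All screening thresholds and stage knobs in one flat record.

    Defaults follow the study design this pipeline emulates: linear fold
    change > 2.0 for lncRNA/mRNA and > 1.5 for miRNA at paired-t p <= 0.05;
    co-expression edges at |r| > 0.90 with p < 0.01; a 10 kb cis window; a
    promoter window from 2000 bp upstream to 500 bp downstream of the TSS.
    """

    fc_threshold_lnc_mrna: float = 2.0
    fc_threshold_mirna: float = 1.5
    p_threshold_de: float = 0.05
    r_threshold: float = 0.90
    p_threshold_corr: float = 0.01
    cis_window_bp: int = 10_000
    promoter_upstream_bp: int = 2_000
    promoter_downstream_bp: int = 500
    seed: int = 0
    # preprocess
    background_level: float = 4.0          # log2 intensity floor
    background_min_samples: int = 1
    normalize_mirna: str = "quantile"      # quantile | none
    normalize_lnc_mrna: str = "none"       # vendor pipeline unspecified; off by default
    # diffexpr
    apply_bh: bool = False                 # Benjamini-Hochberg, off to mirror the source design
    volcano_y_cap: float = 300.0
    # enrichment
    universe: str = "filtered"             # filtered | all_annotated
    min_term_size: int = 0
    # coexpression
    correlation_method: str = "pearson"    # pearson | spearman
    within_biotype_edges: bool = False
    # targets (BLAT-like stand-in)
    trans_tile_size: int = 11
    trans_xdrop: int = 10
    trans_match_score: int = 1
    trans_mismatch_score: int = -3
    trans_min_identity: float = 0.90
    trans_min_length: int = 20
    pwm_score_fraction: float = 0.8
    # validation
    welch: bool = False
    test_on_fold_scale: bool = False

    def __post_init__(self) -> None:
        for name in (
            "fc_threshold_lnc_mrna", "fc_threshold_mirna", "p_threshold_de",
            "r_threshold", "p_threshold_corr", "cis_window_bp",
            "promoter_upstream_bp", "promoter_downstream_bp",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.fc_threshold_lnc_mrna <= 1 or self.fc_threshold_mirna <= 1:
            raise ConfigError("fold-change thresholds must exceed 1 (linear scale)")
        if not (0 < self.r_threshold < 1):
            raise ConfigError("r_threshold must lie in (0, 1)")

    def fc_threshold_for(self, biotype: str) -> float:
        return self.fc_threshold_mirna if biotype == "miRNA" else self.fc_threshold_lnc_mrna

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
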