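"""Synthetic paired-design expression data with planted ceRNA structure.

The generator emulates the kind of paired case/control microarray study the
pipeline is built for: log2-scale intensity matrices for three biotypes over
the same sample pairs, with three kinds of planted signal recorded in a
:class:`TruthTable`:

* differential expression — selected genes receive a +/- ``de_log2fc``
  shift in the case samples;
* ceRNA triplets — each planted (lncRNA, miRNA, mRNA) triplet shares one
  latent regulator level per sample pair, loading positively on the miRNA
  and negatively on the lncRNA and mRNA, so the lncRNA and mRNA are
  positively correlated and both anti-correlate with the miRNA. The loading
  is derived from the requested implied correlation:
  |r| = lambda^2 / (lambda^2 + noise_sd^2). The latent level is matched
  within a pair (a shared biological state of the matched animals), so it
  cancels in paired differences and does not mask planted differential
  expression;
* sequence evidence — the DNA reverse complement of each triplet miRNA's
  seed (positions 2-8) is written into its mRNA 3'UTR and lncRNA transcript
  at recorded offsets, and TF consensus motifs are written into lncRNA
  promoter windows.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SpecError
from .model import Config, ExpressionMatrix, GeneAnnotation, SequenceSet
from .motifs import Motif, reverse_complement
from .targets import SEED_LENGTH, seed_sequence

_BASES = np.array(list("ACGT"))
_RNA_BASES = np.array(list("ACGU"))

# toy TF consensus analogues planted into lncRNA promoter windows
DEFAULT_MOTIF_CONSENSI = {
    "CREB": "TGACGTCA",
    "STAT3": "TTCCCGGAA",
    "OCT1": "ATGCAAAT",
}


@dataclass
class SimulationSpec:
    """Study-condition knobs for the generator.

    Defaults mirror the emulated study where stated (10 sample pairs) and
    otherwise use values a paired microarray screen would consider
    realistic: platform-like gene pools at desk scale (hundreds of probes
    per biotype with a small differentially-expressed fraction, so quantile
    normalization's mostly-unchanged-genes assumption holds), log2
    baselines around 8 +/- 1.5, per-sample noise 0.3 on the log2 scale,
    planted effects of 2 log2 units, and planted correlations implied at
    0.95.
    """

    n_lnc: int = 500
    n_mrna: int = 800
    n_mirna: int = 300
    n_pairs: int = 10
    n_de_lnc: int = 20
    n_de_mrna: int = 20
    n_de_mirna: int = 20
    de_log2fc: float = 2.0
    n_triplets: int = 10
    implied_r: float = 0.95
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0
    triplet_members_forced_de: bool = True
    mirna_length: int = 22
    lnc_length: int = 400
    utr_length: int = 300
    promoter_upstream_bp: int = 2000
    promoter_downstream_bp: int = 500
    qpcr_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_triplets > min(self.n_lnc, self.n_mirna, self.n_mrna):
            raise SpecError(
                f"n_triplets={self.n_triplets} exceeds a gene pool "
                f"({self.n_lnc}/{self.n_mirna}/{self.n_mrna})"
            )
        if self.triplet_members_forced_de and self.n_triplets > min(
            self.n_de_lnc, self.n_de_mrna, self.n_de_mirna
        ):
            raise SpecError("n_triplets exceeds an n_de pool with forced-DE triplets")
        for name in ("noise_sd", "baseline_sd", "de_log2fc"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be non-negative")
        if not (0 < self.implied_r < 1):
            raise SpecError("implied_r must lie in (0, 1)")
        if self.n_pairs < 2:
            raise SpecError("need at least 2 sample pairs")

    @property
    def latent_loading(self) -> float:
        """lambda with lambda^2/(lambda^2 + noise_sd^2) = implied_r."""
        return self.noise_sd * np.sqrt(self.implied_r / (1.0 - self.implied_r))


@dataclass
class TruthTable:
    """Planted ground truth for recovery scoring."""

    de_genes: dict[str, float]                      # gene -> planted log2 effect
    planted_pairs: list[tuple[str, str, str]]       # (gene_a, gene_b, sign)
    planted_triplets: list[tuple[str, str, str]]    # (lncRNA, miRNA, mRNA)
    planted_seed_sites: dict[tuple[str, str], int]  # (miRNA, target) -> offset
    planted_motif_sites: dict[tuple[str, str], int]  # (motif, lncRNA) -> offset
    biotype_of: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        pair_signs = {(a, b): s for a, b, s in self.planted_pairs}
        pair_signs.update({(b, a): s for a, b, s in self.planted_pairs})
        for lnc, mir, mrna in self.planted_triplets:
            expected = [((lnc, mir), "-"), ((mir, mrna), "-"), ((lnc, mrna), "+")]
            for pair, sign in expected:
                if pair_signs.get(pair) != sign:
                    raise SpecError(
                        f"triplet {(lnc, mir, mrna)}: pair {pair} missing or "
                        f"not signed {sign!r} in planted_pairs"
                    )
            for target in (mrna, lnc):
                if (mir, target) not in self.planted_seed_sites:
                    raise SpecError(
                        f"triplet {(lnc, mir, mrna)}: no planted seed site "
                        f"for ({mir}, {target})"
                    )

    def to_json(self, path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "planted_triplets": [list(t) for t in self.planted_triplets],
            "planted_seed_sites": [
                [m, t, o] for (m, t), o in self.planted_seed_sites.items()
            ],
            "planted_motif_sites": [
                [m, l, o] for (m, l), o in self.planted_motif_sites.items()
            ],
            "biotype_of": self.biotype_of,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            de_genes={g: float(e) for g, e in raw["de_genes"].items()},
            planted_pairs=[tuple(p) for p in raw["planted_pairs"]],
            planted_triplets=[tuple(t) for t in raw["planted_triplets"]],
            planted_seed_sites={(m, t): int(o) for m, t, o in raw["planted_seed_sites"]},
            planted_motif_sites={(m, l): int(o) for m, l, o in raw["planted_motif_sites"]},
            biotype_of=raw.get("biotype_of", {}),
        )


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:04d}" for i in range(n)]


def simulate_expression(
    spec: SimulationSpec,
) -> tuple[dict[str, ExpressionMatrix], TruthTable]:
    """Per-biotype expression matrices plus the truth table.

    All three matrices share the same paired samples. Triplet members are
    planted DE by default (the downstream network is built from DE genes
    only), with the miRNA and its two partners shifted in opposite
    directions so the planted correlation signs survive the group shift.
    """
    rng = np.random.default_rng(spec.seed)
    names = {
        "lncRNA": _gene_names("lnc", spec.n_lnc),
        "mRNA": _gene_names("mrna", spec.n_mrna),
        "miRNA": _gene_names("mir", spec.n_mirna),
    }
    pools = {"lncRNA": spec.n_de_lnc, "mRNA": spec.n_de_mrna, "miRNA": spec.n_de_mirna}

    # choose triplet members (disjoint within a biotype), then extra DE genes
    chosen = {
        b: list(rng.choice(names[b], size=spec.n_triplets, replace=False))
        for b in names
    }
    triplets = list(zip(chosen["lncRNA"], chosen["miRNA"], chosen["mRNA"]))

    effect: dict[str, float] = {}
    if spec.triplet_members_forced_de and spec.de_log2fc > 0:
        flips = rng.choice([-1.0, 1.0], size=spec.n_triplets)
        for (lnc, mir, mrna), s in zip(triplets, flips):
            effect[mir] = s * spec.de_log2fc
            effect[lnc] = -s * spec.de_log2fc
            effect[mrna] = -s * spec.de_log2fc
    for b in names:
        remaining = [g for g in names[b] if g not in effect]
        extra = max(0, pools[b] - (spec.n_triplets if spec.triplet_members_forced_de
                                   and spec.de_log2fc > 0 else 0))
        extra = min(extra, len(remaining))
        for g in rng.choice(remaining, size=extra, replace=False):
            effect[g] = float(rng.choice([-1.0, 1.0])) * spec.de_log2fc

    samples_case = [f"case_{i:02d}" for i in range(spec.n_pairs)]
    samples_ctrl = [f"ctrl_{i:02d}" for i in range(spec.n_pairs)]
    sample_ids = samples_case + samples_ctrl
    is_case = np.array([1.0] * spec.n_pairs + [0.0] * spec.n_pairs)
    pair_idx = list(range(spec.n_pairs)) * 2

    lam = spec.latent_loading
    latent = rng.standard_normal((spec.n_triplets, spec.n_pairs))
    latent_by_sample = np.concatenate([latent, latent], axis=1)  # pair-matched

    loading: dict[str, tuple[int, float]] = {}
    for t, (lnc, mir, mrna) in enumerate(triplets):
        loading[mir] = (t, +lam)
        loading[lnc] = (t, -lam)
        loading[mrna] = (t, -lam)

    matrices: dict[str, ExpressionMatrix] = {}
    biotype_of_all: dict[str, str] = {}
    for b, genes in names.items():
        baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
        noise = rng.normal(0.0, spec.noise_sd, size=(len(genes), 2 * spec.n_pairs))
        values = baseline[:, None] + noise
        for i, g in enumerate(genes):
            if g in loading:
                t, coef = loading[g]
                values[i] += coef * latent_by_sample[t]
            if g in effect:
                values[i] += effect[g] * is_case
        frame = pd.DataFrame(values, index=genes, columns=sample_ids)
        biotype = {g: b for g in genes}
        biotype_of_all.update(biotype)
        matrices[b] = ExpressionMatrix(
            values=frame,
            biotype_of=biotype,
            group_of={s: ("case" if s.startswith("case") else "control")
                      for s in sample_ids},
            pair_of=dict(zip(sample_ids, pair_idx)),
        )

    seed_sites: dict[tuple[str, str], int] = {}
    for lnc, mir, mrna in triplets:
        seed_sites[(mir, mrna)] = int(rng.integers(0, spec.utr_length - SEED_LENGTH + 1))
        seed_sites[(mir, lnc)] = int(rng.integers(0, spec.lnc_length - SEED_LENGTH + 1))

    motif_names = list(DEFAULT_MOTIF_CONSENSI)
    motif_sites: dict[tuple[str, str], int] = {}
    window = spec.promoter_upstream_bp + spec.promoter_downstream_bp
    for t, (lnc, _, _) in enumerate(triplets):
        motif = motif_names[t % len(motif_names)]
        width = len(DEFAULT_MOTIF_CONSENSI[motif])
        motif_sites[(motif, lnc)] = int(rng.integers(0, window - width + 1))

    pairs: list[tuple[str, str, str]] = []
    for lnc, mir, mrna in triplets:
        pairs.extend([(lnc, mir, "-"), (mir, mrna, "-"), (lnc, mrna, "+")])

    truth = TruthTable(
        de_genes=effect,
        planted_pairs=pairs,
        planted_triplets=triplets,
        planted_seed_sites=seed_sites,
        planted_motif_sites=motif_sites,
        biotype_of=biotype_of_all,
    )
    truth.validate()
    return matrices, truth


def _random_dna(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_sequences(
    truth: TruthTable, spec: SimulationSpec, seed: int | None = None
) -> SequenceSet:
    """miRNA, lncRNA transcript, mRNA 3'UTR and lncRNA promoter sequences.

    Background nucleotides are uniform (25% each). Each planted seed site
    receives the DNA reverse complement of the miRNA seed at its recorded
    offset; each planted motif site receives the motif consensus within the
    promoter window.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    sequences: dict[str, str] = {}
    roles: dict[str, str] = {}

    genes_by_biotype: dict[str, list[str]] = {}
    for g, b in truth.biotype_of.items():
        genes_by_biotype.setdefault(b, []).append(g)

    for mir in genes_by_biotype.get("miRNA", []):
        sequences[mir] = "".join(rng.choice(_RNA_BASES, size=spec.mirna_length))
        roles[mir] = "mirna"
    for lnc in genes_by_biotype.get("lncRNA", []):
        sequences[lnc] = _random_dna(rng, spec.lnc_length)
        roles[lnc] = "transcript"
    for mrna in genes_by_biotype.get("mRNA", []):
        sequences[mrna] = _random_dna(rng, spec.utr_length)
        roles[mrna] = "three_prime_utr"
    window = spec.promoter_upstream_bp + spec.promoter_downstream_bp
    for lnc in genes_by_biotype.get("lncRNA", []):
        pid = f"{lnc}_promoter"
        sequences[pid] = _random_dna(rng, window)
        roles[pid] = "promoter"

    for (mir, target), offset in truth.planted_seed_sites.items():
        site = seed_sequence(sequences[mir])
        seq = sequences[target]
        if offset + len(site) > len(seq):
            raise SpecError(
                f"planted site for ({mir}, {target}) at offset {offset} "
                f"exceeds sequence length {len(seq)}"
            )
        sequences[target] = seq[:offset] + site + seq[offset + len(site):]

    for (motif, lnc), offset in truth.planted_motif_sites.items():
        consensus = DEFAULT_MOTIF_CONSENSI[motif]
        pid = f"{lnc}_promoter"
        seq = sequences[pid]
        if offset + len(consensus) > len(seq):
            raise SpecError(
                f"planted motif {motif} for {lnc} at offset {offset} "
                f"exceeds promoter window {len(seq)}"
            )
        sequences[pid] = seq[:offset] + consensus + seq[offset + len(consensus):]

    return SequenceSet(sequences, roles)


def simulate_annotations(
    truth: TruthTable, spec: SimulationSpec, seed: int | None = None,
    n_cis_pairs: int = 5, chrom_length: int = 2_000_000, n_chroms: int = 4,
) -> list[GeneAnnotation]:
    """Toy genomic coordinates; the first ``n_cis_pairs`` planted
    lncRNA-mRNA partners are placed within the 10 kb cis window."""
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    lengths = {"lncRNA": spec.lnc_length, "mRNA": 2000, "miRNA": 100}
    out: list[GeneAnnotation] = []
    placed: dict[str, tuple[str, int]] = {}
    for t, (lnc, _mir, mrna) in enumerate(truth.planted_triplets[:n_cis_pairs]):
        chrom = f"chr{t % n_chroms + 1}"
        start = int(rng.integers(10_000, chrom_length - 50_000))
        placed[lnc] = (chrom, start)
        placed[mrna] = (chrom, start + spec.lnc_length + int(rng.integers(0, 8_000)))
    for g, b in sorted(truth.biotype_of.items()):
        if g in placed:
            chrom, start = placed[g]
        else:
            chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
            start = int(rng.integers(10_000, chrom_length - 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(GeneAnnotation(g, chrom, start, start + lengths[b], strand, b))
    return out


def simulate_term_map(
    truth: TruthTable, spec: SimulationSpec, seed: int | None = None,
    n_enriched: int = 2, n_background_terms: int = 6, term_size: int = 15,
    de_share: float = 0.6,
) -> dict[str, set[str]]:
    """A toy pathway map over the mRNA universe with planted enriched terms.

    Enriched terms draw ``de_share`` of their members from planted DE mRNAs;
    background terms sample uniformly.
    """
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    mrnas = sorted(g for g, b in truth.biotype_of.items() if b == "mRNA")
    de_mrnas = [g for g in mrnas if g in truth.de_genes]
    term_size = min(term_size, len(mrnas))
    term_map: dict[str, set[str]] = {}
    for i in range(n_enriched):
        n_de = min(len(de_mrnas), int(round(de_share * term_size)))
        members = set(rng.choice(de_mrnas, size=n_de, replace=False))
        others = [g for g in mrnas if g not in members]
        n_fill = min(term_size - n_de, len(others))
        members |= set(rng.choice(others, size=n_fill, replace=False))
        term_map[f"path_enriched_{i:02d}"] = members
    for i in range(n_background_terms):
        term_map[f"path_random_{i:02d}"] = set(
            rng.choice(mrnas, size=term_size, replace=False)
        )
    return term_map


def simulate_qpcr(
    truth: TruthTable,
    genes: Sequence[str],
    n_pairs: int = 10,
    seed: int = 0,
    noise_sd: float = 0.25,
    reference_genes: Mapping[str, str] = {"U6": "miRNA", "Actb": "mRNA"},
) -> pd.DataFrame:
    """Simulated Ct table: a gene with planted log2 effect e has case-vs-
    control ddCt ~ -e; reference genes carry no effect by construction.

    Sample-wide pipetting/loading shifts are added to every gene of a sample
    and cancel under reference normalization.
    """
    rng = np.random.default_rng(seed)
    unknown = [g for g in genes if g not in truth.biotype_of]
    if unknown:
        raise SpecError(f"genes absent from the truth table: {unknown}")
    all_genes = list(genes) + list(reference_genes)
    base_ct = {g: float(rng.uniform(18.0, 28.0)) for g in all_genes}
    rows = []
    for i in range(2 * n_pairs):
        group = "case" if i < n_pairs else "control"
        sample = f"q{group}_{i % n_pairs:02d}"
        sample_shift = float(rng.normal(0.0, 0.5))
        for g in all_genes:
            e = truth.de_genes.get(g, 0.0) if group == "case" else 0.0
            ct = base_ct[g] - e + sample_shift + float(rng.normal(0.0, noise_sd))
            rows.append((sample, group, g, ct, g in reference_genes))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene_id", "ct", "is_reference"]
    )


def default_motifs() -> list[Motif]:
    return [Motif.from_consensus(name, cons)
            for name, cons in DEFAULT_MOTIF_CONSENSI.items()]
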